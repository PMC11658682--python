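"""Statistical stage: summaries, two-way ANOVA with FDR, Tukey HSD,
and one-sample left-tailed t-tests against shedding frequency.

The analysis mirrors a treatments x speeds factorial on per-sequence
kinematic responses: per-cell mean +/- s.e.m. summaries, fixed-effects
two-way ANOVA with interaction (Type II sums of squares, suited to
mildly unbalanced data), Benjamini-Hochberg false-discovery-rate
adjustment across the family of response variables, Tukey(-Kramer) HSD
post hoc comparisons, and a left-tailed one-sample t-test of tail-beat
frequency against the predicted vortex shedding frequency.  Amplitude
responses may be log-transformed before fitting.

Sequences are treated as replicates without a fish-level random effect
(a per-fish averaging option is provided for sensitivity checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def summary_table(
    records: pd.DataFrame,
    responses: list[str],
    factors: tuple[str, str] = ("treatment", "speed"),
) -> pd.DataFrame:
    """Per-cell mean and s.e.m. (= sd/sqrt(n)) for each response.

    Cells with a single record get NaN s.e.m. flagged in ``note``;
    factor combinations absent from the data are simply not listed.
    """
    rows = []
    for key, cell in records.groupby(list(factors), observed=True, sort=True):
        for resp in responses:
            vals = cell[resp].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                rows.append(
                    dict(zip(factors, key), response=resp, n=0, mean=np.nan,
                         sem=np.nan, note="missing")
                )
                continue
            sem = (
                float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
            )
            rows.append(
                dict(
                    zip(factors, key),
                    response=resp,
                    n=int(vals.size),
                    mean=float(vals.mean()),
                    sem=sem,
                    note="" if vals.size > 1 else "single record: s.e.m. undefined",
                )
            )
    return pd.DataFrame(rows)


def average_per_fish(
    records: pd.DataFrame,
    responses: list[str],
    factors: tuple[str, str] = ("treatment", "speed"),
    fish_col: str = "fish_id",
) -> pd.DataFrame:
    """Collapse sequences to one mean per fish x cell (sensitivity option)."""
    keys = [fish_col, *factors]
    return records.groupby(keys, observed=True, as_index=False)[list(responses)].mean()


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    response: str
    transform: str | None
    table: pd.DataFrame          # index: factor A, factor B, interaction, residual

    def term(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["F"]), float(row["p"])


_P_FLOOR = np.finfo(float).tiny


def two_way_anova(
    records: pd.DataFrame,
    response: str,
    factors: tuple[str, str] = ("treatment", "speed"),
    transform: str | None = None,
) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction, Type II SS.

    ``transform='log'`` log-transforms the response before fitting (used
    for amplitudes, whose multiplicative errors become normal in log
    space).  With zero residual variance all F statistics are 0 and all
    p values 1 when the effects are also zero; nonzero effects on a
    degenerate residual report an underflow-safe minimal p.
    """
    a, b = factors
    df = records[[a, b, response]].dropna().copy()
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    y = df[response].astype(float)
    if transform == "log":
        if (y <= 0).any():
            raise ValueError("log transform requires positive response values")
        y = np.log(y)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    df["_y"] = y

    if np.ptp(y.to_numpy()) == 0.0:
        # all observations identical: no variance anywhere
        idx = [a, b, f"{a}:{b}", "residual"]
        table = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": [0.0, 0.0, 0.0, np.nan],
             "p": [1.0, 1.0, 1.0, np.nan]},
            index=idx,
        )
        return AnovaResult(response=response, transform=transform, table=table)

    model = smf.ols(f"_y ~ C(Q('{a}')) * C(Q('{b}'))", data=df).fit()
    raw = sm.stats.anova_lm(model, typ=2)

    def pretty(name: str) -> str:
        name = name.replace(f"C(Q('{a}'))", a).replace(f"C(Q('{b}'))", b)
        return "residual" if name == "Residual" else name

    raw.index = [pretty(i) for i in raw.index]
    raw = raw.rename(columns={"PR(>F)": "p"})
    resid_ss = float(raw.loc["residual", "sum_sq"])
    if resid_ss <= 0:
        # zero residual variance with nonzero effects
        raw.loc[raw.index != "residual", "F"] = np.inf
        raw.loc[raw.index != "residual", "p"] = _P_FLOOR
    else:
        raw["p"] = raw["p"].clip(lower=_P_FLOOR)
    return AnovaResult(response=response, transform=transform, table=raw)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_adjust(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("fdr_adjust needs at least one p value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def bh_adjusted_alpha(p_values, alpha: float = 0.05) -> float:
    """Effective BH threshold alpha*k/m for a declared family.

    ``k`` is the largest rank whose ordered p value passes the step-up
    rule; with no rejections the strictest threshold alpha/m is
    reported.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    m = p.size
    if m == 0:
        raise ValueError("need at least one p value")
    ranks = np.arange(1, m + 1)
    passed = ranks[p <= alpha * ranks / m]
    k = int(passed.max()) if passed.size else 1
    return alpha * k / m


# ---------------------------------------------------------------------------
# post hoc and t-tests
# ---------------------------------------------------------------------------

def tukey_hsd(
    records: pd.DataFrame,
    response: str,
    grouping: str | list[str],
    transform: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise comparisons with studentized-range p values.

    Unequal cell sizes use the Tukey-Kramer correction (the default of
    the underlying studentized-range machinery).  Groups with fewer
    than two observations are skipped and reported in the ``note``
    column of a sentinel row.
    """
    if isinstance(grouping, str):
        grouping = [grouping]
    df = records[[*grouping, response]].dropna().copy()
    labels = df[grouping].astype(str).agg(":".join, axis=1)
    y = df[response].astype(float)
    if transform == "log":
        y = np.log(y)
    counts = labels.value_counts()
    small = counts[counts < 2].index.tolist()
    keep = ~labels.isin(small)
    if labels[keep].nunique() < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")
    res = pairwise_tukeyhsd(y[keep].to_numpy(), labels[keep].to_numpy(), alpha=alpha)
    out = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    out = out.rename(
        columns={"group1": "group_1", "group2": "group_2", "meandiff": "estimate",
                 "p-adj": "p_adj"}
    )
    out["note"] = ""
    for g in small:
        out.loc[len(out)] = {
            "group_1": g, "group_2": "", "estimate": np.nan, "p_adj": np.nan,
            "note": "skipped: fewer than 2 observations",
        }
    return out


def t_test_vs_shedding(freqs, f_shed: float) -> tuple[float, float]:
    """Left-tailed one-sample t-test of tail-beat frequencies vs f_shed.

    Tests whether the mean tail-beat frequency is *below* the vortex
    shedding frequency.  Returns (t, p).
    """
    x = np.asarray(freqs, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance in tail-beat frequencies: t-test undefined")
    res = scipy.stats.ttest_1samp(x, popmean=f_shed, alternative="less")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# full stage
# ---------------------------------------------------------------------------

@dataclass
class TestTable:
    """ANOVA family with FDR adjustment plus post hoc tables."""

    anovas: dict[str, AnovaResult]
    fdr: pd.DataFrame                       # one row per response x term
    adjusted_alpha: float
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)
    family: str = "per_term_across_responses"


DEFAULT_RESPONSES = ("f_Hz", "wavelength_L", "amp_snout_L", "amp_com_L", "amp_tail_L")
LOG_RESPONSES = ("amp_snout_L", "amp_com_L", "amp_tail_L")


def run_stats(
    records: pd.DataFrame,
    responses: tuple[str, ...] = DEFAULT_RESPONSES,
    log_responses: tuple[str, ...] = LOG_RESPONSES,
    factors: tuple[str, str] = ("treatment", "speed"),
    alpha: float = 0.05,
    family: str = "per_term_across_responses",
    posthoc: bool = True,
) -> TestTable:
    """ANOVA per response, FDR across the family, post hoc where significant.

    ``family`` controls which p values form the FDR family:
    ``per_term_across_responses`` adjusts each ANOVA term across the
    responses (one family per term); ``pooled`` adjusts every term of
    every response together.
    """
    anovas = {
        r: two_way_anova(
            records, r, factors, transform="log" if r in log_responses else None
        )
        for r in responses
    }
    a, b = factors
    terms = [a, b, f"{a}:{b}"]
    rows = []
    for r in responses:
        for term in terms:
            F, p = anovas[r].term(term)
            rows.append({"response": r, "term": term, "F": F, "p": p})
    fdr = pd.DataFrame(rows)
    if family == "per_term_across_responses":
        fdr["p_adj"] = np.nan
        for term in terms:
            mask = fdr["term"] == term
            fdr.loc[mask, "p_adj"] = fdr_adjust(fdr.loc[mask, "p"].to_numpy())
        alpha_eff = bh_adjusted_alpha(
            fdr.loc[fdr["term"] == a, "p"].to_numpy(), alpha
        )
    elif family == "pooled":
        fdr["p_adj"] = fdr_adjust(fdr["p"].to_numpy())
        alpha_eff = bh_adjusted_alpha(fdr["p"].to_numpy(), alpha)
    else:
        raise ValueError(f"unknown FDR family {family!r}")
    fdr["significant"] = fdr["p_adj"] < alpha

    tables = TestTable(
        anovas=anovas, fdr=fdr, adjusted_alpha=alpha_eff, family=family
    )
    if posthoc:
        for r in responses:
            sig = fdr[(fdr["response"] == r) & fdr["significant"]]
            if sig.empty:
                continue
            grouping = list(factors) if f"{a}:{b}" in sig["term"].values else [
                t for t in sig["term"] if t in factors
            ]
            if not grouping:
                continue
            tables.posthoc[r] = tukey_hsd(
                records, r, grouping,
                transform="log" if r in log_responses else None, alpha=alpha,
            )
    return tables
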