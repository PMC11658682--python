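"""Umbrella pipeline: run the synthetic study end to end.

Stage dependency order::

    simulate-wake -> wake-metrics -> optimize-spacing
    simulate-swimmer -> kinematics -> stats

Every stage writes plain-text artifacts into the output directory and a
manifest records the package version, seed and config hash, so a run is
reproducible from config plus seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .field import VelocityField, _jsonable
from .geometry import ArrayGeometry
from .kinematics import analyze_landmarks, results_frame
from .landmarks import read_landmarks
from .optimize import make_wake_evaluator, run_sbo
from .stats import run_stats, summary_table, t_test_vs_shedding
from .synthetic.study import StudyDesign, trial_specs
from .synthetic.swimmer import generate_swimmer
from .synthetic.wake import GridSpec, WakeSpec, generate_vortex_street
from .wake_metrics import (
    blockage_corrected_velocity,
    compute_spectrum,
    default_probe,
    periodicity_score,
    predict_shedding_frequency,
    turbulent_kinetic_energy,
    wake_wavelength,
)

log = logging.getLogger("wakekin.pipeline")

STAGES = (
    "simulate-wake",
    "wake-metrics",
    "optimize-spacing",
    "simulate-swimmer",
    "kinematics",
    "stats",
)
_DEPS = {
    "wake-metrics": ["simulate-wake"],
    "optimize-spacing": [],
    "kinematics": ["simulate-swimmer"],
    "stats": ["kinematics"],
}


class MissingArtifactError(RuntimeError):
    pass


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _geometry(config: RunConfig) -> ArrayGeometry:
    g = config.geometry
    return ArrayGeometry(
        D=g.D, lx_over_d=g.lx_over_d, ly_over_d=g.ly_over_d,
        n_streamwise=g.columns, n_cross_stream=g.rows, tank_width_W=g.W,
    )


def _wake_spec(config: RunConfig, mode: str, seed: int) -> WakeSpec:
    uf = max(config.flow.speeds_Uf)
    u = blockage_corrected_velocity(uf, config.geometry.W, config.geometry.D)
    f = predict_shedding_frequency(
        config.flow.strouhal, config.geometry.D, uf, config.geometry.W
    )
    return WakeSpec(
        shedding_frequency=f,
        convection_speed=u,
        circulation=0.02,
        core_radius=0.4 * config.geometry.D,
        mode=mode,
        cross_stream_offset=config.geometry.D,
        noise_sd=0.05 * u,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate_wake(config: RunConfig, out: Path, seed: int, **ctx) -> None:
    geometry = _geometry(config)
    for i, mode in enumerate(("staggered", "symmetric_parallel")):
        spec = _wake_spec(config, mode, seed + i)
        grid = GridSpec.downstream_of(geometry, spec)
        field = generate_vortex_street(
            spec, geometry, grid, duration=16.0 / spec.shedding_frequency
        )
        field.write_csv(out / f"wake_{mode}.csv")


def stage_wake_metrics(config: RunConfig, out: Path, seed: int, **ctx) -> None:
    geometry = _geometry(config)
    report = {}
    for mode in ("staggered", "symmetric_parallel"):
        path = out / f"wake_{mode}.csv"
        if not path.exists():
            raise MissingArtifactError(
                f"{path.name} missing: run the simulate-wake stage first"
            )
        field = VelocityField.read_csv(path)
        probe = (
            config.analysis.probe_x
            if config.analysis.probe_x is not None
            else default_probe(geometry)[0],
            config.analysis.probe_y,
        )
        series = field.probe_series(*probe)
        spec = compute_spectrum(series, field.dt)
        score = periodicity_score(field, probe)
        uf = max(config.flow.speeds_Uf)
        u = blockage_corrected_velocity(uf, config.geometry.W, config.geometry.D)
        report[mode] = {
            "dominant_frequency_hz": spec.dominant_frequency,
            "strouhal": spec.dominant_frequency * config.geometry.D / u,
            "l_kurtosis": score.l_kurtosis if score.defined else None,
            "tke_m2_s2": turbulent_kinetic_energy(field),
            "wavelength_m": wake_wavelength(field, t=field.t[-1]),
            "probe": list(probe),
        }
    with open(out / "wake_metrics.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)


def stage_optimize_spacing(config: RunConfig, out: Path, seed: int, **ctx) -> None:
    bounds = tuple(tuple(b) for b in config.analysis.design_bounds)
    evaluator = make_wake_evaluator(seed=seed)
    probe = default_probe(_geometry(config))
    best, evaluated, _ = run_sbo(
        bounds, config.analysis.n_design_samples, seed,
        evaluator=evaluator, probe=probe,
    )
    pd.DataFrame(
        [
            {"lx_over_d": p.lx_over_d, "ly_over_d": p.ly_over_d,
             "objective": p.objective_value, "failed": p.failed}
            for p in evaluated
        ]
    ).to_csv(out / "design_table.csv", index=False)
    with open(out / "optimum.json", "w") as fh:
        json.dump(
            {"lx_over_d": best.lx_over_d, "ly_over_d": best.ly_over_d,
             "objective": best.objective_value},
            fh, indent=2,
        )


def stage_simulate_swimmer(config: RunConfig, out: Path, seed: int, **ctx) -> None:
    design = ctx.get("study_design") or StudyDesign(
        body_length=config.fish.body_length, frame_rate=config.video.frame_rate
    )
    trials = trial_specs(design, seed)
    index = []
    for i, trial in enumerate(trials):
        table, truth = generate_swimmer(trial["spec"], trial["duration"])
        name = f"landmarks_{i:03d}.csv"
        table.write_csv(out / name)
        index.append(
            {
                "file": name,
                "fish_id": trial["fish_id"],
                "treatment": trial["treatment"],
                "speed": trial["speed"],
                "true_f_hz": truth.tailbeat_frequency,
                "true_wavelength_L": truth.body_wavelength,
            }
        )
    pd.DataFrame(index).to_csv(out / "trials.csv", index=False)


def stage_kinematics(config: RunConfig, out: Path, seed: int, **ctx) -> None:
    trials_path = out / "trials.csv"
    if not trials_path.exists():
        raise MissingArtifactError(
            "trials.csv missing: run the simulate-swimmer stage first"
        )
    trials = pd.read_csv(trials_path)
    frames = []
    qc = {}
    for _, row in trials.iterrows():
        table = read_landmarks(
            out / row["file"],
            frame_rate=config.video.frame_rate,
            scale=config.video.scale,
        )
        results, _, report = analyze_landmarks(
            table,
            com_fraction=config.fish.com_fraction,
            beats_per_sequence=config.analysis.beats_per_sequence,
            min_likelihood=config.analysis.min_likelihood,
            max_gap=config.analysis.max_gap,
            inaccurate_threshold=config.analysis.inaccurate_threshold,
        )
        frames.append(
            results_frame(
                results, fish_id=row["fish_id"], treatment=row["treatment"],
                speed=row["speed"],
            )
        )
        qc[row["file"]] = {
            "overall_bad_fraction": report.overall_bad_fraction,
            "needs_manual_review": report.needs_manual_review,
        }
    pd.concat(frames, ignore_index=True).to_csv(out / "kinematics.csv", index=False)
    with open(out / "kinematics_qc.json", "w") as fh:
        json.dump(qc, fh, indent=2)


def stage_stats(config: RunConfig, out: Path, seed: int, **ctx) -> None:
    kin_path = out / "kinematics.csv"
    if not kin_path.exists():
        raise MissingArtifactError(
            "kinematics.csv missing: run the kinematics stage first"
        )
    records = pd.read_csv(kin_path)
    responses = [c for c in records.columns if c.endswith(("_Hz", "_L"))]
    tables = run_stats(records, responses=tuple(responses))
    tables.fdr.to_csv(out / "anova_fdr.csv", index=False)
    summary_table(records, responses).to_csv(out / "summary_table.csv", index=False)
    extra = {"adjusted_alpha": tables.adjusted_alpha}
    uf = max(config.flow.speeds_Uf)
    f_shed = predict_shedding_frequency(
        config.flow.strouhal, config.geometry.D, uf, config.geometry.W
    )
    top = records[
        (records["speed"] == records["speed"].max())
        & (records["treatment"] != "freestream")
    ]
    if len(top) >= 2 and top["f_Hz"].std(ddof=1) > 0:
        t, p = t_test_vs_shedding(top["f_Hz"].to_numpy(), f_shed)
        extra["t_test_vs_shedding"] = {"f_shed_hz": f_shed, "t": t, "p": p}
    with open(out / "stats_tests.json", "w") as fh:
        json.dump(_jsonable(extra), fh, indent=2)


_STAGE_FUNCS = {
    "simulate-wake": stage_simulate_wake,
    "wake-metrics": stage_wake_metrics,
    "optimize-spacing": stage_optimize_spacing,
    "simulate-swimmer": stage_simulate_swimmer,
    "kinematics": stage_kinematics,
    "stats": stage_stats,
}


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    stages: list[str] | None = None,
    seed: int | None = None,
    study_design: StudyDesign | None = None,
) -> Path:
    """Execute the requested stages in dependency order.

    Returns the artifact directory; a ``manifest.json`` records the
    package version, seed and config hash.  ``study_design`` overrides
    the synthetic study's replication (e.g. for small demonstration
    runs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.analysis.seed if seed is None else seed
    requested = list(STAGES) if stages is None else list(stages)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {list(STAGES)}")
    ordered = [s for s in STAGES if s in requested]
    for stage in ordered:
        log.info("running stage %s", stage)
        _STAGE_FUNCS[stage](config, out, seed, study_design=study_design)
    manifest = {
        "package": "wakekin",
        "version": __version__,
        "seed": int(seed),
        "config_hash": _config_hash(config),
        "stages": ordered,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
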