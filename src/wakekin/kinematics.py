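"""Midline kinematics from landmark exports.

The chain mirrors a standard undulatory-swimming workflow: quality
control of tracked landmarks, midline reconstruction (left/right edge
midpoints, smoothing spline, equal-arc-length resampling), lateral
excursion about the mean swimming axis, tail-beat frequency from
extremum timing, body wavelength from the phase speed of crests
traveling along the midline, and amplitudes at the snout, the center of
mass and the tail tip, grouped into sequences of a fixed number of tail
beats (four by default).

All thresholds are expressed relative to the body length or to the
series' own dispersion, so every output is invariant under global
translation, rotation and uniform scaling of the landmark coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, splev, splprep
from scipy.signal import find_peaks, savgol_filter

from .landmarks import SIDE_FRACTIONS, LandmarkTable


class InsufficientBeatsError(ValueError):
    """Raised when too few tail-beat extrema are present."""


class WavelengthUndeterminedError(ValueError):
    """Raised when no crest travels along the body long enough to track."""


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    bad_fraction: dict[str, float]
    overall_bad_fraction: float
    interpolated: dict[str, int]
    unresolved: dict[str, int]
    needs_manual_review: bool
    body_length_estimate: float


def _polyline_body_length(table: LandmarkTable) -> float:
    """Median snout->midpoints->tail polyline length, in file units."""
    pts = [table.xy("snout")]
    for i in range(1, 7):
        pts.append(0.5 * (table.xy(f"left_{i}") + table.xy(f"right_{i}")))
    pts.append(table.xy("tail_tip"))
    stack = np.stack(pts, axis=1)                  # (frames, 8, 2)
    seg = np.linalg.norm(np.diff(stack, axis=1), axis=2).sum(axis=1)
    seg = seg[np.isfinite(seg)]
    if seg.size == 0:
        raise ValueError("cannot estimate body length: no finite frames")
    return float(np.median(seg))


def _bad_runs(bad: np.ndarray):
    """(start, stop) index pairs of consecutive-True runs."""
    edges = np.flatnonzero(np.diff(np.concatenate([[0], bad.astype(int), [0]])))
    return list(zip(edges[::2], edges[1::2]))


def qc_landmarks(
    table: LandmarkTable,
    min_likelihood: float = 0.9,
    max_gap: int = 5,
    inaccurate_threshold: float = 0.10,
    jump_threshold: float = 0.2,
) -> tuple[LandmarkTable, QCReport]:
    """Flag, interpolate and report unreliable landmark points.

    A point is bad when its likelihood falls below ``min_likelihood`` or
    it jumps more than ``jump_threshold`` body lengths away from *both*
    temporal neighbors (an isolated outlier).  Bad runs of at most
    ``max_gap`` frames bracketed by good frames are linearly
    interpolated; longer runs are left as NaN for downstream frame
    dropping.  If the overall bad fraction exceeds
    ``inaccurate_threshold`` the table is flagged ``needs_manual_review``
    (processing continues; the flag propagates to outputs).
    """
    out = table.copy()
    bl = _polyline_body_length(table)
    parts = sorted({c[1] for c in table.data.columns})
    scorer = table.scorer

    bad_fraction: dict[str, float] = {}
    interpolated: dict[str, int] = {}
    unresolved: dict[str, int] = {}
    n = table.n_frames
    total_bad = 0

    for part in parts:
        xy = table.xy(part)
        lik = table.likelihood(part)
        bad = lik < min_likelihood
        if n >= 3:
            step = np.linalg.norm(np.diff(xy, axis=0), axis=1)
            # isolated outlier: far from both the previous and next frame
            mid = np.minimum(step[:-1], step[1:]) > jump_threshold * bl
            jump_bad = np.concatenate([[False], mid, [False]])
            bad |= jump_bad
        if bad.all():
            raise ValueError(f"all frames bad for body part {part!r}")
        total_bad += int(bad.sum())
        bad_fraction[part] = float(bad.mean())

        x = xy[:, 0].copy()
        y = xy[:, 1].copy()
        x[bad] = np.nan
        y[bad] = np.nan
        n_interp = 0
        n_left = 0
        for start, stop in _bad_runs(bad):
            width = stop - start
            if width <= max_gap and start > 0 and stop < n:
                frac = (np.arange(start, stop) - (start - 1)) / (width + 1)
                x[start:stop] = x[start - 1] + frac * (x[stop] - x[start - 1])
                y[start:stop] = y[start - 1] + frac * (y[stop] - y[start - 1])
                n_interp += width
            else:
                n_left += width
        interpolated[part] = n_interp
        unresolved[part] = n_left
        out.data[(scorer, part, "x")] = x
        out.data[(scorer, part, "y")] = y

    overall = total_bad / (len(parts) * n)
    flagged = overall > inaccurate_threshold
    out.meta["needs_manual_review"] = flagged
    report = QCReport(
        bad_fraction=bad_fraction,
        overall_bad_fraction=overall,
        interpolated=interpolated,
        unresolved=unresolved,
        needs_manual_review=flagged,
        body_length_estimate=bl * table.scale,
    )
    return out, report


# ---------------------------------------------------------------------------
# midline reconstruction
# ---------------------------------------------------------------------------

@dataclass
class MidlineSeries:
    """Per-frame midline resampled to N equal-arc-length points.

    ``points`` has shape (n_frames, n_points, 2), in meters, ordered
    snout (s=0) to tail tip (s=1).
    """

    points: np.ndarray
    frame_indices: np.ndarray
    frame_rate: float
    body_length: float
    com_fraction: float = 0.35
    dropped_frames: list = field(default_factory=list)
    needs_manual_review: bool = False

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.frame_indices / self.frame_rate

    @property
    def duration(self) -> float:
        return float((self.frame_indices[-1] - self.frame_indices[0]) / self.frame_rate)

    @property
    def s(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_points)

    def point_at(self, s: float) -> np.ndarray:
        """(n_frames, 2) trajectory of the midline point at arc fraction s."""
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"arc fraction must be in [0, 1], got {s}")
        grid = self.s
        j = min(int(np.searchsorted(grid, s, side="right")) - 1, self.n_points - 2)
        j = max(j, 0)
        w = (s - grid[j]) / (grid[j + 1] - grid[j])
        return (1 - w) * self.points[:, j, :] + w * self.points[:, j + 1, :]


def reconstruct_midline(
    table: LandmarkTable,
    n_points: int = 20,
    com_fraction: float = 0.35,
    smoothing: float = 0.003,
) -> MidlineSeries:
    """Reconstruct the midline from a QC'd landmark table.

    Per frame the left/right edge points are paired into midpoints, a
    smoothing spline is fit through snout, midpoints and tail tip
    (ordered head to tail), and the curve is resampled to ``n_points``
    at equal arc length.  ``smoothing`` is the assumed landmark residual
    in body lengths (sets the spline's residual budget).  Frames with
    missing points or with a midpoint sequence that is non-monotonic
    along the body axis (crossed left/right pairs) are dropped and
    reported.  The recording's body length is the median per-frame arc
    length.
    """
    scale = table.scale
    snout = table.xy("snout") * scale
    tail = table.xy("tail_tip") * scale
    mids = [
        0.5 * (table.xy(f"left_{i}") + table.xy(f"right_{i}")) * scale
        for i in range(1, 7)
    ]
    raw = np.stack([snout, *mids, tail], axis=1)   # (frames, 8, 2)

    kept, dropped, curves = [], [], []
    for j in range(raw.shape[0]):
        pts = raw[j]
        if not np.all(np.isfinite(pts)):
            dropped.append(j)
            continue
        chord = pts[-1] - pts[0]
        clen = np.linalg.norm(chord)
        if clen == 0:
            dropped.append(j)
            continue
        proj = (pts - pts[0]) @ (chord / clen)
        if np.any(np.diff(proj) <= 0):
            dropped.append(j)                      # crossed left/right pairs
            continue
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        u = np.concatenate([[0.0], np.cumsum(seg)])
        bl_guess = u[-1]
        u /= bl_guess
        s_budget = pts.shape[0] * (smoothing * bl_guess) ** 2
        tck, _ = splprep([pts[:, 0], pts[:, 1]], u=u, s=s_budget, k=3)
        dense_u = np.linspace(0.0, 1.0, 200)
        dx, dy = splev(dense_u, tck)
        dense = np.column_stack([dx, dy])
        seg_d = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg_d)])
        total = arc[-1]
        targets = np.linspace(0.0, total, n_points)
        resampled = np.column_stack(
            [np.interp(targets, arc, dense[:, 0]), np.interp(targets, arc, dense[:, 1])]
        )
        kept.append(j)
        curves.append((resampled, total))

    if not kept:
        raise ValueError("no usable frames after midline reconstruction")
    points = np.stack([c[0] for c in curves])
    body_length = float(np.median([c[1] for c in curves]))
    return MidlineSeries(
        points=points,
        frame_indices=np.asarray(kept),
        frame_rate=table.frame_rate,
        body_length=body_length,
        com_fraction=com_fraction,
        dropped_frames=dropped,
        needs_manual_review=bool(table.meta.get("needs_manual_review", False)),
    )


# ---------------------------------------------------------------------------
# excursion about the mean swimming axis
# ---------------------------------------------------------------------------

def mean_swimming_axis(
    series: MidlineSeries, min_travel: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(origin, axis, normal) of the mean swimming axis.

    The axis is the principal axis of the COM-point trajectory when the
    trajectory extends at least ``min_travel`` body lengths along it;
    for station-holding recordings with negligible COM travel it falls
    back to the time-mean snout-to-tail body axis.  The normal is the
    axis rotated +90 degrees.
    """
    com = series.point_at(series.com_fraction)
    origin = com.mean(axis=0)
    centered = com - origin
    _, sing, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = vt[0]
    extent = np.ptp(centered @ pc1)
    body_vec = (series.points[:, -1, :] - series.points[:, 0, :]).mean(axis=0)
    if extent >= min_travel * series.body_length:
        axis = pc1
        if axis @ body_vec < 0:
            axis = -axis
    else:
        axis = body_vec / np.linalg.norm(body_vec)
    normal = np.array([-axis[1], axis[0]])
    return origin, axis, normal


def lateral_excursion(series: MidlineSeries, s: float) -> np.ndarray:
    """Signed perpendicular displacement (body lengths) of the midline
    point at arc fraction ``s`` from the mean swimming axis."""
    if series.duration < 1.0:
        raise ValueError(
            f"analysis window must span at least 1 s, got {series.duration:.3g} s"
        )
    origin, _, normal = mean_swimming_axis(series)
    traj = series.point_at(s)
    return ((traj - origin) @ normal) / series.body_length


def excursion_profile(series: MidlineSeries) -> np.ndarray:
    """(n_frames, n_points) signed excursion of every midline point."""
    origin, _, normal = mean_swimming_axis(series)
    return ((series.points - origin) @ normal) / series.body_length


# ---------------------------------------------------------------------------
# tail-beat timing
# ---------------------------------------------------------------------------

@dataclass
class TailbeatResult:
    frequency: float                 # Hz
    extremum_times: np.ndarray       # s, alternating maxima/minima
    extremum_kinds: np.ndarray       # +1 for maxima, -1 for minima
    extremum_values: np.ndarray


def _find_extrema(x: np.ndarray, prominence_frac: float = 0.25):
    """Alternating extrema (indices, kinds, values) of a 1D series.

    Peaks and troughs are located with a prominence threshold of
    ``prominence_frac`` times the series' interquartile range; where two
    same-kind extrema are adjacent the more extreme one is kept.
    """
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr <= 0:
        return np.array([], int), np.array([], int), np.array([])
    prom = prominence_frac * iqr
    peaks, _ = find_peaks(x, prominence=prom)
    troughs, _ = find_peaks(-x, prominence=prom)
    idx = np.concatenate([peaks, troughs])
    kind = np.concatenate([np.ones(peaks.size, int), -np.ones(troughs.size, int)])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]
    keep_idx, keep_kind = [], []
    for i, k in zip(idx, kind):
        if keep_kind and keep_kind[-1] == k:
            if k * x[i] > k * x[keep_idx[-1]]:
                keep_idx[-1] = i
        else:
            keep_idx.append(int(i))
            keep_kind.append(int(k))
    keep_idx = np.asarray(keep_idx, int)
    return keep_idx, np.asarray(keep_kind, int), x[keep_idx]


def _refine_extrema(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-sample extremum positions by local parabolic interpolation."""
    pos = idx.astype(float)
    for j, i in enumerate(idx):
        if 0 < i < x.size - 1:
            denom = x[i - 1] - 2 * x[i] + x[i + 1]
            if denom != 0:
                pos[j] = i + 0.5 * (x[i - 1] - x[i + 1]) / denom
    return pos


def tailbeat_frequency(
    excursion: np.ndarray, frame_rate: float, prominence_frac: float = 0.25
) -> TailbeatResult:
    """Tail-beat frequency from extremum timing.

    The full period is twice the mean interval between successive
    opposite-sign extrema ("time between maxima and minima" being half a
    period); the frequency is its inverse.

    Raises
    ------
    InsufficientBeatsError
        With fewer than four alternating extrema.
    """
    x = np.asarray(excursion, dtype=float)
    idx, kind, vals = _find_extrema(x, prominence_frac)
    if idx.size < 4:
        raise InsufficientBeatsError(
            f"insufficient beats: found {idx.size} extrema, need >= 4"
        )
    times = _refine_extrema(x, idx) / frame_rate
    half_periods = np.diff(times)
    period = 2.0 * float(np.mean(half_periods))
    return TailbeatResult(
        frequency=1.0 / period,
        extremum_times=times,
        extremum_kinds=kind,
        extremum_values=vals,
    )


def segment_tailbeats(
    extremum_times: np.ndarray, beats_per_sequence: int = 4
) -> list[tuple[float, float]]:
    """Group extrema into consecutive windows of whole tail beats.

    One beat spans two successive extremum intervals; windows hold
    exactly ``beats_per_sequence`` full beats and trailing partial beats
    are dropped.
    """
    times = np.asarray(extremum_times, dtype=float)
    n_beats = (times.size - 1) // 2
    if n_beats < beats_per_sequence:
        raise InsufficientBeatsError(
            f"insufficient beats: {n_beats} complete, need {beats_per_sequence}"
        )
    step = 2 * beats_per_sequence
    n_windows = n_beats // beats_per_sequence
    return [
        (float(times[step * i]), float(times[step * i + step]))
        for i in range(n_windows)
    ]


# ---------------------------------------------------------------------------
# amplitudes and wavelength
# ---------------------------------------------------------------------------

def _window_amplitude(
    exc: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float],
    prominence_frac: float = 0.25,
) -> float:
    """Half the mean peak-to-trough excursion within a window.

    Falls back to half the window's range when no extrema are detected
    (e.g. a straight steady swimmer).
    """
    mask = (times >= window[0] - 1e-12) & (times <= window[1] + 1e-12)
    x = exc[mask]
    if x.size < 3:
        raise ValueError("window contains too few samples")
    idx, kind, vals = _find_extrema(x, prominence_frac)
    if (kind == 1).any() and (kind == -1).any():
        return 0.5 * float(vals[kind == 1].mean() - vals[kind == -1].mean())
    return 0.5 * float(x.max() - x.min())


def body_wavelength(
    series: MidlineSeries,
    f: float,
    window: tuple[float, float] | None = None,
    n_fine: int = 200,
    min_travel: float = 0.1,
) -> float:
    """Body wavelength (in L) from crest phase speed along the midline.

    Local excursion maxima along the body ("crests") are located on a
    spline-refined profile each frame, linked across frames into tracks,
    and the phase speed is the mean least-squares slope of crest
    arc-length position versus time over tracks that persist at least
    half a tail-beat period and travel at least ``min_travel`` body
    lengths (ruling out standing-wave deformation).  The wavelength is
    the phase speed divided by ``f``.
    """
    if f <= 0:
        raise ValueError("tail-beat frequency must be positive")
    profile = excursion_profile(series)
    times = series.times
    if window is not None:
        mask = (times >= window[0] - 1e-12) & (times <= window[1] + 1e-12)
        profile, times = profile[mask], times[mask]
    if profile.shape[0] < 4:
        raise WavelengthUndeterminedError("wavelength undetermined: window too short")

    s_grid = series.s
    s_fine = np.linspace(0.0, 1.0, n_fine)
    spread = float(profile.max() - profile.min())
    if spread <= 0:
        raise WavelengthUndeterminedError("wavelength undetermined: flat profile")
    prom = 0.05 * spread

    dt = 1.0 / series.frame_rate
    max_jump = max(0.06, 2.0 * f * dt)
    tracks: list[list[tuple[float, float]]] = []
    active: list[list[tuple[float, float]]] = []
    for j in range(profile.shape[0]):
        spline = CubicSpline(s_grid, profile[j])
        fine = spline(s_fine)
        pk, _ = find_peaks(fine, prominence=prom)
        crest_s = s_fine[pk]
        crest_s = crest_s[(crest_s > 0.02) & (crest_s < 0.98)]
        used = np.zeros(crest_s.size, bool)
        still_active = []
        for tr in active:
            s_last = tr[-1][1]
            cand = np.flatnonzero(~used)
            if cand.size:
                d = np.abs(crest_s[cand] - s_last)
                b = cand[np.argmin(d)]
                if d.min() <= max_jump:
                    tr.append((times[j], crest_s[b]))
                    used[b] = True
                    still_active.append(tr)
                    continue
            tracks.append(tr)
        active = still_active
        for b in np.flatnonzero(~used):
            active.append([(times[j], crest_s[b])])
    tracks.extend(active)

    speeds, weights = [], []
    for tr in tracks:
        if len(tr) < 3:
            continue
        tt = np.array([p[0] for p in tr])
        ss = np.array([p[1] for p in tr])
        if tt[-1] - tt[0] < 0.5 / f:
            continue
        if ss[-1] - ss[0] < min_travel:
            continue
        slope = np.polyfit(tt, ss, 1)[0]
        if slope <= 0:
            continue
        speeds.append(slope)
        weights.append(len(tr))
    if not speeds:
        raise WavelengthUndeterminedError(
            "wavelength undetermined: no trackable crest traveled for half a period"
        )
    phase_speed = float(np.average(speeds, weights=weights))   # L per second
    return phase_speed / f


# ---------------------------------------------------------------------------
# per-sequence results
# ---------------------------------------------------------------------------

@dataclass
class KinematicsResult:
    sequence: int
    tailbeat_frequency: float        # Hz
    body_wavelength: float | None    # body lengths (None if undetermined)
    amplitude_snout: float           # body lengths
    amplitude_com: float
    amplitude_tail: float
    n_beats: int
    window: tuple[float, float]
    qc_flag: str = "ok"


def _smooth(x: np.ndarray, frame_rate: float, f: float) -> np.ndarray:
    """Light Savitzky-Golay smoothing with a quarter-period window."""
    w = int(round(frame_rate / (4.0 * f)))
    w = max(w | 1, 5)                 # odd, at least 5
    if w >= x.size:
        return x
    return savgol_filter(x, w, polyorder=3)


def analyze_landmarks(
    table: LandmarkTable,
    *,
    com_fraction: float = 0.35,
    n_points: int = 20,
    beats_per_sequence: int = 4,
    min_likelihood: float = 0.9,
    max_gap: int = 5,
    inaccurate_threshold: float = 0.10,
    smoothing: float = 0.003,
) -> tuple[list[KinematicsResult], MidlineSeries, QCReport]:
    """Full chain: QC -> midline -> per-sequence kinematics."""
    clean, report = qc_landmarks(
        table,
        min_likelihood=min_likelihood,
        max_gap=max_gap,
        inaccurate_threshold=inaccurate_threshold,
    )
    series = reconstruct_midline(
        clean, n_points=n_points, com_fraction=com_fraction, smoothing=smoothing
    )
    times = series.times
    exc_tail = lateral_excursion(series, 1.0)

    first_pass = tailbeat_frequency(exc_tail, series.frame_rate)
    smoothed_tail = _smooth(exc_tail, series.frame_rate, first_pass.frequency)
    beat = tailbeat_frequency(smoothed_tail, series.frame_rate)
    windows = segment_tailbeats(beat.extremum_times, beats_per_sequence)

    exc = {
        0.0: _smooth(lateral_excursion(series, 0.0), series.frame_rate, beat.frequency),
        com_fraction: _smooth(
            lateral_excursion(series, com_fraction), series.frame_rate, beat.frequency
        ),
        1.0: smoothed_tail,
    }
    flag = "needs_manual_review" if series.needs_manual_review else "ok"

    results = []
    for i, win in enumerate(windows, start=1):
        in_win = (beat.extremum_times >= win[0] - 1e-12) & (
            beat.extremum_times <= win[1] + 1e-12
        )
        t_win = beat.extremum_times[in_win]
        f_win = 1.0 / (2.0 * float(np.mean(np.diff(t_win))))
        try:
            lam = body_wavelength(series, f_win, window=win)
        except WavelengthUndeterminedError:
            lam = None
        results.append(
            KinematicsResult(
                sequence=i,
                tailbeat_frequency=f_win,
                body_wavelength=lam,
                amplitude_snout=_window_amplitude(exc[0.0], times, win),
                amplitude_com=_window_amplitude(exc[com_fraction], times, win),
                amplitude_tail=_window_amplitude(exc[1.0], times, win),
                n_beats=beats_per_sequence,
                window=win,
                qc_flag=flag,
            )
        )
    return results, series, report


def results_frame(
    results: list[KinematicsResult],
    fish_id: str = "fish_1",
    treatment: str = "freestream",
    speed: float = 0.0,
) -> pd.DataFrame:
    """Tidy per-sequence table (one row per four-beat sequence)."""
    return pd.DataFrame(
        [
            {
                "fish_id": fish_id,
                "treatment": treatment,
                "speed": speed,
                "sequence": r.sequence,
                "f_Hz": r.tailbeat_frequency,
                "wavelength_L": np.nan if r.body_wavelength is None else r.body_wavelength,
                "amp_snout_L": r.amplitude_snout,
                "amp_com_L": r.amplitude_com,
                "amp_tail_L": r.amplitude_tail,
                "qc_flag": r.qc_flag,
            }
            for r in results
        ]
    )
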