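"""Synthetic steadily swimming fish as a traveling body wave.

The midline is a head-to-tail traveling wave

    y(x, t) = L * A(x/lx) * sin(2*pi*(f*t - x/(lambda*L)))

about a straight mean path at a given heading, where ``A`` is the
amplitude envelope in body lengths (default linear, growing from snout
to tail), ``f`` the tail-beat frequency and ``lambda`` the body
wavelength in body lengths.  Because the body is inextensible, the
streamwise extent ``lx`` is re-solved every frame so the arc length of
the midline stays equal to the body length within 0.1%.  The whole body
may additionally translate laterally (center-of-mass recoil) at the
tail-beat frequency.

Fourteen landmarks are emitted in the pose-export layout: the snout and
tail tip are the midline endpoints; six left/right edge points are
offset from the midline along the local normal by a fixed fusiform
half-width profile (max half-width 0.12 L at 0.25 L from the snout,
tapering to zero at the tail).  Optional Gaussian jitter and random
dropout emulate tracking noise; dropped points get a likelihood drawn
below 0.1 and a gross position error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from ..landmarks import BODY_PARTS, SIDE_FRACTIONS, LandmarkTable

#: tabulated fusiform half-width profile (arc fraction -> half width in L)
_HALF_WIDTH_S = np.array([0.0, 0.10, 0.25, 0.50, 0.75, 0.90, 1.0])
_HALF_WIDTH_W = np.array([0.01, 0.09, 0.12, 0.09, 0.05, 0.02, 0.0])
half_width_profile = PchipInterpolator(_HALF_WIDTH_S, _HALF_WIDTH_W)


def linear_envelope(snout: float, tail: float) -> Callable[[np.ndarray], np.ndarray]:
    """Amplitude envelope growing linearly from snout to tail (in L)."""

    def env(s):
        return snout + (tail - snout) * np.asarray(s, dtype=float)

    return env


@dataclass(frozen=True)
class SwimmerSpec:
    """Ground-truth parameters of the synthetic swimmer."""

    body_length: float = 0.074            # m
    tailbeat_frequency: float = 3.0       # Hz
    body_wavelength: float = 1.1          # body lengths
    amplitude_snout: float = 0.02         # body lengths
    amplitude_tail: float = 0.15          # body lengths
    amplitude_envelope: Callable | None = None   # overrides the linear default
    com_translation_amplitude: float = 0.0       # body lengths
    com_fraction: float = 0.35            # arc fraction of the center of mass
    heading: float = 0.0                  # radians
    frame_rate: float = 100.0             # Hz
    landmark_noise_sd: float = 0.0        # body lengths
    dropout_rate: float = 0.0             # fraction of points
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")
        if self.tailbeat_frequency < 0:
            raise ValueError("tailbeat_frequency must be non-negative")
        if self.body_wavelength <= 0:
            raise ValueError("body_wavelength must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not 0.0 < self.com_fraction < 1.0:
            raise ValueError("com_fraction must be in (0, 1)")

    def envelope(self) -> Callable[[np.ndarray], np.ndarray]:
        if self.amplitude_envelope is not None:
            return self.amplitude_envelope
        return linear_envelope(self.amplitude_snout, self.amplitude_tail)


@dataclass
class SwimmerTruth:
    """Ground truth recorded alongside a generated landmark table."""

    tailbeat_frequency: float             # Hz
    body_wavelength: float                # body lengths
    amplitude_snout: float                # body lengths
    amplitude_com: float                  # body lengths
    amplitude_tail: float                 # body lengths
    com_fraction: float
    body_length: float                    # m
    heading: float
    midline: np.ndarray = field(repr=False, default=None)
    midline_s: np.ndarray = field(repr=False, default=None)


def _true_amplitude(spec: SwimmerSpec, s: float) -> float:
    """Lateral amplitude (L) at arc fraction s: body wave plus COM recoil,
    two sinusoids at the same frequency combined with their phase lag."""
    a = float(spec.envelope()(s))
    c = spec.com_translation_amplitude
    phase = 2.0 * np.pi * s / spec.body_wavelength
    return float(np.sqrt(a * a + c * c + 2.0 * a * c * np.cos(phase)))


def generate_swimmer(
    spec: SwimmerSpec,
    duration: float,
    *,
    n_midline_truth: int = 20,
    n_dense: int = 400,
) -> tuple[LandmarkTable, SwimmerTruth]:
    """Generate a landmark table and its ground-truth record.

    Raises
    ------
    ValueError
        If the amplitude envelope exceeds 0.5 body lengths anywhere
        (self-intersecting outline) or the duration covers fewer than
        four tail-beat periods at a nonzero frequency.
    """
    L = spec.body_length
    f = spec.tailbeat_frequency
    env = spec.envelope()
    s_dense = np.linspace(0.0, 1.0, n_dense)
    if np.max(env(s_dense)) > 0.5:
        raise ValueError("amplitude envelope exceeds 0.5 body lengths; "
                         "outline would self-intersect")
    if np.min(env(s_dense)) < 0:
        raise ValueError("amplitude envelope must be non-negative")
    if f > 0 and duration < 4.0 / f:
        raise ValueError(
            f"duration {duration} s covers fewer than 4 tail-beat periods"
        )

    n_frames = max(int(round(duration * spec.frame_rate)), 1)
    times = np.arange(n_frames) / spec.frame_rate
    rng = np.random.default_rng(spec.seed)

    lam = spec.body_wavelength * L           # wavelength, m
    rot = np.array(
        [[np.cos(spec.heading), -np.sin(spec.heading)],
         [np.sin(spec.heading), np.cos(spec.heading)]]
    )
    s_truth = np.linspace(0.0, 1.0, n_midline_truth)
    s_marks = np.concatenate([[0.0], SIDE_FRACTIONS, [1.0]])
    widths = half_width_profile(SIDE_FRACTIONS) * L

    truth_midline = np.empty((n_frames, n_midline_truth, 2))
    positions = {p: np.empty((n_frames, 2)) for p in BODY_PARTS}
    likelihoods = {p: np.ones(n_frames) for p in BODY_PARTS}

    for j, t in enumerate(times):
        def lateral(x, lx):
            return L * env(x / lx) * np.sin(2.0 * np.pi * (f * t - x / lam))

        def arclen_err(lx):
            xs = lx * s_dense
            ys = lateral(xs, lx)
            return float(np.hypot(np.diff(xs), np.diff(ys)).sum()) - L

        if arclen_err(L) <= 1e-9 * L:       # straight body (zero envelope)
            lx = L
        else:
            lx = brentq(arclen_err, 0.2 * L, L, xtol=1e-9 * L)
        xs = lx * s_dense
        ys = lateral(xs, lx)
        seg = np.hypot(np.diff(xs), np.diff(ys))
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        arc /= arc[-1]

        # lateral COM recoil translates the whole body
        y_off = L * spec.com_translation_amplitude * np.sin(2.0 * np.pi * f * t)

        def at(s_values):
            px = np.interp(s_values, arc, xs)
            py = np.interp(s_values, arc, ys) + y_off
            return np.column_stack([px, py]) @ rot.T

        truth_midline[j] = at(s_truth)
        pts = at(s_marks)
        # unit tangents along the midline at the side-point fractions
        eps = 1.0 / n_dense
        ahead = at(np.clip(s_marks[1:-1] + eps, 0, 1))
        behind = at(np.clip(s_marks[1:-1] - eps, 0, 1))
        tang = ahead - behind
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])

        positions["snout"][j] = pts[0]
        positions["tail_tip"][j] = pts[-1]
        for i in range(6):
            positions[f"left_{i + 1}"][j] = pts[i + 1] + widths[i] * normal[i]
            positions[f"right_{i + 1}"][j] = pts[i + 1] - widths[i] * normal[i]

    # tracking jitter and dropout, all drawn from the one seed
    for part in BODY_PARTS:
        if spec.landmark_noise_sd > 0:
            positions[part] += rng.normal(
                0.0, spec.landmark_noise_sd * L, (n_frames, 2)
            )
        if spec.dropout_rate > 0:
            drop = rng.random(n_frames) < spec.dropout_rate
            likelihoods[part][drop] = rng.uniform(0.0, 0.1, int(drop.sum()))
            positions[part][drop] += rng.uniform(
                -0.3 * L, 0.3 * L, (int(drop.sum()), 2)
            )

    table = LandmarkTable.from_arrays(
        positions,
        likelihoods,
        frame_rate=spec.frame_rate,
        scale=1.0,
        meta={"generator": "wakekin.synthetic.swimmer", "seed": spec.seed},
    )
    truth = SwimmerTruth(
        tailbeat_frequency=f,
        body_wavelength=spec.body_wavelength,
        amplitude_snout=_true_amplitude(spec, 0.0),
        amplitude_com=_true_amplitude(spec, spec.com_fraction),
        amplitude_tail=_true_amplitude(spec, 1.0),
        com_fraction=spec.com_fraction,
        body_length=L,
        heading=spec.heading,
        midline=truth_midline,
        midline_s=s_truth,
    )
    return table, truth
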