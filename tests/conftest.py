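"""Shared fixtures: small geometries, wakes and hand-built landmark tables."""

from __future__ import annotations

import numpy as np
import pytest

from wakekin import ArrayGeometry, GridSpec, WakeSpec, generate_vortex_street
from wakekin.landmarks import BODY_PARTS, SIDE_FRACTIONS, LandmarkTable
from wakekin.synthetic.swimmer import half_width_profile


@pytest.fixture
def geometry() -> ArrayGeometry:
    return ArrayGeometry(D=0.019, lx_over_d=1.9, ly_over_d=3.0)


def make_street(
    geometry: ArrayGeometry,
    mode: str = "staggered",
    noise_sd: float = 0.0,
    seed: int = 0,
    duration: float = 1.6,
    **overrides,
):
    spec = WakeSpec(
        shedding_frequency=10.0,
        convection_speed=0.5,
        circulation=overrides.pop("circulation", 0.02),
        core_radius=0.008,
        mode=mode,
        noise_sd=noise_sd,
        seed=seed,
        **overrides,
    )
    grid = GridSpec.downstream_of(geometry, spec)
    return generate_vortex_street(spec, geometry, grid, duration=duration), spec


def table_from_midline(midline_fn, n_frames=220, frame_rate=100.0, L=0.074):
    """Build a landmark table from an analytic midline.

    ``midline_fn(s, t)`` returns (len(s), 2) midline points in meters
    for arc fractions ``s`` at time ``t``.  Edges are offset along the
    local normal by the fusiform half-width profile, so the left/right
    midpoints recover the midline exactly.
    """
    times = np.arange(n_frames) / frame_rate
    s_marks = np.concatenate([[0.0], SIDE_FRACTIONS, [1.0]])
    widths = half_width_profile(SIDE_FRACTIONS) * L
    positions = {p: np.empty((n_frames, 2)) for p in BODY_PARTS}
    likelihoods = {p: np.ones(n_frames) for p in BODY_PARTS}
    eps = 1e-4
    for j, t in enumerate(times):
        pts = midline_fn(s_marks, t)
        ahead = midline_fn(np.clip(s_marks[1:-1] + eps, 0, 1), t)
        behind = midline_fn(np.clip(s_marks[1:-1] - eps, 0, 1), t)
        tang = ahead - behind
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])
        positions["snout"][j] = pts[0]
        positions["tail_tip"][j] = pts[-1]
        for i in range(6):
            positions[f"left_{i + 1}"][j] = pts[i + 1] + widths[i] * normal[i]
            positions[f"right_{i + 1}"][j] = pts[i + 1] - widths[i] * normal[i]
    return LandmarkTable.from_arrays(positions, likelihoods, frame_rate=frame_rate)


def straight_fish_midline(L=0.074, offset_fn=None):
    """Rigid straight fish along +x whose whole body may translate.

    ``offset_fn(t)`` returns an (2,) displacement added to every point.
    """

    def fn(s, t):
        base = np.column_stack([np.asarray(s) * L, np.zeros(np.size(s))])
        if offset_fn is not None:
            base = base + np.asarray(offset_fn(t))
        return base

    return fn
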