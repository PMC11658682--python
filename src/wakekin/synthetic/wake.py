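"""Kinematic vortex-street generator.

A wake is modeled as a uniform convection flow plus a train of finite-core
(Lamb-Oseen-profile) vortices released at the shedding frequency on a
seeding line just downstream of the cylinder array and advected at the
convection speed.  Two release patterns are supported:

* ``staggered`` - successive vortices alternate sign and cross-stream
  side, the classic alternating (Karman) street;
* ``symmetric_parallel`` - mirror-image vortex pairs are released
  simultaneously on both sides, a symmetric parallel street.

The generator is a kinematic stand-in whose job is controllable spectral
structure, not fluid-dynamic fidelity: there is no solver, no boundary
layer, no turbulence model.  Circulation may decay with downstream
distance (e-folding ``decay_length``) and i.i.d. Gaussian noise may be
added per sample.  Vortices with negative release times populate the
grid at t=0, so the field is statistically stationary from the first
sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from ..field import VelocityField
from ..geometry import ArrayGeometry

MODES = ("staggered", "symmetric_parallel")


@dataclass(frozen=True)
class WakeSpec:
    """Parameters of one synthetic vortex street.

    ``streamwise_spacing`` is the same-sign vortex-to-vortex distance and
    must equal ``convection_speed / shedding_frequency``; pass ``None``
    to derive it.
    """

    shedding_frequency: float            # Hz
    convection_speed: float              # m/s
    circulation: float                   # m^2/s per vortex
    core_radius: float                   # m
    mode: str = "staggered"
    cross_stream_offset: float = 0.02    # m, center-to-center across the street
    streamwise_spacing: float | None = None
    decay_length: float = math.inf       # m, e-folding of circulation downstream
    noise_sd: float = 0.0                # m/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shedding_frequency <= 0:
            raise ValueError("shedding_frequency must be positive")
        if self.convection_speed <= 0:
            raise ValueError("convection_speed must be positive")
        if self.core_radius <= 0:
            raise ValueError("core_radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive (use inf to disable)")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        natural = self.convection_speed / self.shedding_frequency
        if self.streamwise_spacing is None:
            object.__setattr__(self, "streamwise_spacing", natural)
        elif not math.isclose(self.streamwise_spacing, natural, rel_tol=1e-9):
            raise ValueError(
                "streamwise_spacing must equal convection_speed/shedding_frequency "
                f"({natural:g}), got {self.streamwise_spacing:g}"
            )


@dataclass(frozen=True)
class GridSpec:
    """Uniform sampling lattice for the generated field."""

    x_min: float
    x_max: float
    nx: int
    y_min: float
    y_max: float
    ny: int
    dt: float

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("grid extents must be non-degenerate")
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2 nodes per axis")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @classmethod
    def downstream_of(
        cls,
        geometry: ArrayGeometry,
        spec: WakeSpec,
        *,
        x_extent: float | None = None,
        nx: int = 64,
        ny: int = 33,
        samples_per_period: int = 24,
    ) -> "GridSpec":
        """A convenient grid covering the near wake of the array.

        Spans from the seeding line to ``x_extent`` downstream (default
        eight streamwise vortex spacings) and +/- half the array height
        cross-stream, sampled at ``samples_per_period`` times the
        shedding frequency.
        """
        x0 = seeding_line(geometry)
        if x_extent is None:
            x_extent = 8.0 * spec.streamwise_spacing
        half_h = 0.5 * geometry.cross_stream_pitch * max(geometry.n_cross_stream - 1, 1)
        half_h = max(half_h, 2.0 * spec.cross_stream_offset)
        return cls(
            x_min=x0,
            x_max=x0 + x_extent,
            nx=nx,
            y_min=-half_h,
            y_max=half_h,
            ny=ny,
            dt=1.0 / (samples_per_period * spec.shedding_frequency),
        )


def seeding_line(geometry: ArrayGeometry) -> float:
    """Streamwise position where vortices enter, one diameter past the
    most-downstream cylinder column (the origin)."""
    return geometry.D


def generate_vortex_street(
    spec: WakeSpec,
    geometry: ArrayGeometry,
    grid: GridSpec,
    duration: float,
    *,
    record_tracks: bool = False,
) -> VelocityField:
    """Synthesize a vortex-street velocity field on the given lattice.

    Raises
    ------
    ValueError
        If ``duration`` is shorter than two shedding periods (a spectral
        estimate would be impossible) or the grid extends upstream of
        the vortex seeding line.
    """
    f = spec.shedding_frequency
    if duration < 2.0 / f:
        raise ValueError(
            f"duration {duration} s is shorter than 2 shedding periods "
            f"({2.0 / f:.4g} s); spectral estimate impossible"
        )
    x_seed = seeding_line(geometry)
    if grid.x_min < x_seed - 1e-12:
        raise ValueError(
            f"grid starts at x={grid.x_min} upstream of the vortex seeding "
            f"line x={x_seed}"
        )

    x = np.linspace(grid.x_min, grid.x_max, grid.nx)
    y = np.linspace(grid.y_min, grid.y_max, grid.ny)
    nt = max(int(round(duration / grid.dt)), 2)
    t = np.arange(nt) * grid.dt

    u_x = np.full((nt, grid.ny, grid.nx), spec.convection_speed)
    u_y = np.zeros_like(u_x)

    tracks: list[list[tuple[float, float]]] | None = (
        [[] for _ in range(nt)] if record_tracks else None
    )
    if spec.circulation != 0.0:
        _add_vortices(spec, x_seed, x, y, t, u_x, u_y, tracks)

    if spec.noise_sd > 0.0:
        rng = np.random.default_rng(spec.seed)
        u_x += rng.normal(0.0, spec.noise_sd, u_x.shape)
        u_y += rng.normal(0.0, spec.noise_sd, u_y.shape)

    provenance = {
        "generator": "wakekin.synthetic.wake",
        "spec": {k: (None if v is math.inf else v) for k, v in asdict(spec).items()},
        "geometry": asdict(geometry),
        "ground_truth": {
            "shedding_frequency_hz": f,
            "wake_wavelength_m": spec.streamwise_spacing,
            "convection_speed_m_s": spec.convection_speed,
        },
        "seed": spec.seed,
    }
    if tracks is not None:
        provenance["vortex_tracks"] = tracks
    return VelocityField(x=x, y=y, t=t, u_x=u_x, u_y=u_y, provenance=provenance)


def _add_vortices(spec, x_seed, x, y, t, u_x, u_y, tracks=None):
    """Superpose the induced velocity of every vortex active on the grid."""
    f = spec.shedding_frequency
    uc = spec.convection_speed
    a = spec.streamwise_spacing
    # one release per half period in staggered mode (alternating sides, so
    # same-sign vortices sit one spacing a = Uc/f apart); one mirror pair
    # per period in symmetric mode
    release_dt = 0.5 / f if spec.mode == "staggered" else 1.0 / f
    # retain vortices until 2 spacings past the grid so deletion is invisible
    x_kill = x.max() + 2.0 * a
    # release index range covering every vortex ever on-grid during [0, T]
    k_min = int(math.floor(-(x_kill - x_seed) / uc / release_dt)) - 1
    k_max = int(math.ceil(t[-1] / release_dt)) + 1

    yy, xx = np.meshgrid(y, x, indexing="ij")
    half = 0.5 * spec.cross_stream_offset
    rc2 = spec.core_radius**2

    for k in range(k_min, k_max + 1):
        t_release = k * release_dt
        # contiguous time-slice where vortex k lies within [x_seed, x_kill]
        lo = np.searchsorted(t, t_release)
        hi = np.searchsorted(t, t_release + (x_kill - x_seed) / uc, side="right")
        if hi <= lo:
            continue
        xc = x_seed + uc * (t[lo:hi] - t_release)       # (m,)
        if spec.mode == "staggered":
            sign = 1.0 if k % 2 == 0 else -1.0
            members = [(sign * spec.circulation, sign * half)]
        else:  # symmetric_parallel: mirror-image pair released together
            members = [(spec.circulation, half), (-spec.circulation, -half)]
        if tracks is not None:
            for m, xc_m in enumerate(xc):
                for _, yc in members:
                    tracks[lo + m].append((float(xc_m), float(yc)))
        for gamma0, yc in members:
            gamma = gamma0
            if math.isfinite(spec.decay_length):
                gamma = gamma0 * np.exp(-(xc - x_seed) / spec.decay_length)
                gamma = gamma[:, None, None]
            dx = xx[None, :, :] - xc[:, None, None]      # (m, ny, nx)
            dy = yy[None, :, :] - yc
            r2 = dx**2 + dy**2
            # Lamb-Oseen swirl: u_theta = G/(2 pi r) (1 - exp(-r^2/rc^2));
            # the limit at r=0 is 0, guarded by the tiny floor
            factor = (gamma / (2.0 * np.pi)) * (1.0 - np.exp(-r2 / rc2)) / np.maximum(
                r2, 1e-300
            )
            u_x[lo:hi] += -dy * factor
            u_y[lo:hi] += dx * factor
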