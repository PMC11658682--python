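"""Cylinder-array geometry and bulk flow conditions.

Coordinate convention used throughout the package: x positive downstream,
y positive to the left of the flow, origin at the center of the
most-downstream cylinder column.  All internal units are SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Kinematic viscosity of water at 15 degC, m^2/s.
NU_WATER_15C = 1.139e-6


@dataclass(frozen=True)
class ArrayGeometry:
    """A rectangular array of equal-diameter cylinders in a tank.

    Parameters
    ----------
    D : float
        Cylinder diameter in meters.
    lx_over_d, ly_over_d : float
        Gap-to-diameter spacing ratios in the streamwise (Lx/D) and
        cross-stream (Ly/D) directions.
    n_streamwise, n_cross_stream : int
        Number of cylinder columns (streamwise) and rows (cross-stream).
    tank_width_W : float
        Tank width in meters; used for the solid-blockage velocity
        correction.
    """

    D: float
    lx_over_d: float
    ly_over_d: float
    n_streamwise: int = 5
    n_cross_stream: int = 3
    tank_width_W: float = 0.25

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"cylinder diameter must be positive, got {self.D}")
        if self.tank_width_W <= self.D:
            raise ValueError(
                f"tank width W={self.tank_width_W} must exceed cylinder diameter D={self.D}"
            )
        if self.lx_over_d <= 0 or self.ly_over_d <= 0:
            raise ValueError("spacing ratios must be positive")
        if self.n_streamwise < 1 or self.n_cross_stream < 1:
            raise ValueError("array must contain at least one cylinder")

    @property
    def streamwise_pitch(self) -> float:
        """Center-to-center streamwise spacing (gap + diameter), m."""
        return self.D * (1.0 + self.lx_over_d)

    @property
    def cross_stream_pitch(self) -> float:
        """Center-to-center cross-stream spacing (gap + diameter), m."""
        return self.D * (1.0 + self.ly_over_d)


@dataclass
class FlowConditions:
    """Bulk flow descriptors for one treatment level."""

    nominal_speed_Uf: float
    corrected_speed_U: float | None = None
    inlet_speed_Uinf: float | None = None
    kinematic_viscosity: float = NU_WATER_15C
    strouhal_St: float | None = None
    shedding_frequency_f: float | None = None
    reynolds_Re: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("nominal_speed_Uf", "corrected_speed_U", "inlet_speed_Uinf"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
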