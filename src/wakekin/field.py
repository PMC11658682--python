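"""Gridded 2D time-resolved velocity fields.

A :class:`VelocityField` holds the two in-plane velocity components on a
uniform (time, y, x) lattice.  It is the substrate for every wake metric
and is exchanged on disk as a long-format CSV (columns ``t,x,y,ux,uy``,
SI units) with a sidecar JSON provenance record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class VelocityField:
    """Velocity components on a uniform space-time lattice.

    Attributes
    ----------
    x, y : ndarray
        Ascending, uniformly spaced grid coordinates (m).
    t : ndarray
        Ascending, uniformly spaced sample times (s).
    u_x, u_y : ndarray
        Velocity components (m/s), shape ``(len(t), len(y), len(x))``.
    provenance : dict
        Free-form record of how the field was produced (generator
        parameters, seed, ground truth).
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    u_x: np.ndarray
    u_y: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        shape = (self.t.size, self.y.size, self.x.size)
        if self.u_x.shape != shape or self.u_y.shape != shape:
            raise ValueError(
                f"velocity arrays must have shape (nt, ny, nx)={shape}, "
                f"got u_x {self.u_x.shape}, u_y {self.u_y.shape}"
            )
        for name, coords in (("x", self.x), ("y", self.y), ("t", self.t)):
            if coords.size > 1:
                d = np.diff(coords)
                if np.any(d <= 0):
                    raise ValueError(f"{name} coordinates must be strictly ascending")
                if not np.allclose(d, d[0], rtol=1e-6, atol=0.0):
                    raise ValueError(f"{name} coordinates must be uniformly spaced")
        if not (np.all(np.isfinite(self.u_x)) and np.all(np.isfinite(self.u_y))):
            raise ValueError("velocity field contains non-finite values")

    # -- lattice spacings -------------------------------------------------
    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])

    # -- probing ----------------------------------------------------------
    def nearest_index(self, x: float, y: float) -> tuple[int, int]:
        """Indices of the grid node nearest to the point (x, y)."""
        if not (self.x[0] <= x <= self.x[-1] and self.y[0] <= y <= self.y[-1]):
            raise ValueError(
                f"probe ({x}, {y}) outside grid "
                f"x=[{self.x[0]}, {self.x[-1]}], y=[{self.y[0]}, {self.y[-1]}]"
            )
        return int(np.argmin(np.abs(self.y - y))), int(np.argmin(np.abs(self.x - x)))

    def probe_series(self, x: float, y: float, component: str = "u_y") -> np.ndarray:
        """Time series of one velocity component at the nearest grid node."""
        iy, ix = self.nearest_index(x, y)
        return getattr(self, component)[:, iy, ix].copy()

    # -- I/O --------------------------------------------------------------
    def to_long_dataframe(self) -> pd.DataFrame:
        tt, yy, xx = np.meshgrid(self.t, self.y, self.x, indexing="ij")
        return pd.DataFrame(
            {
                "t": tt.ravel(),
                "x": xx.ravel(),
                "y": yy.ravel(),
                "ux": self.u_x.ravel(),
                "uy": self.u_y.ravel(),
            }
        )

    def write_csv(self, path: str | Path) -> Path:
        """Write the long-format CSV plus a ``<path>.json`` provenance sidecar."""
        path = Path(path)
        self.to_long_dataframe().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(_jsonable(self.provenance), fh, indent=2)
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "VelocityField":
        path = Path(path)
        df = pd.read_csv(path)
        missing = {"t", "x", "y", "ux", "uy"} - set(df.columns)
        if missing:
            raise ValueError(f"field CSV missing columns: {sorted(missing)}")
        t = np.unique(df["t"].to_numpy())
        y = np.unique(df["y"].to_numpy())
        x = np.unique(df["x"].to_numpy())
        shape = (t.size, y.size, x.size)
        if len(df) != np.prod(shape):
            raise ValueError("field CSV does not describe a full lattice")
        order = df.sort_values(["t", "y", "x"], kind="mergesort")
        u_x = order["ux"].to_numpy().reshape(shape)
        u_y = order["uy"].to_numpy().reshape(shape)
        provenance: dict = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            with open(sidecar) as fh:
                provenance = json.load(fh)
        return cls(x=x, y=y, t=t, u_x=u_x, u_y=u_y, provenance=provenance)


def _jsonable(obj):
    """Recursively coerce numpy scalars/arrays for json.dump."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
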