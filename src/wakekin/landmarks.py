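"""Landmark tables in the DeepLabCut CSV export dialect.

Fourteen named body points are tracked per frame: ``snout``,
``tail_tip`` and six points on each side of the body outline
(``left_1..left_6`` head-to-tail, likewise ``right_*``).  Each point
carries ``x``, ``y`` and a ``likelihood`` in [0, 1].  On disk the table
uses the three-header-row dialect (scorer / bodyparts / coords) with the
frame index in the first column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BODY_PARTS: tuple[str, ...] = (
    "snout",
    *(f"left_{i}" for i in range(1, 7)),
    *(f"right_{i}" for i in range(1, 7)),
    "tail_tip",
)

#: arc-length fractions of the six side-point pairs, head to tail
SIDE_FRACTIONS: np.ndarray = np.arange(1, 7) / 7.0


class LandmarkFormatError(ValueError):
    """Raised when a landmark file does not match the expected dialect."""


@dataclass
class LandmarkTable:
    """Per-frame landmark positions with tracking confidence.

    ``data`` has a three-level column MultiIndex (scorer, bodypart,
    coord) and one row per frame.  Coordinates are in the units the file
    was digitized in; ``scale`` converts them to meters.
    """

    data: pd.DataFrame
    frame_rate: float
    scale: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        self.validate()

    def validate(self) -> None:
        cols = self.data.columns
        if cols.nlevels != 3:
            raise LandmarkFormatError(
                "landmark table needs (scorer, bodyparts, coords) columns"
            )
        present = set(cols.get_level_values(1))
        for part in BODY_PARTS:
            if part not in present:
                raise LandmarkFormatError(f"missing body part: {part}")
        lik = self.data.loc[:, (slice(None), slice(None), "likelihood")].to_numpy()
        finite = lik[np.isfinite(lik)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise LandmarkFormatError(
                f"likelihood outside [0, 1]: range {finite.min()}..{finite.max()}"
            )

    # -- accessors --------------------------------------------------------
    @property
    def scorer(self) -> str:
        return str(self.data.columns.get_level_values(0)[0])

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def xy(self, part: str) -> np.ndarray:
        """(n_frames, 2) array of a body part's coordinates, file units."""
        s = self.scorer
        return np.column_stack(
            [self.data[(s, part, "x")].to_numpy(), self.data[(s, part, "y")].to_numpy()]
        )

    def likelihood(self, part: str) -> np.ndarray:
        return self.data.loc[:, (self.scorer, part, "likelihood")].to_numpy()

    def copy(self) -> "LandmarkTable":
        return LandmarkTable(
            data=self.data.copy(),
            frame_rate=self.frame_rate,
            scale=self.scale,
            meta=dict(self.meta),
        )

    # -- I/O --------------------------------------------------------------
    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index_label="scorer")
        return path

    @classmethod
    def from_arrays(
        cls,
        positions: dict[str, np.ndarray],
        likelihoods: dict[str, np.ndarray],
        frame_rate: float,
        scale: float = 1.0,
        scorer: str = "wakekin",
        meta: dict | None = None,
    ) -> "LandmarkTable":
        """Build a table from per-part (n_frames, 2) position arrays."""
        blocks = {}
        for part in BODY_PARTS:
            xy = np.asarray(positions[part], dtype=float)
            blocks[(scorer, part, "x")] = xy[:, 0]
            blocks[(scorer, part, "y")] = xy[:, 1]
            blocks[(scorer, part, "likelihood")] = np.asarray(
                likelihoods[part], dtype=float
            )
        df = pd.DataFrame(blocks)
        df.columns = pd.MultiIndex.from_tuples(
            df.columns, names=["scorer", "bodyparts", "coords"]
        )
        return cls(
            data=df, frame_rate=frame_rate, scale=scale, meta=meta or {}
        )


def read_landmarks(
    path: str | Path, frame_rate: float, scale: float = 1.0
) -> LandmarkTable:
    """Read a DeepLabCut-dialect CSV into a :class:`LandmarkTable`.

    Frame rate and pixel-to-meter scale come from configuration, not
    from the file.  Non-numeric cells are reported with their row
    numbers; a missing body part is named in the error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        rows = sorted(set(df.index[bad.any(axis=1)]))
        raise LandmarkFormatError(f"non-numeric cells in rows: {rows[:20]}")
    df = numeric
    df.columns = df.columns.set_names(["scorer", "bodyparts", "coords"])
    return LandmarkTable(data=df, frame_rate=frame_rate, scale=scale)
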