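"""Per-session nucleus point clouds.

A :class:`SessionCloud` holds one imaging week's nucleus centroids in
micrometres together with per-nucleus labels (tangle flag, fiducial flag)
and the axis-aligned bounds of the imaged field.  Clouds round-trip
through plain CSV with the columns
``neuron_id, week, x_um, y_um, z_um, tangle, fiducial``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

CSV_COLUMNS = ["neuron_id", "week", "x_um", "y_um", "z_um", "tangle", "fiducial"]


@dataclass
class SessionCloud:
    """3D nucleus centroids of one imaging session.

    Parameters
    ----------
    xyz
        ``(n, 3)`` centroid coordinates in micrometres.
    ids
        ``(n,)`` integer nucleus identifiers, unique within the session.
    tangle
        ``(n,)`` boolean flags: nucleus is associated with a tau tangle.
    fiducial
        ``(n,)`` boolean flags: nucleus is a registration landmark.
    bounds
        ``(2, 3)`` array ``[lo, hi]`` of the imaged field in micrometres.
    week
        1-based week index of the session.
    """

    xyz: np.ndarray
    ids: np.ndarray
    tangle: np.ndarray
    fiducial: np.ndarray
    bounds: np.ndarray
    week: int = 1

    def __post_init__(self) -> None:
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        if self.xyz.size == 0:
            self.xyz = self.xyz.reshape(0, 3)
        if self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        n = len(self.xyz)
        self.ids = np.asarray(self.ids, dtype=np.int64).reshape(n)
        self.tangle = np.asarray(self.tangle, dtype=bool).reshape(n)
        self.fiducial = np.asarray(self.fiducial, dtype=bool).reshape(n)
        self.bounds = np.asarray(self.bounds, dtype=float).reshape(2, 3)
        if len(np.unique(self.ids)) != n:
            raise ValueError("nucleus ids must be unique within a session")

    @property
    def n(self) -> int:
        return len(self.xyz)

    def subset(self, mask: np.ndarray) -> "SessionCloud":
        """Return a new cloud restricted to ``mask`` (boolean or index array)."""
        return replace(
            self,
            xyz=self.xyz[mask],
            ids=self.ids[mask],
            tangle=self.tangle[mask],
            fiducial=self.fiducial[mask],
        )

    def fiducial_cloud(self) -> "SessionCloud":
        return self.subset(self.fiducial)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": self.ids,
                "week": np.full(self.n, self.week, dtype=int),
                "x_um": self.xyz[:, 0],
                "y_um": self.xyz[:, 1],
                "z_um": self.xyz[:, 2],
                "tangle": self.tangle.astype(int),
                "fiducial": self.fiducial.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, bounds: np.ndarray | None = None) -> "SessionCloud":
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        weeks = frame["week"].unique()
        if len(weeks) != 1:
            raise ValueError("a session table must contain exactly one week")
        xyz = frame[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        if bounds is None:
            bounds = np.stack([xyz.min(axis=0), xyz.max(axis=0)])
        return cls(
            xyz=xyz,
            ids=frame["neuron_id"].to_numpy(dtype=np.int64),
            tangle=frame["tangle"].to_numpy().astype(bool),
            fiducial=frame["fiducial"].to_numpy().astype(bool),
            bounds=bounds,
            week=int(weeks[0]),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def read_csv(cls, path: str | Path, bounds: np.ndarray | None = None) -> "SessionCloud":
        return cls.from_frame(pd.read_csv(path), bounds=bounds)
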