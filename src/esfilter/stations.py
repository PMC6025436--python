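"""Station table container: ids, planar coordinates, response, covariates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StationSet"]

_RESERVED = ("station_id", "x", "y", "value")


@dataclass
class StationSet:
    """An observational unit set: monitoring stations on a planar grid.

    Parameters
    ----------
    ids
        Opaque station labels, length n.
    xy
        (n, 2) planar coordinates (same length unit throughout, e.g. km).
        Longitude/latitude input must be projected before construction.
    values
        Measured exposure concentration per station (e.g. ug/m3).
    covariates
        DataFrame of named covariate columns, n rows, unique names.
    """

    ids: np.ndarray
    xy: np.ndarray
    values: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.xy = np.asarray(self.xy, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if n < 3:
            raise ValueError(f"need at least 3 stations, got {n}")
        if self.xy.shape != (n, 2):
            raise ValueError(f"xy must have shape ({n}, 2), got {self.xy.shape}")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("station coordinates must be finite")
        if self.values.shape != (n,):
            raise ValueError(f"values must have shape ({n},)")
        if len(self.covariates) not in (0, n):
            raise ValueError("covariates must have one row per station")
        if self.covariates.columns.duplicated().any():
            dup = self.covariates.columns[self.covariates.columns.duplicated()]
            raise ValueError(f"duplicate covariate names: {list(dup)}")
        # duplicate coordinates break the strictly-positive-distance requirement
        _, counts = np.unique(self.xy, axis=0, return_counts=True)
        if np.any(counts > 1):
            where = np.unique(self.xy, axis=0)[counts > 1][0]
            dup_ids = self.ids[np.all(self.xy == where, axis=1)]
            raise ValueError(
                f"duplicate station coordinates {tuple(where)} for ids {list(dup_ids)}"
            )
        self.covariates = self.covariates.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def subset(self, mask: np.ndarray) -> "StationSet":
        """Return a StationSet restricted to a boolean mask or index array."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return StationSet(
            ids=self.ids[idx],
            xy=self.xy[idx],
            values=self.values[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "station_id": self.ids,
                "x": self.xy[:, 0],
                "y": self.xy[:, 1],
                "value": self.values,
            }
        )
        return pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StationSet":
        missing = [c for c in _RESERVED if c not in df.columns]
        if missing:
            raise ValueError(f"station table missing required columns: {missing}")
        cov = df.drop(columns=list(_RESERVED))
        return cls(
            ids=df["station_id"].to_numpy(),
            xy=df[["x", "y"]].to_numpy(dtype=float),
            values=df["value"].to_numpy(dtype=float),
            covariates=cov,
        )

    @classmethod
    def from_csv(cls, path) -> "StationSet":
        return cls.from_frame(pd.read_csv(path))
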