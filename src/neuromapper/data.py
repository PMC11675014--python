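"""Core container for time-by-feature matrices.

A :class:`DataMatrix` holds an ``N x M`` real matrix whose rows are time
points sampled every ``tr`` seconds and whose columns are features
(parcels, voxels, or synthetic coordinates), plus optional per-row
categorical state labels.  It is the single input type of the Mapper
pipeline and of every synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DataMatrix"]


@dataclass
class DataMatrix:
    """``N x M`` time-by-feature matrix with sampling interval and labels.

    Parameters
    ----------
    values:
        Real matrix, rows = time points (N >= 2), columns = features
        (M >= 1).  All entries must be finite.
    tr:
        Sampling interval in seconds per row (repetition time).
    feature_names:
        Optional list of M identifiers; defaults to ``f0..f{M-1}``.
    labels:
        Optional per-row categorical state (length N).
    """

    values: np.ndarray
    tr: float = 1.0
    feature_names: list[str] | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 time points, got {n}")
        if m < 1:
            raise ValueError("need at least 1 feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.feature_names is None:
            self.feature_names = [f"f{i}" for i in range(m)]
        elif len(self.feature_names) != m:
            raise ValueError("feature_names length must equal column count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length must equal row count")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds: ``0, tr, 2*tr, ...``."""
        return np.arange(self.n_timepoints) * self.tr

    def zscore(self) -> "DataMatrix":
        """Per-feature z-scoring; zero-variance features are left centered."""
        mu = self.values.mean(axis=0)
        sd = self.values.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return DataMatrix((self.values - mu) / sd, tr=self.tr,
                          feature_names=list(self.feature_names),
                          labels=None if self.labels is None else self.labels.copy())

    # -- plain-text persistence -------------------------------------------

    def to_tsv(self, path: str | Path, labels_path: str | Path | None = None) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.to_csv(path, sep="\t", index=False)
        if labels_path is not None and self.labels is not None:
            pd.DataFrame({"time": self.times, "state": self.labels}).to_csv(
                labels_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, tr: float = 1.0,
                 labels_path: str | Path | None = None) -> "DataMatrix":
        """Load a matrix written by :meth:`to_tsv` (or any delimited table).

        The delimiter is sniffed from the extension: ``.csv`` uses commas,
        anything else tabs.
        """
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep)
        labels = None
        if labels_path is not None:
            labels = pd.read_csv(labels_path, sep="\t")["state"].to_numpy()
        return cls(df.to_numpy(dtype=float), tr=tr,
                   feature_names=list(df.columns), labels=labels)
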