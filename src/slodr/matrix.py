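"""Core data container: a person x measure score table.

A :class:`ScoreMatrix` wraps a pandas DataFrame whose index holds unique
person identifiers and whose columns are numeric performance measures,
oriented so that higher always means better.  Most pipeline stages take a
ScoreMatrix and return a new one; the underlying frame is never mutated in
place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ScoreMatrix", "ScoreMatrixError"]


class ScoreMatrixError(ValueError):
    """Raised when a score table violates the container's invariants."""


@dataclass(frozen=True)
class ScoreMatrix:
    """Person x measure table of performance scores (higher = better).

    Parameters
    ----------
    data
        DataFrame indexed by person id, one numeric column per measure.
    standardized
        True once every column has been z-scored (mean 0, sample SD 1).
    """

    data: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ScoreMatrixError(f"duplicate person ids: {dupes[:5]}")
        if self.data.shape[1] < 3:
            raise ScoreMatrixError(
                f"need at least 3 measures, got {self.data.shape[1]}"
            )
        non_numeric = [
            c for c in self.data.columns
            if not pd.api.types.is_numeric_dtype(self.data[c])
        ]
        if non_numeric:
            raise ScoreMatrixError(f"non-numeric score columns: {non_numeric}")
        if self.standardized:
            vals = self.data.to_numpy(dtype=float)
            mu = np.nanmean(vals, axis=0)
            sd = np.nanstd(vals, axis=0, ddof=1)
            if not (np.all(np.abs(mu) < 1e-8) and np.all(np.abs(sd - 1) < 1e-8)):
                raise ScoreMatrixError(
                    "standardized flag set but columns are not z-scored"
                )

    # -- conveniences -----------------------------------------------------
    @property
    def person_ids(self) -> pd.Index:
        return self.data.index

    @property
    def measure_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_measures(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, *, standardized: bool | None = None) -> "ScoreMatrix":
        """Return a copy holding *data* (standardized flag kept unless given)."""
        std = self.standardized if standardized is None else standardized
        return ScoreMatrix(data=data, standardized=std)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ScoreMatrix(n_persons={self.n_persons}, "
            f"n_measures={self.n_measures}, standardized={self.standardized})"
        )
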