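"""Ingestion and preprocessing of rectangular score tables.

Stages, in the order the pipeline applies them by default: read a CSV,
trim extreme values at pooled percentiles, reverse columns where lower raw
values mean better performance (e.g. reaction times), convert running times
to speeds, drop incomplete rows, z-score every column, and finally compute
each person's within-individual mean (WIM) and standard deviation (WISD).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import ScoreMatrix, ScoreMatrixError

__all__ = [
    "read_scores",
    "write_scores",
    "reverse_scores",
    "times_to_speed",
    "percentile_trim",
    "complete_cases",
    "standardize",
    "wim_wisd",
]

log = logging.getLogger(__name__)


def read_scores(path, id_column: str = "person_id") -> ScoreMatrix:
    """Parse a CSV with a header row into a :class:`ScoreMatrix`.

    Missing cells stay missing (NaN), never zero.  Raises on duplicate ids,
    non-numeric score cells and tables with fewer than 3 measures, naming
    the offending row/column.
    """
    raw = pd.read_csv(path)
    if id_column not in raw.columns:
        raise ScoreMatrixError(f"id column {id_column!r} not found in {path}")
    frame = raw.set_index(id_column)
    frame.index.name = "person_id"
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad][0]
            raise ScoreMatrixError(
                f"non-numeric value in column {col!r}, row {row!r}"
            )
        frame[col] = coerced
    return ScoreMatrix(frame)


def write_scores(m: ScoreMatrix, path) -> None:
    """Write the table back to CSV (header row, person_id first column)."""
    m.data.to_csv(path, index=True)


def reverse_scores(m: ScoreMatrix, columns: list[str]) -> ScoreMatrix:
    """Negate the named columns so that higher uniformly means better."""
    unknown = [c for c in columns if c not in m.data.columns]
    if unknown:
        raise ScoreMatrixError(f"unknown columns to reverse: {unknown}")
    data = m.data.copy()
    data[columns] = -data[columns]
    return m.with_data(data)


def times_to_speed(m: ScoreMatrix, distances: dict[str, float]) -> ScoreMatrix:
    """Replace time columns (seconds) by speed = distance / time (m/s)."""
    unknown = [c for c in distances if c not in m.data.columns]
    if unknown:
        raise ScoreMatrixError(f"unknown time columns: {unknown}")
    data = m.data.copy()
    for col, dist in distances.items():
        nonpos = data.index[data[col] <= 0]
        if len(nonpos):
            raise ScoreMatrixError(
                f"non-positive time in column {col!r}, row {nonpos[0]!r}"
            )
        data[col] = dist / data[col]
    return m.with_data(data)


def percentile_trim(
    m: ScoreMatrix,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
    columns: list[str] | None = None,
    per_column: bool = False,
) -> tuple[ScoreMatrix, int]:
    """Blank out values outside the pooled [low, high] percentile band.

    By default the percentile bounds come from pooling every trimmed column
    into one distribution; ``per_column=True`` trims each column against its
    own percentiles instead.  Returns the trimmed matrix and the number of
    cells set to missing.  Empirical percentiles use linear interpolation.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    cols = list(m.data.columns) if columns is None else columns
    data = m.data.copy()
    deleted = 0
    if per_column:
        for col in cols:
            vals = data[col]
            lo, hi = np.nanpercentile(vals.to_numpy(float), [low_pct, high_pct])
            if lo == hi:
                log.warning("percentile_trim: degenerate column %r, skipped", col)
                continue
            mask = (vals < lo) | (vals > hi)
            deleted += int(mask.sum())
            data.loc[mask, col] = np.nan
    else:
        pooled = data[cols].to_numpy(float).ravel()
        lo, hi = np.nanpercentile(pooled, [low_pct, high_pct])
        if lo == hi:
            log.warning("percentile_trim: degenerate pooled distribution, no-op")
            return m.with_data(data), 0
        for col in cols:
            mask = (data[col] < lo) | (data[col] > hi)
            deleted += int(mask.sum())
            data.loc[mask, col] = np.nan
    log.info("percentile_trim: %d cells set to missing", deleted)
    return m.with_data(data), deleted


def complete_cases(m: ScoreMatrix) -> tuple[ScoreMatrix, int]:
    """Drop rows containing any missing value; return (matrix, n_removed)."""
    keep = m.data.notna().all(axis=1)
    removed = int((~keep).sum())
    if removed == m.n_persons:
        raise ScoreMatrixError("complete_cases would remove every row")
    log.info("complete_cases: removed %d of %d rows", removed, m.n_persons)
    return m.with_data(m.data.loc[keep]), removed


def standardize(m: ScoreMatrix) -> ScoreMatrix:
    """Z-score every column (mean 0, sample SD 1 with denominator n-1)."""
    vals = m.values
    if np.isnan(vals).any():
        raise ScoreMatrixError("standardize requires a complete matrix")
    sd = vals.std(axis=0, ddof=1)
    zero = np.asarray(sd == 0).nonzero()[0]
    if zero.size:
        raise ScoreMatrixError(
            f"zero-variance column: {m.measure_names[zero[0]]!r}"
        )
    z = (vals - vals.mean(axis=0)) / sd
    data = pd.DataFrame(z, index=m.data.index, columns=m.data.columns)
    return ScoreMatrix(data, standardized=True)


def wim_wisd(m: ScoreMatrix) -> pd.DataFrame:
    """Per-person mean (WIM) and sample SD (WISD) across the p measures.

    Returns a DataFrame indexed by person_id with columns ``wim`` and
    ``wisd`` (denominator p-1).  Expects a complete matrix, normally
    standardized first so WIM/WISD are in z-units.
    """
    vals = m.values
    if np.isnan(vals).any():
        raise ScoreMatrixError("wim_wisd requires a complete matrix")
    prof = pd.DataFrame(
        {
            "wim": vals.mean(axis=1),
            "wisd": vals.std(axis=1, ddof=1),
        },
        index=m.data.index,
    )
    return prof
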