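"""The two SLODR criteria per cell, and their size-weighted aggregation.

Criterion 1: significantly *negative* skewness of the estimated latent
ability scores (moment skewness g1 with the D'Agostino z-test).
Criterion 2: significantly *positive* correlation between latent scores and
the log within-individual residual variance (Pearson by default).
A cell "shows SLODR" only when both hold at the chosen alpha; the sweep
summary reports the subsample-size-weighted proportion of such cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SlodrCellResult",
    "skewness_test",
    "corr_latent_residvar",
    "evaluate_cell",
    "weighted_probability",
]


@dataclass(frozen=True)
class SlodrCellResult:
    """Per-cell SLODR outcomes (one stripe of a sliced sweep)."""

    direction: str
    k: int
    slice_index: int
    n: int
    rho_wim_wisd: float
    rho_p: float
    skewness: float
    skew_z: float
    skew_p: float
    r_latent_logrv: float
    r_p: float
    criterion_skew: bool
    criterion_corr: bool
    slodr_both: bool
    converged: bool
    status: str = "converged"   # converged | skipped | failed


def skewness_test(values) -> tuple[float, float, float]:
    """Moment skewness g1 = m3 / m2^(3/2) with the D'Agostino z-test.

    Returns (g1, z, two-sided p).  The z-test needs n >= 8; for smaller
    samples g1 is still returned with z and p as NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("skewness_test needs n >= 3")
    if np.ptp(values) == 0:
        raise ValueError("skewness_test needs non-constant values")
    g1 = float(stats.skew(values, bias=True))
    if values.size < 8:
        return g1, float("nan"), float("nan")
    z, p = stats.skewtest(values)
    return g1, float(z), float(p)


def corr_latent_residvar(
    fscore, log_resid_var, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between latent scores and log residual variance.

    Pearson with the t-approximation p-value (n-2 df) by default; a
    Spearman variant is selectable (rank-invariant to the log transform).
    """
    x = np.asarray(fscore, dtype=float)
    y = np.asarray(log_resid_var, dtype=float)
    if x.size < 4:
        raise ValueError("corr_latent_residvar needs n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("corr_latent_residvar: zero variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def evaluate_cell(
    *,
    direction: str,
    k: int,
    slice_index: int,
    n: int,
    rho_wim_wisd: float,
    rho_p: float,
    fscore,
    log_resid_var,
    alpha: float = 0.05,
    corr_method: str = "pearson",
) -> SlodrCellResult:
    """Score one converged cell against both SLODR criteria.

    criterion_skew: g1 < 0 and skew_p <= alpha;
    criterion_corr: r > 0 and r_p <= alpha;
    slodr_both: both.  Monotone in alpha by construction.
    """
    g1, z, skew_p = skewness_test(fscore)
    r, r_p = corr_latent_residvar(fscore, log_resid_var, method=corr_method)
    crit_skew = bool(g1 < 0 and skew_p <= alpha)
    crit_corr = bool(r > 0 and r_p <= alpha)
    return SlodrCellResult(
        direction=direction,
        k=k,
        slice_index=slice_index,
        n=n,
        rho_wim_wisd=rho_wim_wisd,
        rho_p=rho_p,
        skewness=g1,
        skew_z=z,
        skew_p=skew_p,
        r_latent_logrv=r,
        r_p=r_p,
        criterion_skew=crit_skew,
        criterion_corr=crit_corr,
        slodr_both=crit_skew and crit_corr,
        converged=True,
    )


def weighted_probability(
    results: list[SlodrCellResult], include_nonconverged: bool = False
) -> float:
    """Size-weighted proportion of cells satisfying both SLODR criteria.

    sum(n_c * I(slodr_both_c)) / sum(n_c) over converged cells.  With
    ``include_nonconverged=True`` skipped/failed cells enter the denominator
    as non-fulfilling cells.
    """
    if include_nonconverged:
        pool = results
    else:
        pool = [r for r in results if r.converged]
    if not pool:
        raise ValueError("weighted_probability: no cells to aggregate")
    total = sum(r.n for r in pool)
    hits = sum(r.n for r in pool if r.converged and r.slodr_both)
    return hits / total
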