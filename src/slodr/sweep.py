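"""End-to-end sweep: preprocess -> WIM/WISD -> slice -> fit -> SLODR metrics.

``run_sweep`` executes every (direction, k) slicing plan up to k_max on one
dataset, refits the single-factor model inside each stripe on the globally
standardized scores (no re-standardization within cells), evaluates both
SLODR criteria per cell, and aggregates the size-weighted joint-criterion
probability.  Cells too small to fit (n < p + margin) are recorded as
"skipped", failed fits as "failed"; nothing silently vanishes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import factor, metrics, preprocess, slicing
from .matrix import ScoreMatrix

__all__ = ["RunConfig", "SweepSummary", "run_sweep", "emit_report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one sweep run (serializable)."""

    k_max: int = 8
    directions: tuple[str, ...] = slicing.DIRECTIONS
    alpha: float = 0.05
    min_cell_margin: int = 5          # cells with n < p + margin are skipped
    seed: int = 0
    corr_method: str = "pearson"      # latent vs log-resid-var correlation
    standardize_axes: bool = True     # z-score WIM/WISD before slicing
    include_nonconverged: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["directions"] = list(self.directions)
        return d


@dataclass
class SweepSummary:
    """All per-cell results of a sweep plus aggregate counts."""

    config: RunConfig
    cells: list[metrics.SlodrCellResult]
    weighted_prob: float | None
    n_attempted: int
    n_converged: int
    n_skipped: int
    n_failed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(c) for c in self.cells])


def _skipped_cell(cell: slicing.SliceCell, status: str) -> metrics.SlodrCellResult:
    nan = float("nan")
    return metrics.SlodrCellResult(
        direction=cell.direction,
        k=cell.k,
        slice_index=cell.slice_index,
        n=cell.n,
        rho_wim_wisd=cell.rho_wim_wisd,
        rho_p=cell.rho_p,
        skewness=nan,
        skew_z=nan,
        skew_p=nan,
        r_latent_logrv=nan,
        r_p=nan,
        criterion_skew=False,
        criterion_corr=False,
        slodr_both=False,
        converged=False,
        status=status,
    )


def run_sweep(m: ScoreMatrix, config: RunConfig = RunConfig()) -> SweepSummary:
    """Run the full slicing sweep on an (unstandardized or z-scored) matrix.

    Scores are standardized once globally; WIM/WISD and every per-cell
    factor fit use those same standardized values.  Deterministic given the
    matrix and config.
    """
    if not m.standardized:
        m = preprocess.standardize(m)
    profiles = preprocess.wim_wisd(m)
    p = m.n_measures
    min_n = p + config.min_cell_margin

    results: list[metrics.SlodrCellResult] = []
    n_conv = n_skip = n_fail = 0
    for plan in slicing.enumerate_sweep(config.k_max, tuple(config.directions)):
        cells = slicing.slice_sample(
            profiles, plan.direction, plan.k, standardize_axes=config.standardize_axes
        )
        for cell in cells:
            if cell.n < min_n:
                log.info(
                    "cell %s k=%d idx=%d: skipped (n=%d < %d)",
                    cell.direction, cell.k, cell.slice_index, cell.n, min_n,
                )
                results.append(_skipped_cell(cell, "skipped"))
                n_skip += 1
                continue
            # subset in input row order so results do not depend on the
            # direction's internal ordering of the same member set
            mask = m.data.index.isin(cell.person_ids)
            sub = m.with_data(m.data.loc[mask], standardized=False)
            try:
                sol = factor.fit_single_factor_cov(
                    np.cov(sub.values, rowvar=False, ddof=0),
                    sub.n_persons,
                    seed=config.seed,
                )
                if not sol.converged:
                    raise RuntimeError("non-converged factor solution")
                f = factor.factor_scores(sol, sub)
                latents = factor.predicted_and_residuals(sol, f, sub)
                res = metrics.evaluate_cell(
                    direction=cell.direction,
                    k=cell.k,
                    slice_index=cell.slice_index,
                    n=cell.n,
                    rho_wim_wisd=cell.rho_wim_wisd,
                    rho_p=cell.rho_p,
                    fscore=latents["fscore"],
                    log_resid_var=latents["log_resid_var"],
                    alpha=config.alpha,
                    corr_method=config.corr_method,
                )
                results.append(res)
                n_conv += 1
            except (np.linalg.LinAlgError, RuntimeError, ValueError) as exc:
                log.warning(
                    "cell %s k=%d idx=%d failed: %s",
                    cell.direction, cell.k, cell.slice_index, exc,
                )
                results.append(_skipped_cell(cell, "failed"))
                n_fail += 1

    weighted = (
        metrics.weighted_probability(results, config.include_nonconverged)
        if n_conv > 0
        else None
    )
    return SweepSummary(
        config=config,
        cells=results,
        weighted_prob=weighted,
        n_attempted=len(results),
        n_converged=n_conv,
        n_skipped=n_skip,
        n_failed=n_fail,
    )


def emit_report(summary: SweepSummary, out_dir) -> dict[str, Path]:
    """Write cells_results.csv, summary.json, run.log and resolved_config.json.

    Every summary statistic is recomputable from cells_results.csv; an empty
    converged-cell set is flagged in summary.json instead of emitting NaN.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": out / "cells_results.csv",
        "summary": out / "summary.json",
        "log": out / "run.log",
        "config": out / "resolved_config.json",
    }
    summary.to_frame().to_csv(paths["cells"], index=False)
    payload = {
        "weighted_prob": summary.weighted_prob,
        "no_converged_cells": summary.n_converged == 0,
        "n_attempted": summary.n_attempted,
        "n_converged": summary.n_converged,
        "n_skipped": summary.n_skipped,
        "n_failed": summary.n_failed,
    }
    paths["summary"].write_text(json.dumps(payload, indent=2) + "\n")
    paths["config"].write_text(json.dumps(summary.config.to_dict(), indent=2) + "\n")
    with paths["log"].open("w") as fh:
        fh.write(
            f"attempted={summary.n_attempted} converged={summary.n_converged} "
            f"skipped={summary.n_skipped} failed={summary.n_failed}\n"
        )
        for c in summary.cells:
            fh.write(
                f"{c.direction} k={c.k} idx={c.slice_index} n={c.n} "
                f"status={c.status} both={c.slodr_both}\n"
            )
    return paths
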