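"""Recipes for analysing external datasets with the pipeline.

Only a generic CSV ingester plus a documented decathlon recipe live here;
acquisition of the external datasets themselves is manual (see README).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import factor, preprocess, slicing, sweep

__all__ = ["DECATHLON_RUNNING_DISTANCES", "DecathlonAnalysis", "analyze_decathlon"]

# Running events are recorded as times (seconds); everything else is a
# distance/height already oriented "higher = better".
DECATHLON_RUNNING_DISTANCES = {
    "100m": 100.0,
    "400m": 400.0,
    "110mh": 110.0,
    "1500m": 1500.0,
}


@dataclass(frozen=True)
class DecathlonAnalysis:
    """Headline quantities of the decathlon pipeline run."""

    n: int
    spearman_wim_wisd: float
    spearman_p: float
    mean_inter_event_corr: float
    mean_loading: float
    weighted_prob: float
    summary: sweep.SweepSummary


def analyze_decathlon(
    path,
    id_column: str = "person_id",
    running_distances: dict[str, float] | None = None,
    k_max: int = 15,
    alpha: float = 0.05,
) -> DecathlonAnalysis:
    """Full pipeline on a decathlon results table.

    Expects one row per athlete-Games with the ten event columns; running
    events named in *running_distances* (defaults to the standard four) are
    converted from seconds to speed so higher uniformly means better, then
    rows with missing events are dropped and all events standardized.
    """
    dists = DECATHLON_RUNNING_DISTANCES if running_distances is None else running_distances
    m = preprocess.read_scores(path, id_column=id_column)
    present = {c: d for c, d in dists.items() if c in m.data.columns}
    m = preprocess.times_to_speed(m, present)
    m, _ = preprocess.complete_cases(m)
    m = preprocess.standardize(m)

    profiles = preprocess.wim_wisd(m)
    rho, rho_p = slicing.spearman_wim_wisd(profiles["wim"], profiles["wisd"])

    corr = m.data.corr().to_numpy()
    mean_corr = float(corr[~np.eye(corr.shape[0], dtype=bool)].mean())

    sol = factor.fit_single_factor(m)
    mean_loading = float(sol.loadings.mean())

    summary = sweep.run_sweep(m, sweep.RunConfig(k_max=k_max, alpha=alpha))
    return DecathlonAnalysis(
        n=m.n_persons,
        spearman_wim_wisd=rho,
        spearman_p=rho_p,
        mean_inter_event_corr=mean_corr,
        mean_loading=mean_loading,
        weighted_prob=summary.weighted_prob,
        summary=summary,
    )
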