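"""Synthetic score-matrix generator with controllable mean-variance coupling.

The generator emulates the statistical structure the analysis pipeline
assumes: a single common ability factor, a per-person noise scale that may
be coupled (positively or negatively) to ability, an optional monotone
skewing transform, optional hard floor/ceiling censoring, and an optional
negatively skewing person-level disturbance.

Generative model
----------------
For person *i* and measure *j*:

    a_i   ~ N(0, 1)                     (true ability)
    sig_i = sigma0 * exp(c * a_i)       (person noise SD; c = coupling)
    x_ij  = lambda_j * a_i + sig_i * eps_ij,   eps_ij ~ N(0, 1)

optionally followed, in order, by

    x_ij <- x_ij - d_i * b_ij           d_i ~ Exp(rate), b_ij ~ U(0, 1)
    y_ij = (exp(beta * x_ij) - 1)/beta  (beta != 0; identity when beta = 0)
    censoring of y at its pooled empirical (low, high) quantiles.

A negative coupling *c* makes able people less variable, producing the
negative within-individual mean/SD (WIM-WISD) correlation seen in e.g.
reaction-time or athletic data; a positive *c* mimics income-like data.
A negative *beta* compresses the upper tail (ceiling-like negative
skewness); positive *beta* the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ScoreMatrix

__all__ = ["SimConfig", "SimResult", "generate_scores", "true_values"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic score generator.

    Attributes
    ----------
    n_persons, n_measures
        Table dimensions; at least 3 measures are required downstream.
    loadings
        Common-factor loading per measure. A scalar is broadcast to all
        measures; typical values lie in (0, 1).
    noise_scale
        Baseline within-person noise SD ``sigma0`` (> 0).
    coupling
        Log-linear dependence ``c`` of a person's noise SD on ability.
        Negative values couple high ability to low variability.
    skew_beta
        Parameter of the scaled-exponential skewing transform; 0 = identity,
        negative values induce negative score skewness.
    censor_quantiles
        Optional ``(low, high)`` in [0, 1]: scores are clamped at the pooled
        empirical quantiles, mimicking hard floor/ceiling effects.
    disturbance_rate
        Optional rate of an exponential person-level disturbance severity;
        a minority of persons score well below their ability, skewing scores
        negatively.
    seed
        RNG seed; identical configs produce bit-identical output.
    """

    n_persons: int
    n_measures: int = 10
    loadings: float | tuple[float, ...] = 0.7
    noise_scale: float = 0.714
    coupling: float = 0.0
    skew_beta: float = 0.0
    censor_quantiles: tuple[float, float] | None = None
    disturbance_rate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be positive")
        if self.n_measures < 3:
            raise ValueError("n_measures must be >= 3")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")
        lam = self.loading_vector
        if lam.shape != (self.n_measures,):
            raise ValueError(
                f"loadings length {lam.shape[0]} != n_measures {self.n_measures}"
            )
        if self.censor_quantiles is not None:
            low, high = self.censor_quantiles
            if not (0 <= low < high <= 1):
                raise ValueError("censor_quantiles must satisfy 0 <= low < high <= 1")
        if self.disturbance_rate is not None and self.disturbance_rate <= 0:
            raise ValueError("disturbance_rate must be > 0")

    @property
    def loading_vector(self) -> np.ndarray:
        lam = np.asarray(self.loadings, dtype=float)
        if lam.ndim == 0:
            lam = np.full(self.n_measures, float(lam))
        return lam


@dataclass(frozen=True)
class SimResult:
    """Generated scores plus the ground truth used to produce them."""

    scores: ScoreMatrix
    ability: np.ndarray       # a_i, the true latent ability
    noise_sd: np.ndarray      # sig_i, the person noise scale actually used


def _skew_transform(x: np.ndarray, beta: float) -> np.ndarray:
    if beta == 0.0:
        return x
    with np.errstate(over="raise"):
        try:
            return np.expm1(beta * x) / beta
        except FloatingPointError as exc:
            raise ValueError(
                f"skew_beta={beta} overflows the skewing transform; "
                "reduce |skew_beta| or the score scale"
            ) from exc


def generate_scores(config: SimConfig) -> SimResult:
    """Draw one score matrix (and its ground truth) from the model.

    Returns a :class:`SimResult`; ``result.scores`` is the person x measure
    :class:`ScoreMatrix` and the true ability / noise-scale vectors are kept
    alongside for parameter-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_persons, config.n_measures
    lam = config.loading_vector

    ability = rng.standard_normal(n)
    noise_sd = config.noise_scale * np.exp(config.coupling * ability)
    eps = rng.standard_normal((n, p))
    x = lam[None, :] * ability[:, None] + noise_sd[:, None] * eps

    if config.disturbance_rate is not None:
        severity = rng.exponential(scale=1.0 / config.disturbance_rate, size=n)
        x = x - severity[:, None] * rng.uniform(size=(n, p))

    y = _skew_transform(x, config.skew_beta)

    if config.censor_quantiles is not None:
        low, high = config.censor_quantiles
        lo_val, hi_val = np.quantile(y, [low, high])
        y = np.clip(y, lo_val, hi_val)

    if not np.all(np.isfinite(y)):
        raise ValueError(
            "non-finite scores generated; check skew_beta/noise_scale magnitude"
        )

    ids = pd.Index([f"p{i + 1:05d}" for i in range(n)], name="person_id")
    cols = [f"m{j + 1:02d}" for j in range(p)]
    frame = pd.DataFrame(y, index=ids, columns=cols)
    return SimResult(scores=ScoreMatrix(frame), ability=ability, noise_sd=noise_sd)


def true_values(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return the (ability, noise_sd) vectors a given config generates.

    Deterministic under the config's seed: replays the same draws as
    :func:`generate_scores`, so the vectors match the retained ground truth.
    """
    res = generate_scores(config)
    return res.ability, res.noise_sd
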