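"""Prior and posterior predictive simulation of rater performance.

The prior predictive pass draws every hyperparameter and effect from the
priors and simulates a whole study, mapping the joint prior to the scale an
investigator can judge (overall error rates).  The posterior predictive
pass asks what error probability an *average* pathologist at a given career
level would have: per posterior draw the rater intercept is combined with
the level effect only — the task, specimen and subspecialty effects are
deliberately excluded, because case composition is a property of this
study's (non-random) case selection, not of the rater.  Intervals are
highest-posterior-density (HPDI), the shortest interval holding the
requested mass, at the conventional 89% by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
from scipy.special import expit

from .data_model import LEVELS, StudyDesign, ValidationError
from .hier_model import PosteriorDraws
from .synthetic_study import GenerativeParams, _simulate_flags

__all__ = [
    "PredictiveSummary",
    "PriorConfig",
    "prior_predictive",
    "hpdi",
    "average_pathologist",
]


@dataclass(frozen=True)
class PriorConfig:
    """Hyperprior settings for prior predictive simulation."""

    alpha_bar_mean: float = 0.0
    alpha_bar_sd: float = 1.5
    sigma_rate: float = 1.0  # rate of the Exponential prior on every SD


@dataclass(frozen=True)
class PredictiveSummary:
    """Posterior-predictive error probability for one career level."""

    level: str
    mean_error_prob: float
    hpdi_low: float
    hpdi_high: float
    mass: float
    mode: str
    raw_rate: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.hpdi_low <= self.hpdi_high <= 1.0):
            raise ValidationError("HPDI bounds must be ordered and within [0, 1]")


def hpdi(draws: Sequence[float], mass: float = 0.89) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws.

    Ties between equally short windows break to the lowest starting index,
    so the result is deterministic.
    """
    arr = np.sort(np.asarray(draws, dtype=float))
    n = arr.size
    if n < 2:
        raise ValidationError("hpdi needs at least 2 draws")
    if not 0.0 < mass < 1.0:
        raise ValidationError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    k = min(max(k, 2), n)
    widths = arr[k - 1 :] - arr[: n - k + 1]
    start = int(np.argmin(widths))
    return float(arr[start]), float(arr[start + k - 1])


def prior_predictive(
    design: StudyDesign,
    n_draws: int,
    seed: int,
    prior: PriorConfig | None = None,
) -> np.ndarray:
    """Distribution of overall study error rates implied by the priors alone.

    For each draw: sample hyperparameters from the hyperpriors, cluster
    effects from their population distributions, then simulate a full study
    (no missingness) and record its overall error rate.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    prior = prior or PriorConfig()
    rng = np.random.default_rng(seed)
    rates = np.empty(n_draws)
    for d in range(n_draws):
        params = GenerativeParams(
            alpha_bar=float(rng.normal(prior.alpha_bar_mean, prior.alpha_bar_sd)),
            sigma_alpha=float(rng.exponential(1.0 / prior.sigma_rate)),
            sigma_beta=float(rng.exponential(1.0 / prior.sigma_rate)),
            sigma_gamma=float(rng.exponential(1.0 / prior.sigma_rate)),
            sigma_delta=float(rng.exponential(1.0 / prior.sigma_rate)),
            sigma_epsilon=float(rng.exponential(1.0 / prior.sigma_rate)),
        )
        _, is_err, _ = _simulate_flags(design, params, rng, missing_rate=0.0)
        rates[d] = is_err.mean()
    return rates


def average_pathologist(
    posterior: PosteriorDraws,
    level: str,
    mode: str = "new_pathologist",
    mass: float = 0.89,
    raw_rate: float | None = None,
    seed: int = 0,
) -> PredictiveSummary:
    """Posterior-predictive error probability of an average rater at a level.

    Per posterior draw the probability is ``inverse-logit(a + beta_level)``
    where ``a`` is either the grand mean ``alpha_bar`` itself
    (``mode='grand_mean'``) or a fresh rater intercept drawn from
    ``Normal(alpha_bar, sigma_alpha)`` (``mode='new_pathologist'``, the
    default, which propagates between-rater spread).  Task, specimen and
    subspecialty effects are set to zero.
    """
    if level not in LEVELS:
        raise ValidationError(f"unknown career level {level!r}; expected one of {LEVELS}")
    if mode not in ("grand_mean", "new_pathologist"):
        raise ValidationError("mode must be 'grand_mean' or 'new_pathologist'")
    level_ix = LEVELS.index(level)
    alpha_bar = posterior.flat("alpha_bar")
    beta = posterior.flat("beta")[:, level_ix]
    if mode == "grand_mean":
        probs = expit(alpha_bar + beta)
    else:
        rng = np.random.default_rng(seed)
        sigma_alpha = posterior.flat("sigma_alpha")
        # pair the fresh-rater noise with draws in a canonical sort order so
        # the summary does not depend on how the draws happen to be arranged
        order = np.lexsort((beta, sigma_alpha, alpha_bar))
        z = rng.standard_normal(alpha_bar.size)
        probs = expit(alpha_bar[order] + sigma_alpha[order] * z + beta[order])
    if probs.size >= 2:
        low, high = hpdi(probs, mass)
    else:
        low = high = float(probs[0])
    return PredictiveSummary(
        level=level,
        mean_error_prob=float(probs.mean()),
        hpdi_low=low,
        hpdi_high=high,
        mass=mass,
        mode=mode,
        raw_rate=raw_rate,
    )
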