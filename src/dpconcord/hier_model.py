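"""The hierarchical varying-intercepts Bernoulli error model and its fit.

Each answered item *i* is a Bernoulli trial for the error indicator
``W_i`` with ``logit(p_i)`` the sum of five additive cluster effects:

    logit(p_i) = alpha[PID_i] + beta[LEVEL_i] + gamma[CATEGORY_i]
                 + delta[SPECIMEN_i] + epsilon[SUBSPECIALTY_i]

Rater intercepts are partially pooled around a grand mean,
``alpha_j ~ Normal(alpha_bar, sigma_alpha)``; the other clusters are
zero-centred, ``Normal(0, sigma_k)``.  Hyperpriors:
``alpha_bar ~ Normal(0, 1.5)`` (weakly regularizing after the logit
transform) and ``Exponential(1)`` on every SD (the maximum-entropy choice
for a nonnegative scale).

Identifiability note: each rater has exactly one career level, so the
likelihood only constrains ``alpha_j + beta_level`` (and likewise the grand
level of the linear predictor is shared between ``alpha_bar`` and the soft
zero-centring of the other clusters).  Only the partial-pooling priors
identify the split; posterior summaries of ``alpha_bar`` must be read with
that in mind.

Posterior sampling uses the package's Hamiltonian Monte Carlo engine; the
non-centred parametrization (``alpha_j = alpha_bar + sigma_alpha * z_j``
with standard-normal ``z``) is the default, the centred form is retained
for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import _hmc
from .data_model import (
    CATEGORIES,
    LEVELS,
    SPECIMENS,
    SUBSPECIALTIES,
    ResponseItem,
    StudyDesign,
    ValidationError,
)

__all__ = [
    "CLUSTER_SIZES",
    "ModelParams",
    "RawParams",
    "ModelData",
    "FitConfig",
    "PosteriorDraws",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "noncentered_transform",
    "fit",
]

#: Cluster sizes of the study: (levels, categories, specimens, subspecialties).
CLUSTER_SIZES = {
    "beta": len(LEVELS),
    "gamma": len(CATEGORIES),
    "delta": len(SPECIMENS),
    "epsilon": len(SUBSPECIALTIES),
}

_SIGMA_NAMES = ("sigma_alpha", "sigma_beta", "sigma_gamma", "sigma_delta", "sigma_epsilon")


@dataclass
class ModelParams:
    """All model parameters on the natural (constrained) scale."""

    alpha_bar: float
    sigma_alpha: float
    sigma_beta: float
    sigma_gamma: float
    sigma_delta: float
    sigma_epsilon: float
    alpha: np.ndarray     # per-rater intercepts
    beta: np.ndarray      # career-level effects (4)
    gamma: np.ndarray     # task-category effects (5)
    delta: np.ndarray     # specimen effects (2)
    epsilon: np.ndarray   # subspecialty effects (3)

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        for name, size in CLUSTER_SIZES.items():
            vec = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if vec.size != size:
                raise ValidationError(f"{name} must have length {size}, got {vec.size}")
            setattr(self, name, vec)

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _SIGMA_NAMES])

    @classmethod
    def zeros(cls, n_raters: int = 17) -> "ModelParams":
        return cls(
            alpha_bar=0.0,
            sigma_alpha=1.0,
            sigma_beta=1.0,
            sigma_gamma=1.0,
            sigma_delta=1.0,
            sigma_epsilon=1.0,
            alpha=np.zeros(n_raters),
            beta=np.zeros(4),
            gamma=np.zeros(5),
            delta=np.zeros(2),
            epsilon=np.zeros(3),
        )


@dataclass
class RawParams:
    """Non-centred coordinates: hyperparameters plus standard-normal offsets."""

    alpha_bar: float
    sigma_alpha: float
    sigma_beta: float
    sigma_gamma: float
    sigma_delta: float
    sigma_epsilon: float
    z_alpha: np.ndarray
    z_beta: np.ndarray
    z_gamma: np.ndarray
    z_delta: np.ndarray
    z_epsilon: np.ndarray


def noncentered_transform(raw: RawParams) -> ModelParams:
    """Map standard-normal offsets to natural-scale effects.

    ``alpha_j = alpha_bar + sigma_alpha * z_j``; the zero-centred clusters
    scale as ``sigma_k * z_j``.  Bijective given the hyperparameters.
    """
    return ModelParams(
        alpha_bar=raw.alpha_bar,
        sigma_alpha=raw.sigma_alpha,
        sigma_beta=raw.sigma_beta,
        sigma_gamma=raw.sigma_gamma,
        sigma_delta=raw.sigma_delta,
        sigma_epsilon=raw.sigma_epsilon,
        alpha=raw.alpha_bar + raw.sigma_alpha * np.asarray(raw.z_alpha, dtype=float),
        beta=raw.sigma_beta * np.asarray(raw.z_beta, dtype=float),
        gamma=raw.sigma_gamma * np.asarray(raw.z_gamma, dtype=float),
        delta=raw.sigma_delta * np.asarray(raw.z_delta, dtype=float),
        epsilon=raw.sigma_epsilon * np.asarray(raw.z_epsilon, dtype=float),
    )


# ---------------------------------------------------------------------------
# Data container


@dataclass(frozen=True)
class ModelData:
    """Answered items coded as integer index arrays for the likelihood."""

    w: np.ndarray        # error indicator, 0/1
    pid: np.ndarray      # rater index into design.participants order
    level: np.ndarray
    category: np.ndarray
    specimen: np.ndarray
    subspecialty: np.ndarray
    participant_ids: tuple[str, ...]

    @classmethod
    def from_items(cls, items: Sequence[ResponseItem], design: StudyDesign) -> "ModelData":
        pid_order = {p: i for i, p in enumerate(design.participant_ids)}
        level_of = {p.id: LEVELS.index(p.career_level) for p in design.participants}
        case_of = {c.id: c for c in design.cases}
        w, pid, lvl, cat, spec, subsp = [], [], [], [], [], []
        for it in items:
            if it.outcome == "missing":
                raise ValidationError(
                    "likelihood uses complete cases only; filter missing items first"
                )
            c = case_of[it.case_id]
            w.append(1 if it.outcome == "error" else 0)
            pid.append(pid_order[it.participant_id])
            lvl.append(level_of[it.participant_id])
            cat.append(it.category - 1)
            spec.append(SPECIMENS.index(c.specimen))
            subsp.append(SUBSPECIALTIES.index(c.subspecialty))
        if not w:
            raise ValidationError("at least one answered item is required")
        return cls(
            w=np.array(w),
            pid=np.array(pid),
            level=np.array(lvl),
            category=np.array(cat),
            specimen=np.array(spec),
            subspecialty=np.array(subsp),
            participant_ids=design.participant_ids,
        )

    @property
    def n_items(self) -> int:
        return self.w.size

    @property
    def n_raters(self) -> int:
        return len(self.participant_ids)

def answered_only(items: Sequence[ResponseItem]) -> list[ResponseItem]:
    """Complete cases: drop items with a missing outcome."""
    return [it for it in items if it.outcome != "missing"]


# ---------------------------------------------------------------------------
# Densities


def _linear_predictor(params: ModelParams, data: ModelData) -> np.ndarray:
    return (
        params.alpha[data.pid]
        + params.beta[data.level]
        + params.gamma[data.category]
        + params.delta[data.specimen]
        + params.epsilon[data.subspecialty]
    )


def log_likelihood(params: ModelParams, data: ModelData) -> float:
    """Bernoulli log likelihood of the error indicators.

    Computed as ``-sum(log1pexp(s_i * eta_i))`` with ``s_i = 1 - 2 W_i``,
    which is exact and stable for any magnitude of the linear predictor.
    """
    if params.alpha.size != data.n_raters:
        raise ValidationError(
            f"alpha has length {params.alpha.size} but data index {data.n_raters} raters"
        )
    eta = _linear_predictor(params, data)
    sign = 1.0 - 2.0 * data.w
    return float(-np.sum(np.logaddexp(0.0, sign * eta)))


_HYPER_SD = 1.5  # prior SD of the grand-mean intercept


def log_prior(params: ModelParams) -> float:
    """Joint log prior density; ``-inf`` outside the support (SD <= 0)."""
    sig = params.sigmas
    if np.any(sig <= 0):
        return -np.inf
    lp = -0.5 * (params.alpha_bar / _HYPER_SD) ** 2 - np.log(_HYPER_SD) - 0.5 * np.log(2 * np.pi)
    lp += float(-np.sum(sig))  # Exponential(1) on each SD
    for vec, mean, sd in (
        (params.alpha, params.alpha_bar, params.sigma_alpha),
        (params.beta, 0.0, params.sigma_beta),
        (params.gamma, 0.0, params.sigma_gamma),
        (params.delta, 0.0, params.sigma_delta),
        (params.epsilon, 0.0, params.sigma_epsilon),
    ):
        n = vec.size
        lp += float(
            -0.5 * np.sum(((vec - mean) / sd) ** 2)
            - n * np.log(sd)
            - 0.5 * n * np.log(2 * np.pi)
        )
    return float(lp)


def log_posterior(params: ModelParams, data: ModelData) -> float:
    """Unnormalised log posterior on the natural scale."""
    lp = log_prior(params)
    if not np.isfinite(lp):
        return lp
    return lp + log_likelihood(params, data)


# ---------------------------------------------------------------------------
# Unconstrained-space densities and gradients for the sampler
#
# Layout (dim = 6 + n_raters + 14):
#   [alpha_bar, log sigma_(alpha,beta,gamma,delta,epsilon),
#    offsets_alpha (n_raters), offsets_beta (4), offsets_gamma (5),
#    offsets_delta (2), offsets_epsilon (3)]
# In the non-centred parametrization the offsets are the standard-normal z;
# in the centred one they are the natural-scale effects themselves.


def _slices(n_raters: int):
    sizes = [n_raters, 4, 5, 2, 3]
    out = []
    start = 6
    for s in sizes:
        out.append(slice(start, start + s))
        start += s
    return out, start


def _unpack(x: np.ndarray, n_raters: int, noncentered: bool) -> ModelParams:
    sl, _ = _slices(n_raters)
    sig = np.exp(x[1:6])
    vecs = [x[s] for s in sl]
    if noncentered:
        raw = RawParams(
            alpha_bar=float(x[0]),
            sigma_alpha=sig[0],
            sigma_beta=sig[1],
            sigma_gamma=sig[2],
            sigma_delta=sig[3],
            sigma_epsilon=sig[4],
            z_alpha=vecs[0],
            z_beta=vecs[1],
            z_gamma=vecs[2],
            z_delta=vecs[3],
            z_epsilon=vecs[4],
        )
        return noncentered_transform(raw)
    return ModelParams(
        alpha_bar=float(x[0]),
        sigma_alpha=sig[0],
        sigma_beta=sig[1],
        sigma_gamma=sig[2],
        sigma_delta=sig[3],
        sigma_epsilon=sig[4],
        alpha=vecs[0],
        beta=vecs[1],
        gamma=vecs[2],
        delta=vecs[3],
        epsilon=vecs[4],
    )


def _make_logp_grad(data: ModelData | None, n_raters: int, noncentered: bool,
                    likelihood: bool = True):
    """Closure computing (log density, gradient) in unconstrained coordinates.

    The Exponential(1) priors on the SDs are expressed through
    ``sigma = exp(u)`` with the log-Jacobian ``u`` added, so the sampler
    works on an unbounded space.
    """
    sl, dim = _slices(n_raters)
    sizes = np.array([n_raters, 4, 5, 2, 3])

    if data is not None:
        # Aggregate items sharing a (rater, level, category, specimen,
        # subspecialty) cell into binomial counts: exact for the posterior
        # (the binomial coefficient is constant in the parameters) and much
        # cheaper per gradient evaluation.
        code = np.ravel_multi_index(
            (data.pid, data.level, data.category, data.specimen, data.subspecialty),
            tuple(sizes),
        )
        uniq, inv = np.unique(code, return_inverse=True)
        n_cell = np.bincount(inv).astype(float)
        e_cell = np.bincount(inv, weights=data.w)
        cell_idx = np.array(np.unravel_index(uniq, tuple(sizes)))
        c_pid, c_level, c_cat, c_spec, c_subsp = cell_idx

    def logp_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return _logp_grad_inner(x)

    def _logp_grad_inner(x: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros(dim)
        alpha_bar = x[0]
        u = x[1:6]
        sig = np.exp(u)
        vecs = [x[s] for s in sl]

        # hyperpriors: alpha_bar ~ N(0, 1.5); sigma_k ~ Exp(1) with Jacobian
        lp = -0.5 * (alpha_bar / _HYPER_SD) ** 2
        grad[0] += -alpha_bar / _HYPER_SD**2
        lp += np.sum(-sig + u)
        grad[1:6] += -sig + 1.0

        if noncentered:
            # offsets are standard normal
            for s, v in zip(sl, vecs):
                lp += -0.5 * np.sum(v * v)
                grad[s] += -v
            alpha = alpha_bar + sig[0] * vecs[0]
            effs = [alpha] + [sig[k] * vecs[k] for k in range(1, 5)]
        else:
            # centred: effects carry their hierarchical normal priors
            for k, (s, v) in enumerate(zip(sl, vecs)):
                mean = alpha_bar if k == 0 else 0.0
                resid = (v - mean) / sig[k]
                lp += -0.5 * np.sum(resid**2) - sizes[k] * u[k]
                grad[s] += -resid / sig[k]
                if k == 0:
                    grad[0] += np.sum(resid / sig[k])
                grad[1 + k] += np.sum(resid**2) - sizes[k]
            effs = vecs

        if likelihood and data is not None:
            # |eta| > 500 saturates the Bernoulli terms; clipping avoids
            # inf*0 artifacts on wildly divergent proposals (rejected anyway)
            eta = np.clip(
                effs[0][c_pid]
                + effs[1][c_level]
                + effs[2][c_cat]
                + effs[3][c_spec]
                + effs[4][c_subsp],
                -500.0,
                500.0,
            )
            lp += -np.sum(
                e_cell * np.logaddexp(0.0, -eta) + (n_cell - e_cell) * np.logaddexp(0.0, eta)
            )
            r = e_cell - n_cell * expit(eta)  # d loglik / d eta per cell
            g_eff = [
                np.bincount(idx, weights=r, minlength=n)
                for idx, n in zip((c_pid, c_level, c_cat, c_spec, c_subsp), sizes)
            ]
            if noncentered:
                grad[0] += np.sum(g_eff[0])
                for k, s in enumerate(sl):
                    grad[s] += sig[k] * g_eff[k]
                    # d eta/d u_k = sigma_k * z (chain rule through sigma)
                    grad[1 + k] += sig[k] * np.dot(g_eff[k], vecs[k])
            else:
                for k, s in enumerate(sl):
                    grad[s] += g_eff[k]
        return float(lp), grad

    return logp_grad, dim


# ---------------------------------------------------------------------------
# Fitting


@dataclass(frozen=True)
class FitConfig:
    """MCMC configuration."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    target_accept: float = 0.95
    seed: int = 0
    parametrization: str = "noncentered"
    prior_only: bool = False  # sampler check: draw from the prior alone

    def validate(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_samples) < 1:
            raise ValidationError("chain, warmup and sample counts must be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ValidationError("target_accept must be in (0, 1)")
        if self.parametrization not in ("centered", "noncentered"):
            raise ValidationError("parametrization must be 'centered' or 'noncentered'")


@dataclass
class PosteriorDraws:
    """Labelled posterior draws with convergence diagnostics.

    ``draws`` maps parameter name to an array of shape (chains, samples)
    for scalars or (chains, samples, k) for cluster vectors, always on the
    natural scale.
    """

    draws: dict[str, np.ndarray]
    n_divergent: int
    diagnostics: pd.DataFrame  # per scalar parameter: rhat, ess_bulk
    warnings: list[str]
    config: FitConfig
    accept_rate: float

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All draws of one parameter pooled across chains."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def max_rhat(self) -> float:
        return float(self.diagnostics["rhat"].max())

    @property
    def min_ess(self) -> float:
        return float(self.diagnostics["ess_bulk"].min())

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(posterior=self.draws)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per draw, one column per scalar parameter, plus chain/draw."""
        n_c, n_s = self.n_chains, self.n_samples
        cols: dict[str, np.ndarray] = {
            "chain": np.repeat(np.arange(n_c), n_s),
            "draw": np.tile(np.arange(n_s), n_c),
        }
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                cols[name] = arr.reshape(-1)
            else:
                for k in range(arr.shape[2]):
                    cols[f"{name}[{k + 1}]"] = arr[:, :, k].reshape(-1)
        return pd.DataFrame(cols)

    def params_at(self, chain: int, draw: int) -> ModelParams:
        d = self.draws
        return ModelParams(
            alpha_bar=float(d["alpha_bar"][chain, draw]),
            sigma_alpha=float(d["sigma_alpha"][chain, draw]),
            sigma_beta=float(d["sigma_beta"][chain, draw]),
            sigma_gamma=float(d["sigma_gamma"][chain, draw]),
            sigma_delta=float(d["sigma_delta"][chain, draw]),
            sigma_epsilon=float(d["sigma_epsilon"][chain, draw]),
            alpha=d["alpha"][chain, draw],
            beta=d["beta"][chain, draw],
            gamma=d["gamma"][chain, draw],
            delta=d["delta"][chain, draw],
            epsilon=d["epsilon"][chain, draw],
        )


_VECTOR_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon")


def fit(
    items: Sequence[ResponseItem] | None,
    design: StudyDesign,
    config: FitConfig | None = None,
) -> PosteriorDraws:
    """Sample the posterior of the hierarchical error model by adaptive HMC.

    ``items`` may include missing outcomes (they are dropped: complete-case
    likelihood).  With ``config.prior_only`` the likelihood is switched off
    and the sampler must recover the prior — a correctness check.
    Convergence problems (any split-R-hat above 1.01, any divergent
    transition) are attached as warnings, never silenced.
    """
    config = config or FitConfig()
    config.validate()
    n_raters = len(design.participants)
    if config.prior_only:
        data = None
    else:
        if items is None:
            raise ValidationError("items are required unless prior_only is set")
        answered = answered_only(items)
        if not answered:
            raise ValidationError("no answered items to fit")
        data = ModelData.from_items(answered, design)
        observed = [np.unique(ix) for ix in (data.pid, data.level, data.category,
                                             data.specimen, data.subspecialty)]
        sizes = [n_raters, 4, 5, 2, 3]
        unseen = [int(n - len(obs)) for n, obs in zip(sizes, observed)]

    noncentered = config.parametrization == "noncentered"
    logp_grad, dim = _make_logp_grad(data, n_raters, noncentered,
                                     likelihood=not config.prior_only)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    n_divergent = 0
    accept = 0.0
    for cs in seeds:
        rng = np.random.default_rng(cs)
        x0 = rng.uniform(-0.5, 0.5, size=dim)
        res = _hmc.sample_chain(
            logp_grad,
            x0,
            n_warmup=config.n_warmup,
            n_samples=config.n_samples,
            rng=rng,
            target_accept=config.target_accept,
        )
        chains.append(res.draws)
        n_divergent += res.n_divergent
        accept += res.accept_rate
    accept /= config.n_chains

    raw = np.stack(chains)  # (chains, samples, dim)
    draws = _constrain_draws(raw, n_raters, noncentered)
    diagnostics = _diagnostics_table(draws)
    warnings: list[str] = []
    if n_divergent > 0:
        warnings.append(f"{n_divergent} divergent transitions after warmup")
    bad = diagnostics[diagnostics["rhat"] > 1.01]
    if not bad.empty:
        warnings.append(
            "R-hat above 1.01 for: " + ", ".join(bad["parameter"].tolist())
        )
    if data is not None and any(unseen):
        warnings.append(f"cluster levels never observed in data: {unseen}")
    return PosteriorDraws(
        draws=draws,
        n_divergent=n_divergent,
        diagnostics=diagnostics,
        warnings=warnings,
        config=config,
        accept_rate=accept,
    )


def _constrain_draws(raw: np.ndarray, n_raters: int, noncentered: bool) -> dict[str, np.ndarray]:
    n_c, n_s, _ = raw.shape
    sl, _dim = _slices(n_raters)
    sig = np.exp(raw[:, :, 1:6])
    out: dict[str, np.ndarray] = {"alpha_bar": raw[:, :, 0]}
    for k, name in enumerate(_SIGMA_NAMES):
        out[name] = sig[:, :, k]
    for k, name in enumerate(_VECTOR_NAMES):
        v = raw[:, :, sl[k]]
        if noncentered:
            scale = sig[:, :, k][:, :, None]
            v = v * scale
            if name == "alpha":
                v = v + raw[:, :, 0][:, :, None]
        out[name] = v
    return out


def _diagnostics_table(draws: dict[str, np.ndarray]) -> pd.DataFrame:
    import arviz as az

    rows = []
    for name, arr in draws.items():
        if arr.ndim == 2:
            entries = {name: arr}
        else:
            entries = {f"{name}[{k + 1}]": arr[:, :, k] for k in range(arr.shape[2])}
        for label, a in entries.items():
            rows.append(
                {
                    "parameter": label,
                    "rhat": float(az.rhat(a)),
                    "ess_bulk": float(az.ess(a, method="bulk")),
                    "mean": float(a.mean()),
                    "sd": float(a.std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)
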