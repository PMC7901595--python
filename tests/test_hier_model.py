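"""Likelihood/prior densities, the non-centred map, and sampler validation."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from dpconcord.data_model import ValidationError
from dpconcord.hier_model import (
    FitConfig,
    ModelData,
    ModelParams,
    RawParams,
    answered_only,
    fit,
    log_likelihood,
    log_posterior,
    log_prior,
    noncentered_transform,
)
from dpconcord.synthetic_study import GenerativeParams, generate_design, simulate_responses

# --- oracles ---------------------------------------------------------------


def brute_force_log_posterior(params: ModelParams, data: ModelData) -> float:
    """Independent per-item / per-density implementation (naive loops)."""
    lp = stats.norm.logpdf(params.alpha_bar, 0.0, 1.5)
    for s in params.sigmas:
        if s <= 0:
            return -math.inf
        lp += stats.expon.logpdf(s)
    for j in range(params.alpha.size):
        lp += stats.norm.logpdf(params.alpha[j], params.alpha_bar, params.sigma_alpha)
    for vec, sd in (
        (params.beta, params.sigma_beta),
        (params.gamma, params.sigma_gamma),
        (params.delta, params.sigma_delta),
        (params.epsilon, params.sigma_epsilon),
    ):
        for v in vec:
            lp += stats.norm.logpdf(v, 0.0, sd)
    for i in range(data.n_items):
        eta = (
            params.alpha[data.pid[i]]
            + params.beta[data.level[i]]
            + params.gamma[data.category[i]]
            + params.delta[data.specimen[i]]
            + params.epsilon[data.subspecialty[i]]
        )
        p = expit(eta)
        lp += math.log(p) if data.w[i] == 1 else math.log1p(-p)
    return lp


def random_params(rng, n_raters=17):
    return ModelParams(
        alpha_bar=rng.normal(0, 1.5),
        sigma_alpha=rng.exponential() + 0.05,
        sigma_beta=rng.exponential() + 0.05,
        sigma_gamma=rng.exponential() + 0.05,
        sigma_delta=rng.exponential() + 0.05,
        sigma_epsilon=rng.exponential() + 0.05,
        alpha=rng.normal(-2, 1, n_raters),
        beta=rng.normal(0, 1, 4),
        gamma=rng.normal(0, 1, 5),
        delta=rng.normal(0, 1, 2),
        epsilon=rng.normal(0, 1, 3),
    )


@pytest.fixture(scope="module")
def toy_data():
    design = generate_design()
    items = simulate_responses(
        design, GenerativeParams(alpha_bar=-1.5), seed=8, missing_rate=0.05
    )
    return ModelData.from_items(answered_only(items), design), design, items


# --- likelihood ------------------------------------------------------------


def test_loglik_at_zero_params_is_n_log_half(toy_data):
    data, _, _ = toy_data
    params = ModelParams.zeros()
    assert log_likelihood(params, data) == pytest.approx(data.n_items * math.log(0.5))


def test_loglik_single_item_closed_form():
    from dpconcord.data_model import CaseRecord, Participant, ResponseItem, StudyDesign

    design = StudyDesign(
        (Participant("P1", "junior"),),
        (CaseRecord(1, "breast", "biopsy", "benign",
                    eligible_categories=frozenset({1, 2, 3})),),
    )
    data = ModelData.from_items([ResponseItem("P1", 1, 1, "error")], design)
    params = ModelParams.zeros(1)
    params.alpha[0] = 2.0  # linear predictor 2.0, W = 1
    assert log_likelihood(params, data) == pytest.approx(math.log(expit(2.0)), abs=1e-12)
    assert log_likelihood(params, data) == pytest.approx(-0.126928, abs=1e-6)


def test_missing_items_are_rejected_by_model_data(toy_data):
    _, design, items = toy_data
    with pytest.raises(ValidationError, match="missing"):
        ModelData.from_items(items, design)  # unfiltered: contains missing


# --- prior -----------------------------------------------------------------


def test_log_prior_analytic_value():
    params = ModelParams.zeros()
    expected = (
        stats.norm.logpdf(0, 0, 1.5)
        + 5 * stats.expon.logpdf(1.0)
        + (17 + 4 + 5 + 2 + 3) * stats.norm.logpdf(0, 0, 1)
    )
    assert log_prior(params) == pytest.approx(expected, rel=1e-12)


def test_log_prior_outside_support_is_minus_inf():
    params = ModelParams.zeros()
    params.sigma_alpha = -1.0
    assert log_prior(params) == -math.inf


def test_log_prior_decreases_away_from_mode():
    params = ModelParams.zeros()
    base = log_prior(params)
    far = ModelParams.zeros()
    far.alpha = far.alpha + 2.0  # move every intercept away from alpha_bar
    assert log_prior(far) < base


# --- oracle equivalence ----------------------------------------------------


def test_log_posterior_matches_brute_force(toy_data):
    data, _, _ = toy_data
    rng = np.random.default_rng(42)
    for _ in range(10):
        params = random_params(rng)
        mine = log_posterior(params, data)
        oracle = brute_force_log_posterior(params, data)
        assert mine == pytest.approx(oracle, rel=1e-10)


# --- non-centred map -------------------------------------------------------


def _raw(alpha_bar=0.0, sigmas=(1, 1, 1, 1, 1), z=None):
    z = z or {}
    return RawParams(
        alpha_bar=alpha_bar,
        sigma_alpha=sigmas[0], sigma_beta=sigmas[1], sigma_gamma=sigmas[2],
        sigma_delta=sigmas[3], sigma_epsilon=sigmas[4],
        z_alpha=z.get("alpha", np.zeros(17)),
        z_beta=z.get("beta", np.zeros(4)),
        z_gamma=z.get("gamma", np.zeros(5)),
        z_delta=z.get("delta", np.zeros(2)),
        z_epsilon=z.get("epsilon", np.zeros(3)),
    )


def test_zero_offsets_give_grand_mean_intercepts():
    params = noncentered_transform(_raw(alpha_bar=-1.3))
    assert np.allclose(params.alpha, -1.3)
    assert np.allclose(params.beta, 0) and np.allclose(params.gamma, 0)


def test_noncentered_arithmetic():
    z_alpha = np.zeros(17)
    z_alpha[0] = 2.0
    params = noncentered_transform(_raw(alpha_bar=-2.0, sigmas=(0.5, 1, 1, 1, 1),
                                        z={"alpha": z_alpha}))
    assert params.alpha[0] == pytest.approx(-1.0)


# --- sampler validation ----------------------------------------------------


def test_prior_only_sampling_recovers_the_prior(canonical_design):
    post = fit(None, canonical_design,
               FitConfig(n_chains=4, n_warmup=500, n_samples=500, seed=11, prior_only=True))
    assert post.n_divergent == 0
    ab = post.flat("alpha_bar")
    assert abs(ab.mean()) < 0.15          # prior mean 0, MCSE ~0.04
    assert abs(ab.std() - 1.5) < 0.15     # prior SD 1.5
    for name in ("sigma_alpha", "sigma_beta", "sigma_gamma", "sigma_delta", "sigma_epsilon"):
        s = post.flat(name)
        assert abs(s.mean() - 1.0) < 0.15  # Exponential(1) mean


def test_centered_and_noncentered_fits_agree_on_toy_data():
    """The two parametrizations target the same posterior; their means must
    agree within combined Monte Carlo error on a small dataset."""
    design = generate_design()
    items = simulate_responses(design, GenerativeParams(alpha_bar=-1.0), seed=3,
                               missing_rate=0.0)[:50]
    fits = {
        par: fit(items, design,
                 FitConfig(n_chains=2, n_warmup=600, n_samples=600, seed=5,
                           parametrization=par))
        for par in ("noncentered", "centered")
    }
    for name in ("alpha_bar", "sigma_alpha", "sigma_gamma"):
        means, mcses = [], []
        for post in fits.values():
            row = post.diagnostics.set_index("parameter").loc[name]
            means.append(row["mean"])
            mcses.append(row["sd"] / np.sqrt(max(row["ess_bulk"], 1.0)))
        combined = np.hypot(*mcses)
        assert abs(means[0] - means[1]) < 3 * combined + 1e-6, name


def test_posterior_of_identified_predictor_concentrates():
    """More data pins the identified quantity (the study-average linear
    predictor) even though the grand-mean/cluster-mean split stays
    prior-limited; its posterior SD must drop at 25x replication."""
    def scaled(k, seed):
        from dpconcord.synthetic_study import DesignConfig

        cfg = DesignConfig(
            n_per_subspecialty={"breast": 10 * k, "urology": 5 * k, "gastrointestinal": 10 * k},
            n_per_specimen={"biopsy": 14 * k, "surgery": 11 * k},
            n_per_lesion={"nontumoral": 8 * k, "benign": 7 * k, "malignant": 10 * k},
            grade_split=(5 * k, 5 * k),
            eligibility_counts={1: 25 * k, 2: 16 * k, 3: 25 * k, 4: 10 * k, 5: 9 * k},
            seed=seed,
        )
        return generate_design(cfg)

    truth = GenerativeParams(alpha_bar=-2.0)

    def predictor_sd(k, seed):
        design = scaled(k, seed)
        items = simulate_responses(design, truth, seed=seed + 50, missing_rate=0.0)
        post = fit(items, design, FitConfig(n_chains=2, n_warmup=400, n_samples=400, seed=seed))
        data = ModelData.from_items(items, design)

        def freq(idx, n):
            return np.bincount(idx, minlength=n) / idx.size

        # item-averaged linear predictor per draw (a likelihood-pinned combination)
        eta = (
            post.flat("alpha") @ freq(data.pid, 17)
            + post.flat("beta") @ freq(data.level, 4)
            + post.flat("gamma") @ freq(data.category, 5)
            + post.flat("delta") @ freq(data.specimen, 2)
            + post.flat("epsilon") @ freq(data.subspecialty, 3)
        )
        return eta.std()

    wins = sum(predictor_sd(25, s) < predictor_sd(1, s) for s in (1, 2, 3))
    assert wins >= 2


def test_fit_requires_answered_items(canonical_design):
    with pytest.raises(ValidationError):
        fit([], canonical_design, FitConfig(n_chains=1, n_warmup=10, n_samples=10))


def test_agreement_with_independent_ensemble_sampler():
    """Cross-check the HMC engine against emcee on a small dataset: the two
    samplers must agree on posterior means within Monte Carlo error."""
    emcee = pytest.importorskip("emcee")
    from dpconcord.hier_model import _make_logp_grad

    design = generate_design()
    items = simulate_responses(design, GenerativeParams(alpha_bar=-1.5), seed=13,
                               missing_rate=0.0)[:120]
    data = ModelData.from_items(items, design)
    logp_grad, dim = _make_logp_grad(data, 17, noncentered=True)

    post = fit(items, design, FitConfig(n_chains=2, n_warmup=600, n_samples=600, seed=4))

    def logp(x):
        return logp_grad(x)[0]

    nw = 2 * dim + 2
    rng = np.random.default_rng(99)
    p0 = rng.normal(0, 0.3, size=(nw, dim))
    sampler = emcee.EnsembleSampler(nw, dim, logp)
    state = sampler.run_mcmc(p0, 1500, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=700, flat=True)
    # compare alpha_bar (coordinate 0): generous tolerance, both are MCMC
    hmc_mean = post.flat("alpha_bar").mean()
    emcee_mean = chain[:, 0].mean()
    pooled_sd = post.flat("alpha_bar").std()
    assert abs(hmc_mean - emcee_mean) < 0.5 * pooled_sd
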