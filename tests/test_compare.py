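import numpy as np
import pytest
from scipy import stats

import motifcompare as mc
from motifcompare.compare import bf_category, dic_pd, log_evidence_gd


# ---------------------------------------------------------------------------
# Conjugate toy with analytic evidence
# ---------------------------------------------------------------------------

def _conjugate_toy(n_draws, seed=0, n_obs=20, sigma2=0.25, tau2=4.0):
    """Normal mean with known variance and normal prior: everything closed-form."""
    rng = np.random.default_rng(seed)
    y = rng.normal(0.7, np.sqrt(sigma2), size=n_obs)
    post_var = 1.0 / (n_obs / sigma2 + 1.0 / tau2)
    post_mean = post_var * y.sum() / sigma2
    draws = rng.normal(post_mean, np.sqrt(post_var), size=n_draws)
    logliks = np.array([stats.norm.logpdf(y, m, np.sqrt(sigma2)).sum() for m in draws])
    logpriors = stats.norm.logpdf(draws, 0.0, np.sqrt(tau2))
    # analytic marginal: y ~ N(0, sigma2 I + tau2 J)
    cov = sigma2 * np.eye(n_obs) + tau2 * np.ones((n_obs, n_obs))
    exact = stats.multivariate_normal.logpdf(y, mean=np.zeros(n_obs), cov=cov)
    return draws[:, None], logliks, logpriors, float(exact)


def test_gd_evidence_matches_analytic_marginal():
    draws, lls, lps, exact = _conjugate_toy(10_000)
    est = log_evidence_gd(draws, lls, lps)
    assert abs(est.value - exact) < 0.1
    assert abs(est.value - exact) < 3 * max(est.se, 1e-3)


def test_gd_evidence_is_permutation_invariant():
    draws, lls, lps, _ = _conjugate_toy(4000, seed=1)
    est = log_evidence_gd(draws, lls, lps)
    perm = np.random.default_rng(2).permutation(4000)
    est_p = log_evidence_gd(draws[perm], lls[perm], lps[perm])
    assert est_p.value == pytest.approx(est.value, abs=1e-10)


def test_gd_evidence_stable_under_halving():
    draws, lls, lps, _ = _conjugate_toy(10_000, seed=3)
    full = log_evidence_gd(draws, lls, lps)
    half = log_evidence_gd(draws[:5000], lls[:5000], lps[:5000])
    tol = 3 * np.hypot(full.se, half.se)
    assert abs(full.value - half.value) <= max(tol, 0.02)


def test_gd_evidence_all_nonfinite_is_flagged():
    draws = np.zeros((10, 1))
    est = log_evidence_gd(draws, np.full(10, -np.inf), np.zeros(10))
    assert est.flagged and est.value == -np.inf


def test_gd_evidence_needs_enough_draws():
    with pytest.raises(ValueError):
        log_evidence_gd(np.zeros((3, 2)), np.zeros(3), np.zeros(3))


# ---------------------------------------------------------------------------
# DIC / pD
# ---------------------------------------------------------------------------

class _ConstantLikStub:
    """Results stand-in whose likelihood is flat over the posterior draws."""

    class _Model:
        def loglik(self, theta, sigma2):
            return -4.2

    class _Archive:
        def pooled_logliks(self):
            return np.full(100, -4.2)

        def pooled(self):
            return np.zeros((100, 3))

        def posterior_mean(self):
            return np.ones(3)

    model = _Model()
    archive = _Archive()


def test_constant_likelihood_gives_zero_pd():
    out = dic_pd(_ConstantLikStub())
    assert out.pd == pytest.approx(0.0, abs=1e-12)
    assert out.dic == pytest.approx(out.mean_deviance)


def test_dic_identity_on_real_fit(sim_fit):
    d = sim_fit.dic()
    assert d.dic == pytest.approx(d.mean_deviance + d.pd, abs=1e-9)
    assert not d.unstable
    # a well-identified four-rate motif has about 5 sampled parameters but
    # the heavy-tailed noise prior contributes almost nothing
    assert 2.5 < d.pd < 6.0


# ---------------------------------------------------------------------------
# AIC / LRT / Bayes factors
# ---------------------------------------------------------------------------

def test_aic_values():
    assert mc.aic(0.0, 0) == 0.0
    assert mc.aic(100.0, 5) == pytest.approx(-190.0)
    with pytest.raises(ValueError):
        mc.aic(1.0, -1)


def test_lrt_equal_likelihoods():
    r = mc.lrt(50.0, 4, 50.0, 5)
    assert r.statistic == 0.0 and r.pvalue == pytest.approx(1.0)


def test_lrt_boundary_of_significance():
    r = mc.lrt(0.0, 4, 1.92, 5)   # statistic 3.84, df 1
    assert r.pvalue == pytest.approx(0.05, abs=0.002)


def test_lrt_rejects_wrong_ordering():
    with pytest.raises(ValueError):
        mc.lrt(10.0, 5, 11.0, 5)


def test_lrt_clamps_small_negative_statistics():
    with pytest.warns(RuntimeWarning):
        r = mc.lrt(10.0, 4, 9.0, 5)
    assert r.statistic == 0.0


def test_non_nested_pair_is_refused(sim_fit, sim_dataset):
    rc_fit = mc.MotifModel(sim_dataset, "RC").fit(
        mc.ChainConfig(n_chains=2, n_iterations=600, burn_in=300, thinning=5, seed=1))
    with pytest.raises(mc.NotNestedError, match="not nested"):
        mc.lrt_models(sim_fit, rc_fit)


def test_bayes_factor_categories():
    bf, cat = mc.bayes_factor(1.0, 1.0)
    assert bf == 1.0 and cat == "weak"
    assert bf_category(58.55) == "decisive"
    assert bf_category(250.0) == "overwhelming"
    assert bf_category(5.0) == "substantial"
    bf_ij, _ = mc.bayes_factor(1.0, 0.0)
    bf_ji, _ = mc.bayes_factor(0.0, 1.0)
    assert bf_ij * bf_ji == pytest.approx(1.0)


def test_bayes_factor_with_minus_infinite_evidence():
    bf, cat = mc.bayes_factor(-3.0, -np.inf)
    assert np.isinf(bf) and cat == "overwhelming"
    bf2, cat2 = mc.bayes_factor(-np.inf, -np.inf)
    assert np.isnan(bf2) and cat2 == "undefined"


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def test_report_identities_and_gaps(sim_fit, sim_dataset):
    ff_fit = mc.MotifModel(sim_dataset, "FF").fit(
        mc.ChainConfig(n_chains=2, n_iterations=4000, burn_in=2000, thinning=5, seed=5))
    report = mc.rank_models({"SIM": sim_fit, "FF": ff_fit, "FB": None})
    assert report.gaps == ("FB",)
    t = report.table
    for name, res in (("SIM", sim_fit), ("FF", ff_fit)):
        p = res.model.spec.aic_param_count
        assert t.loc["aic", name] == pytest.approx(-2 * t.loc["max_loglik", name] + 2 * p)
        d = res.dic()
        assert t.loc["dic", name] == pytest.approx(d.mean_deviance + d.pd, abs=1e-9)
    bf = report.bayes_factors()
    assert bf.loc["SIM", "FF"] * bf.loc["FF", "SIM"] == pytest.approx(1.0)
    lrt_tab = report.lrt_table()
    assert set(zip(lrt_tab["simple"], lrt_tab["complex"])) == {("SIM", "FF")}
    assert "best by evidence" in str(report)
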