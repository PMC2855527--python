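import numpy as np
import pandas as pd
import pytest

import motifcompare as mc
from motifcompare.model import gelman_rubin, max_likelihood_from_chains
from motifcompare.motifs import ConfigurationError

_LOG_2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def test_loglik_zero_residuals_equals_normalisation():
    """Perfect fit: log L = N log(1/(sigma sqrt(2 pi)))."""
    ds = mc.simulate_motif_dataset("SIM", seed=0, noise_sd=0.0)
    m = mc.MotifModel(ds, "SIM")
    sigma2 = 0.01
    expected = ds.n_records * (-0.5 * np.log(sigma2) - 0.5 * _LOG_2PI)
    got = m.loglik(mc.get_model("SIM").true_params(), sigma2)
    assert got == pytest.approx(expected, abs=1e-5)


def test_loglik_single_record_one_sigma_residual():
    sigma = 0.3
    data = pd.DataFrame([("main", 4.0, "z", np.nan)],
                        columns=["step", "time", "variable", "value"])
    m0 = mc.MotifModel.from_dataframe(data, "SIM")
    clean = m0.predict(np.ones(4))[0]
    data["value"] = clean + sigma
    m = mc.MotifModel.from_dataframe(data, "SIM")
    expected = -0.5 * np.log(sigma**2) - 0.5 * _LOG_2PI - 0.5
    assert m.loglik(np.ones(4), sigma**2) == pytest.approx(expected, abs=1e-8)


def test_loglik_decreases_with_growing_residual():
    ds = mc.simulate_motif_dataset("SIM", seed=1)
    m = mc.MotifModel(ds, "SIM")
    p = mc.get_model("SIM").true_params()
    base = m.loglik(p, 0.0025)
    shifted = dict(p, beta_y=2.0)   # doubles the y residuals
    assert m.loglik(shifted, 0.0025) < base


def test_mismatched_dataset_model_pairs_rejected():
    ds = mc.simulate_ff_dataset("ara", seed=0)
    with pytest.raises(ConfigurationError):
        mc.MotifModel(ds, "SIM")   # no ON/OFF steps in the motif family


# ---------------------------------------------------------------------------
# Archive bookkeeping
# ---------------------------------------------------------------------------

def test_archive_counts_and_shape(sim_fit):
    cfg = sim_fit.archive.config
    assert sim_fit.archive.draws.shape == (
        cfg.n_chains, (cfg.n_iterations - cfg.burn_in) // cfg.thinning, 5)
    assert sim_fit.archive.n_draws == cfg.n_chains * cfg.n_retained


def test_stored_logliks_reproduce_recomputation(sim_fit):
    """Stored traces must match a fresh likelihood evaluation at the draw."""
    model = sim_fit.model
    pooled = sim_fit.archive.pooled()
    lls = sim_fit.archive.pooled_logliks()
    rng = np.random.default_rng(0)
    for idx in rng.choice(pooled.shape[0], size=20, replace=False):
        assert model._loglik_log(pooled[idx]) == pytest.approx(lls[idx], abs=1e-8)


def test_fit_is_seed_reproducible(sim_dataset):
    cfg = mc.ChainConfig(n_chains=2, n_iterations=800, burn_in=400,
                         thinning=4, seed=99)
    a = mc.MotifModel(sim_dataset, "SIM").fit(cfg)
    b = mc.MotifModel(sim_dataset, "SIM").fit(cfg)
    assert np.array_equal(a.archive.draws, b.archive.draws)


def test_archive_csv_roundtrip(tmp_path, sim_fit):
    path = tmp_path / "chains.csv"
    sim_fit.archive.to_csv(path)
    back = mc.ChainArchive.read_csv(path)
    assert back.param_names == sim_fit.archive.param_names
    assert np.allclose(back.draws, sim_fit.archive.draws)
    assert np.allclose(back.logliks, sim_fit.archive.logliks)
    assert back.config == sim_fit.archive.config


def test_max_likelihood_from_chains_is_exhaustive_argmax(sim_fit):
    params, ll = max_likelihood_from_chains(sim_fit.archive)
    # brute-force scan over all stored draws
    pooled_ll = sim_fit.archive.pooled_logliks()
    assert ll == pooled_ll.max()
    best = np.exp(sim_fit.archive.pooled()[np.argmax(pooled_ll)])
    assert np.allclose(list(params.values()), best)
    assert sim_fit.max_loglik == ll


# ---------------------------------------------------------------------------
# Fitted-results surface
# ---------------------------------------------------------------------------

def test_reduced_fit_converges_and_covers_truth(sim_fit):
    rhat = gelman_rubin(sim_fit.archive)
    assert max(rhat.values()) < 1.05
    ci = sim_fit.ci()
    for name in ("beta_y", "alpha_y", "beta_z", "alpha_z"):
        assert ci.loc[name, "lower"] < 1.0 < ci.loc[name, "upper"]


def test_summary_mentions_all_metrics(sim_fit):
    text = sim_fit.summary()
    for token in ("log evidence", "DIC", "pD", "AIC", "R-hat", "sigma2"):
        assert token in text


def test_predict_band_shapes(sim_fit):
    bands = sim_fit.predict_band(n_draws=50, n_times=31)
    assert set(bands) == {"main"}
    times, mean, lo, hi = bands["main"]["z"]
    assert times.shape == mean.shape == lo.shape == hi.shape == (31,)
    assert np.all(lo <= hi)


# ---------------------------------------------------------------------------
# Least squares
# ---------------------------------------------------------------------------

def test_ls_recovers_noiseless_parameters():
    ds = mc.simulate_motif_dataset("SIM", seed=0, noise_sd=0.0)
    res = mc.MotifModel(ds, "SIM").fit_ls()
    for name, value in res.params.items():
        assert value == pytest.approx(1.0, abs=1e-4), name
    assert res.sigma2 == pytest.approx(0.0, abs=1e-10)


def test_ls_unbiased_noise_estimate_formula():
    ds = mc.simulate_motif_dataset("RC", seed=3)
    m = mc.MotifModel(ds, "RC")
    res = m.fit_ls()
    p = len(res.params)
    assert res.sigma2 == pytest.approx(res.rss / (ds.n_records - p), rel=1e-12)
    # noise was generated at sd 0.05
    assert np.sqrt(res.sigma2) == pytest.approx(0.05, rel=0.35)


def test_ls_confidence_intervals_cover_truth():
    ds = mc.simulate_motif_dataset("SIM", seed=4)
    res = mc.MotifModel(ds, "SIM").fit_ls()
    ci = res.ci()
    assert ci is not None
    inside = (ci["lower"] < 1.0) & (1.0 < ci["upper"])
    assert inside.sum() >= 3  # 95% Wald intervals, 4 true-unit rates
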