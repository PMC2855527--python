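"""Random-walk Metropolis with burn-in-only adaptation.

The proposal is a multivariate Gaussian centred on the current state.
During burn-in the proposal is adapted in two stages: a scalar step size
tuned towards a target acceptance rate, and -- once enough burn-in
samples exist -- a covariance-shaped proposal (scaled empirical
covariance of the burn-in draws, the classic 2.38^2/d rule).  All
adaptation freezes at the end of burn-in, so the retained draws come
from a fixed, valid Metropolis kernel.

The target density is supplied as ``log_post(x) -> (log_lik, log_prior)``
so that both components can be archived with every retained draw; a
``-inf`` log likelihood (e.g. a failed ODE solve) auto-rejects the
proposal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChainResult", "MCMCDiagnosticError", "run_chain", "n_retained"]


class MCMCDiagnosticError(RuntimeError):
    """Raised when a chain shows pathological behaviour (e.g. zero acceptance)."""


@dataclass
class ChainResult:
    """Retained draws and traces of a single chain."""

    draws: np.ndarray          # (n_kept, d), sampling (log) scale
    logliks: np.ndarray        # (n_kept,)
    logpriors: np.ndarray      # (n_kept,)
    accept_rate: float
    n_infeasible: int          # proposals rejected because log_lik was -inf
    proposal_scale: float
    proposal_chol: np.ndarray = field(repr=False, default=None)


def n_retained(n_iter: int, burn_in: int, thinning: int) -> int:
    """Number of stored draws: every ``thinning``-th post-burn-in iterate."""
    return (n_iter - burn_in) // thinning


def run_chain(log_post, x0, n_iter, burn_in, thinning, rng, *,
              init_scale=0.2, target_accept=0.3, adapt=True,
              tune_interval=200, cov_start=1000) -> ChainResult:
    """Run one Metropolis chain and return its retained draws.

    Parameters follow the chain protocol of the study: ``burn_in``
    iterations are discarded, then every ``thinning``-th iterate is
    stored.  ``rng`` is a ``numpy.random.Generator``; runs are
    reproducible chain-by-chain.
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    ll, lp = log_post(x)
    if not np.isfinite(ll + lp):
        raise MCMCDiagnosticError("chain started at a point of zero posterior density")

    n_keep = n_retained(n_iter, burn_in, thinning)
    draws = np.empty((n_keep, d))
    lls = np.empty(n_keep)
    lps = np.empty(n_keep)
    burn_buf = np.empty((burn_in, d))

    scale = float(init_scale)
    chol = np.eye(d)
    use_cov = False
    accepted = 0
    window_accepted = 0
    n_infeasible = 0
    kept = 0

    for it in range(n_iter):
        step = rng.standard_normal(d)
        xp = x + scale * (chol @ step)
        llp, lpp = log_post(xp)
        if not np.isfinite(llp):
            n_infeasible += 1
            accept = False
        else:
            log_ratio = (llp + lpp) - (ll + lp)
            accept = log_ratio >= 0 or np.log(rng.uniform()) < log_ratio
        if accept:
            x, ll, lp = xp, llp, lpp
            accepted += 1
            window_accepted += 1

        if it < burn_in:
            burn_buf[it] = x
            if adapt and (it + 1) % tune_interval == 0:
                rate = window_accepted / tune_interval
                window_accepted = 0
                scale *= float(np.exp(rate - target_accept))
                scale = float(np.clip(scale, 1e-4, 1e4))
                if it + 1 >= cov_start:
                    sample = burn_buf[(it + 1) // 2: it + 1]
                    cov = np.cov(sample.T)
                    cov = np.atleast_2d(cov) + 1e-10 * np.eye(d)
                    try:
                        new_chol = np.linalg.cholesky((2.38**2 / d) * cov)
                    except np.linalg.LinAlgError:
                        new_chol = None
                    if new_chol is not None:
                        chol = new_chol
                        if not use_cov:
                            use_cov = True
                            scale = 1.0
        else:
            k = it - burn_in
            if (k + 1) % thinning == 0 and kept < n_keep:
                draws[kept] = x
                lls[kept] = ll
                lps[kept] = lp
                kept += 1

    if accepted == 0:
        raise MCMCDiagnosticError(
            "no proposal was ever accepted; reduce the proposal scale "
            "(init_scale) or check the model/data combination")
    return ChainResult(draws=draws, logliks=lls, logpriors=lps,
                       accept_rate=accepted / n_iter, n_infeasible=n_infeasible,
                       proposal_scale=scale, proposal_chol=chol)


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor, per parameter.

    ``chains`` has shape (m, n, d): m >= 2 chains of n >= 2 retained
    draws.  Classic between/within version: with W the mean within-chain
    variance and B/n the variance of chain means,
    ``R = sqrt(((n-1)/n * W + B/n) / W)``.  Identical chains give exactly 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    m, n, _ = chains.shape
    if m < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    if n < 2:
        raise ValueError("Gelman-Rubin needs at least two draws per chain")
    means = chains.mean(axis=1)
    within = chains.var(axis=1, ddof=1).mean(axis=0)
    between_over_n = means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * within + between_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / within)
    return np.where(within == 0, 1.0, rhat)
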