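"""Model-comparison statistics and ranking reports.

Implements the comparison toolbox applied to each fitted model:

* marginal likelihood ("model evidence") p(Y|M) by the Gelfand-Dey
  reciprocal importance sampler over posterior draws, with a
  multivariate-t auxiliary density fitted to the sample;
* the deviance information criterion DIC = D-bar + pD, with the
  effective number of parameters pD = D-bar - D(theta-bar);
* AIC = -2 max log-likelihood + 2p (p excludes the noise variance);
* likelihood-ratio tests for nested model pairs;
* Bayes factors with the conventional interpretation scale
  (>1 weak, >3 substantial, >10 decisive, >100 overwhelming).

Evidence is computed in the sampling (log-parameter) space with the
change-of-variables Jacobian inside the prior density, so the estimate
is parameterisation-consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .motifs import ConfigurationError

__all__ = [
    "EvidenceEstimate",
    "DICStats",
    "LRTResult",
    "NotNestedError",
    "log_evidence_gd",
    "dic_pd",
    "aic",
    "lrt",
    "lrt_models",
    "bayes_factor",
    "bf_category",
    "rank_models",
    "ComparisonReport",
]


class NotNestedError(ConfigurationError):
    """LRT requested for a non-nested model pair."""


@dataclass
class EvidenceEstimate:
    """Gelfand-Dey log-evidence estimate with a batch-based Monte-Carlo SE."""

    value: float
    se: float
    t_dof: int
    n_draws: int
    flagged: bool = False   # True when every draw had non-finite density

    def __float__(self):
        return float(self.value)


@dataclass
class DICStats:
    """DIC decomposition: DIC = mean deviance + pD."""

    dic: float
    pd: float
    mean_deviance: float
    deviance_at_mean: float
    unstable: bool = False


@dataclass
class LRTResult:
    statistic: float
    df: int
    pvalue: float


def _mvt_logpdf(x: np.ndarray, mean: np.ndarray, scale: np.ndarray, dof: float):
    """Log density of a multivariate t at rows of ``x``."""
    d = mean.size
    diff = x - mean
    try:
        chol = cho_factor(scale, lower=True)
    except np.linalg.LinAlgError:
        warnings.warn("singular draw covariance: ridge-regularising the "
                      "auxiliary density", RuntimeWarning)
        scale = scale + 1e-8 * np.eye(d)
        chol = cho_factor(scale, lower=True)
    maha = np.einsum("ij,ij->i", diff, cho_solve(chol, diff.T).T)
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    return (gammaln((dof + d) / 2) - gammaln(dof / 2)
            - 0.5 * d * np.log(dof * np.pi) - 0.5 * logdet
            - 0.5 * (dof + d) * np.log1p(maha / dof))


def log_evidence_gd(draws: np.ndarray, logliks: np.ndarray, logpriors: np.ndarray,
                    *, t_dof: int = 4, n_batches: int = 20) -> EvidenceEstimate:
    """Reciprocal-importance-sampling estimate of log p(Y|M).

    ``draws`` are posterior samples in the sampling (log) space with
    matching per-draw log likelihoods and log priors (Jacobians
    included).  The auxiliary density h is a multivariate t (location =
    sample mean, scale = sample covariance, ``t_dof`` degrees of
    freedom); the estimator averages h/(likelihood x prior) over the
    draws and returns the negative log of that average, computed with a
    stable log-sum-exp.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[:, None]
    logliks = np.asarray(logliks, dtype=float)
    logpriors = np.asarray(logpriors, dtype=float)
    finite = np.isfinite(logliks) & np.isfinite(logpriors)
    if not finite.any():
        return EvidenceEstimate(value=-np.inf, se=np.nan, t_dof=t_dof,
                                n_draws=0, flagged=True)
    draws, logliks, logpriors = draws[finite], logliks[finite], logpriors[finite]
    n, d = draws.shape
    if n < 2 * d:
        raise ValueError("need at least 2 x dim draws for the evidence estimate")
    mean = draws.mean(axis=0)
    cov = np.atleast_2d(np.cov(draws.T))
    log_h = _mvt_logpdf(draws, mean, cov, float(t_dof))
    core = log_h - logliks - logpriors
    value = -(logsumexp(core) - np.log(n))
    n_batches = min(n_batches, n)
    edges = np.linspace(0, n, n_batches + 1).astype(int)
    batch_vals = np.array([
        -(logsumexp(core[a:b]) - np.log(b - a))
        for a, b in zip(edges[:-1], edges[1:]) if b > a])
    se = float(batch_vals.std(ddof=1) / np.sqrt(batch_vals.size))
    return EvidenceEstimate(value=float(value), se=se, t_dof=t_dof, n_draws=n)


def dic_pd(results, *, log_scale_mean: bool = False) -> DICStats:
    """DIC and effective parameter count from a fitted model.

    ``D-bar`` averages the deviance -2 log p(y|theta_s) over the retained
    draws; ``D(theta-bar)`` evaluates it at the posterior parameter
    means.  Means are taken on the natural parameter scale by default
    (``log_scale_mean=True`` uses geometric means instead).  A failed
    solve at the plug-in point flags the estimate unstable.
    """
    archive = results.archive
    lls = archive.pooled_logliks()
    finite = np.isfinite(lls)
    mean_dev = float(-2.0 * lls[finite].mean())
    if log_scale_mean:
        theta_bar = np.exp(archive.pooled().mean(axis=0))
    else:
        theta_bar = archive.posterior_mean()
    ll_at_mean = results.model.loglik(theta_bar[:-1], float(theta_bar[-1]))
    unstable = not np.isfinite(ll_at_mean)
    dev_at_mean = float(-2.0 * ll_at_mean)
    p_d = mean_dev - dev_at_mean
    return DICStats(dic=mean_dev + p_d, pd=p_d, mean_deviance=mean_dev,
                    deviance_at_mean=dev_at_mean, unstable=unstable)


def aic(max_loglik: float, p: int) -> float:
    """Akaike information criterion, -2 log L_max + 2p (lower is better)."""
    if p < 0:
        raise ValueError("parameter count must be non-negative")
    return -2.0 * float(max_loglik) + 2.0 * p


def lrt(loglik_simple: float, p_simple: int, loglik_complex: float,
        p_complex: int, *, tol: float = 1e-9) -> LRTResult:
    """Likelihood-ratio test of a nested pair.

    The statistic 2 (log L_c - log L_s) is referred to a chi-squared
    distribution with ``p_complex - p_simple`` degrees of freedom.  A
    slightly negative statistic (within sampler/optimiser noise) is
    clamped to zero with a warning.
    """
    if p_complex <= p_simple:
        raise ValueError("the complex model must have more parameters")
    stat = 2.0 * (float(loglik_complex) - float(loglik_simple))
    if stat < -tol:
        warnings.warn(
            f"complex model fits worse than the simple one (statistic {stat:.3g}); "
            "clamping to 0 -- check convergence of the fits", RuntimeWarning)
    stat = max(stat, 0.0)
    df = int(p_complex - p_simple)
    return LRTResult(statistic=stat, df=df, pvalue=float(chi2.sf(stat, df)))


def lrt_models(results_simple, results_complex) -> LRTResult:
    """LRT between two fitted models, refusing non-nested pairs."""
    simple, complex_ = results_simple.model.spec, results_complex.model.spec
    if simple.name not in complex_.nests:
        raise NotNestedError(
            f"The LRT cannot be applied to the {simple.name}/{complex_.name} "
            "pair because the models are not nested")
    return lrt(results_simple.max_loglik, simple.aic_param_count,
               results_complex.max_loglik, complex_.aic_param_count)


def bf_category(bf: float) -> str:
    """Conventional evidence categories for a Bayes factor."""
    if np.isnan(bf):
        return "undefined"
    if bf > 100:
        return "overwhelming"
    if bf > 10:
        return "decisive"
    if bf > 3:
        return "substantial"
    if bf >= 1:
        return "weak"
    return "favours the other model"


def bayes_factor(log_evidence_i: float, log_evidence_j: float):
    """Bayes factor of model i over model j with its interpretation label."""
    if np.isneginf(log_evidence_i) and np.isneginf(log_evidence_j):
        return np.nan, "undefined"
    bf = float(np.exp(log_evidence_i - log_evidence_j))
    return bf, bf_category(bf)


_MEASURES = ("log_evidence", "dic", "pd", "max_loglik", "aic")
_HIGHER_BETTER = {"log_evidence": True, "dic": False, "pd": None,
                  "max_loglik": True, "aic": False}


class ComparisonReport:
    """Per-dataset ranking of candidate models over all measures.

    ``table`` holds one column per model and one row per measure
    (log evidence, DIC, pD, maximum log likelihood, AIC).  Models whose
    fit is missing appear as NaN columns and are listed in ``gaps``.
    """

    def __init__(self, fits: Mapping[str, object], meta: dict | None = None,
                 tie_threshold: float = 1.0):
        self.fits = {k: v for k, v in fits.items() if v is not None}
        self.gaps = tuple(k for k, v in fits.items() if v is None)
        self.meta = dict(meta or {})
        self.tie_threshold = float(tie_threshold)
        cols = {}
        for name in fits:
            res = fits.get(name)
            if res is None:
                cols[name] = {m: np.nan for m in _MEASURES}
                continue
            dic = res.dic()
            cols[name] = {
                "log_evidence": res.log_evidence().value,
                "dic": dic.dic,
                "pd": dic.pd,
                "max_loglik": res.max_loglik,
                "aic": res.aic,
            }
        self.table = pd.DataFrame(cols).reindex(list(_MEASURES))

    # ------------------------------------------------------------------
    def best(self, measure: str = "log_evidence") -> str:
        """Best model under one measure (max or min as appropriate)."""
        if _HIGHER_BETTER.get(measure) is None:
            raise ValueError(f"{measure!r} is not a ranking measure")
        row = self.table.loc[measure].dropna()
        return row.idxmax() if _HIGHER_BETTER[measure] else row.idxmin()

    def evidence_ties(self) -> list[tuple[str, str]]:
        """Model pairs whose log evidences differ by < tie_threshold.

        A pragmatic reader may prefer the formally smaller model in a tie;
        the report flags ties but does not enforce that preference.
        """
        row = self.table.loc["log_evidence"].dropna()
        names = list(row.index)
        return [(a, b) for i, a in enumerate(names) for b in names[i + 1:]
                if abs(row[a] - row[b]) < self.tie_threshold]

    def bayes_factors(self) -> pd.DataFrame:
        """Pairwise Bayes factors BF[i, j] = p(Y|M_i)/p(Y|M_j)."""
        row = self.table.loc["log_evidence"]
        names = list(row.index)
        mat = np.exp(row.to_numpy()[:, None] - row.to_numpy()[None, :])
        return pd.DataFrame(mat, index=names, columns=names)

    def lrt_table(self) -> pd.DataFrame:
        """LRT results for every nested pair among the fitted models."""
        rows = []
        for s_name, s_res in self.fits.items():
            for c_name, c_res in self.fits.items():
                if s_name in c_res.model.spec.nests:
                    r = lrt_models(s_res, c_res)
                    rows.append((s_name, c_name, r.statistic, r.df, r.pvalue))
        return pd.DataFrame(rows, columns=["simple", "complex", "statistic",
                                           "df", "pvalue"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def to_json(self, path=None):
        payload = {"table": {c: self.table[c].to_dict() for c in self.table.columns},
                   "best_by_evidence": self.best(),
                   "ties": self.evidence_ties(), "gaps": list(self.gaps),
                   "meta": self.meta}
        if path is None:
            return payload
        import json
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)

    def __str__(self):
        header = self.meta.get("title", "Model comparison")
        body = self.table.to_string(float_format=lambda v: f"{v:10.2f}")
        notes = []
        if self.table.loc["log_evidence"].notna().any():
            notes.append(f"best by evidence: {self.best()}")
        ties = self.evidence_ties()
        if ties:
            notes.append("evidence ties (|delta log E| < "
                         f"{self.tie_threshold:g}): {ties}")
        if self.gaps:
            notes.append(f"missing fits: {list(self.gaps)}")
        return "\n".join([header, body] + notes)


def rank_models(fits: Mapping[str, object], meta: dict | None = None,
                tie_threshold: float = 1.0) -> ComparisonReport:
    """Build a :class:`ComparisonReport` from fitted results.

    ``fits`` maps model names to :class:`~motifcompare.model.MCMCResults`
    (or None for a failed fit, which is recorded as a gap).
    """
    return ComparisonReport(fits, meta=meta, tie_threshold=tie_threshold)
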