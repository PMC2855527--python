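"""Model objects: build a motif model on a dataset, fit it, inspect results.

:class:`MotifModel` binds one dynamical model from the registry to one
:class:`~motifcompare.datasets.TimeSeriesDataset` and exposes the
Gaussian log likelihood, a Metropolis sampler (:meth:`MotifModel.fit`)
and a least-squares/maximum-likelihood fit (:meth:`MotifModel.fit_ls`).

The observation model: each record value is the model solution of its
variable at its time plus independent N(0, sigma^2) noise, with a single
noise variance shared by all variables and times.  sigma^2 is treated as
a parameter: the sampler works on ``x = [log theta_1..p, log sigma^2]``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import _kernels
from .datasets import TimeSeriesDataset
from .motifs import ConfigurationError, ModelSpec, get_model
from .priors import PriorSet
from .sampling import MCMCDiagnosticError, gelman_rubin as _psrf, n_retained, run_chain
from .signals import SignalProfile

__all__ = [
    "ChainConfig",
    "ChainArchive",
    "MotifModel",
    "MCMCResults",
    "LSResults",
    "gelman_rubin",
    "max_likelihood_from_chains",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ChainConfig:
    """Sampler protocol: chains, iterations, burn-in, thinning, seed."""

    n_chains: int = 5
    n_iterations: int = 40_000
    burn_in: int = 20_000
    thinning: int = 10
    init_scale: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return n_retained(self.n_iterations, self.burn_in, self.thinning)


#: Reduced protocol used for quick studies and continuous testing.
REDUCED_CONFIG = ChainConfig(n_chains=3, n_iterations=8_000, burn_in=4_000, thinning=10)
#: Full protocol of the study.
FULL_CONFIG = ChainConfig()


@dataclass
class ChainArchive:
    """Post-burn-in, thinned draws of all chains, with density traces.

    ``draws`` has shape (n_chains, n_retained, d) on the sampling (log)
    scale; the last coordinate is log sigma^2.  ``param_names`` are the
    natural-scale names with ``"sigma2"`` appended.
    """

    param_names: tuple[str, ...]
    draws: np.ndarray
    logliks: np.ndarray
    logpriors: np.ndarray
    accept_rates: np.ndarray
    n_infeasible: np.ndarray
    config: ChainConfig

    def __post_init__(self):
        m, n, d = self.draws.shape
        if d != len(self.param_names):
            raise ValueError("draw dimension does not match parameter names")
        if n != self.config.n_retained:
            raise ValueError("retained draw count does not match the chain config")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        """Total pooled draws."""
        return self.draws.shape[0] * self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        """All chains concatenated, sampling scale: (n_draws, d)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def pooled_natural(self) -> np.ndarray:
        return np.exp(self.pooled())

    def pooled_logliks(self) -> np.ndarray:
        return self.logliks.reshape(-1)

    def pooled_logpriors(self) -> np.ndarray:
        return self.logpriors.reshape(-1)

    def posterior_mean(self) -> np.ndarray:
        """Natural-scale posterior means (back-transformed draws averaged)."""
        return self.pooled_natural().mean(axis=0)

    def to_csv(self, path) -> None:
        """Long-format CSV (chain, draw, log params, traces) + config sidecar."""
        path = Path(path)
        m, n, d = self.draws.shape
        frame = pd.DataFrame(self.pooled(), columns=[f"log_{p}" for p in self.param_names])
        frame.insert(0, "draw", np.tile(np.arange(n), m))
        frame.insert(0, "chain", np.repeat(np.arange(m), n))
        frame["loglik"] = self.pooled_logliks()
        frame["logprior"] = self.pooled_logpriors()
        frame.to_csv(path, index=False)
        echo = {"param_names": list(self.param_names),
                "accept_rates": self.accept_rates.tolist(),
                "n_infeasible": self.n_infeasible.tolist(),
                "config": {k: getattr(self.config, k) for k in
                           ("n_chains", "n_iterations", "burn_in", "thinning",
                            "init_scale", "seed")}}
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(echo, fh, indent=2)

    @classmethod
    def read_csv(cls, path) -> "ChainArchive":
        path = Path(path)
        frame = pd.read_csv(path)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            echo = json.load(fh)
        names = tuple(echo["param_names"])
        cfg = ChainConfig(**echo["config"])
        m = int(frame["chain"].max()) + 1
        n = len(frame) // m
        draws = frame[[f"log_{p}" for p in names]].to_numpy().reshape(m, n, len(names))
        return cls(param_names=names, draws=draws,
                   logliks=frame["loglik"].to_numpy().reshape(m, n),
                   logpriors=frame["logprior"].to_numpy().reshape(m, n),
                   accept_rates=np.asarray(echo["accept_rates"], dtype=float),
                   n_infeasible=np.asarray(echo["n_infeasible"]),
                   config=cfg)


@dataclass
class _PreparedStep:
    """Precompiled integration layout for one experimental step."""

    label: str
    x0: tuple[float, float]
    s2: float
    nodes: np.ndarray
    levels: np.ndarray
    nsub: np.ndarray
    obs_node: np.ndarray    # node index per record
    obs_state: np.ndarray   # state index per record
    y_obs: np.ndarray       # observed values per record
    rows: np.ndarray        # dataset row index per record
    t_eval: np.ndarray
    step_init: object
    out: np.ndarray = field(repr=False, default=None)


def _constant_level(value) -> float:
    if isinstance(value, SignalProfile):
        if len(set(value.levels)) != 1:
            raise ConfigurationError("secondary inputs must be constant within a step")
        return float(value.levels[0])
    return float(value)


class MotifModel:
    """One registry model bound to one dataset, ready for inference.

    Parameters
    ----------
    dataset
        Observations; every record's step label must have a canonical
        initialisation in the model's spec, and every observed variable
        must be a state of the model.
    model
        Registry name (e.g. ``"SIM"``, ``"FF.C1.OR.2"``) or a spec.
    priors
        Defaults to the shared study priors.
    dt
        RK4 sub-step for likelihood solves (delay models use ``delay_dt``).
    """

    def __init__(self, dataset: TimeSeriesDataset, model: str | ModelSpec,
                 priors: PriorSet | None = None, *, dt: float = 0.02,
                 delay_dt: float = 0.01):
        self.dataset = dataset
        self.spec = get_model(model)
        self.priors = priors or PriorSet()
        self.dt = float(dt)
        self.delay_dt = float(delay_dt)
        self._steps = self._prepare(dataset)
        self.n_obs = int(sum(s.y_obs.size for s in self._steps))
        self.exog_names = list(self.spec.param_names) + ["sigma2"]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, model: str, **kwargs) -> "MotifModel":
        """Build from a tidy frame with step/time/variable/value columns."""
        if "step" not in data.columns:
            data = data.assign(step="main")
        return cls(TimeSeriesDataset(data=data.copy()), model, **kwargs)

    # ------------------------------------------------------------------
    def _prepare(self, dataset) -> list[_PreparedStep]:
        spec = self.spec
        steps = []
        for label, group in dataset.data.groupby("step", sort=False):
            if label not in spec.steps:
                raise ConfigurationError(
                    f"model {spec.name} has no canonical step {label!r}")
            init = spec.steps[label]
            bad = set(group["variable"]) - set(spec.states)
            if bad:
                raise ConfigurationError(
                    f"dataset variables {sorted(bad)} are not states of {spec.name}")
            t_obs = group["time"].to_numpy(dtype=float)
            t_eval = np.unique(t_obs)
            profile = init.signal("S")
            interior = [b for b in profile.breakpoints if 0.0 < b < t_eval[-1]]
            nodes = np.unique(np.concatenate([[0.0], t_eval, interior]))
            levels = np.atleast_1d(profile(nodes[:-1])).astype(float)
            gaps = np.diff(nodes)
            nsub = np.maximum(np.ceil(gaps / self.dt), 1).astype(np.int64)
            pos_in_nodes = np.searchsorted(nodes, t_eval)
            node_of_time = dict(zip(t_eval, pos_in_nodes))
            obs_node = np.array([node_of_time[t] for t in t_obs], dtype=np.int64)
            obs_state = np.array([spec.states.index(v) for v in group["variable"]],
                                 dtype=np.int64)
            x0 = tuple(init.x0) + (0.0,) * (2 - len(init.x0))
            s2 = _constant_level(init.inputs.get("S2", 1.0))
            steps.append(_PreparedStep(
                label=label, x0=x0, s2=s2, nodes=nodes, levels=levels, nsub=nsub,
                obs_node=obs_node, obs_state=obs_state,
                y_obs=group["value"].to_numpy(dtype=float),
                rows=group.index.to_numpy(), t_eval=t_eval, step_init=init,
                out=np.empty((nodes.size, 2))))
        if not steps:
            raise ValueError("dataset is empty")
        return steps

    # ------------------------------------------------------------------
    def predict(self, params) -> np.ndarray:
        """Noise-free predictions aligned with the dataset rows."""
        theta = self._as_theta(params)
        out = np.empty(len(self.dataset.data))
        for step, pred in zip(self._steps, self._step_predictions(theta)):
            out[step.rows] = pred
        return out

    def _as_theta(self, params) -> np.ndarray:
        if isinstance(params, Mapping):
            return self.spec.params_to_array(params)
        theta = np.asarray(params, dtype=float)
        if theta.size == len(self.spec.param_names) + 1:
            theta = theta[:-1]
        return theta

    def _step_predictions(self, theta: np.ndarray):
        spec = self.spec
        if spec.delayed:
            from .delay import integrate_delayed
            p = dict(zip(spec.param_names, theta))
            for step in self._steps:
                sig = {name: step.step_init.signal(name) for name in spec.inputs}
                traj = integrate_delayed(
                    spec, p, sig, step.t_eval, np.asarray(step.x0[:spec.n_states]),
                    dt=self.delay_dt,
                    s_pre=step.step_init.s_pre.get("S"))
                vals = traj.values if traj.ok else np.full_like(traj.values, np.nan)
                yield vals[np.searchsorted(step.t_eval, step.nodes[step.obs_node]),
                           step.obs_state]
        else:
            for step in self._steps:
                out = _kernels.integrate_nodes(
                    spec.code, theta, step.s2, step.nodes, step.levels, step.nsub,
                    step.x0[0], step.x0[1], step.out)
                yield out[step.obs_node, step.obs_state]

    # ------------------------------------------------------------------
    def loglik(self, params, sigma2: float) -> float:
        """Gaussian log likelihood at natural-scale parameters."""
        if sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        theta = self._as_theta(params)
        ssr = 0.0
        for step, pred in zip(self._steps, self._step_predictions(theta)):
            r = step.y_obs - pred
            ssr += float(np.dot(r, r))
        if not np.isfinite(ssr):
            return -np.inf
        return -0.5 * self.n_obs * (_LOG_2PI + np.log(sigma2)) - 0.5 * ssr / sigma2

    def _loglik_log(self, x: np.ndarray) -> float:
        """Log likelihood at sampling-scale x = [log theta, log sigma2]."""
        return self.loglik(np.exp(x[:-1]), float(np.exp(x[-1])))

    def _log_post(self, x: np.ndarray):
        ll = self._loglik_log(x)
        lp = self.priors.log_prior(x)
        return ll, lp

    # ------------------------------------------------------------------
    def fit(self, config: ChainConfig | None = None, **overrides) -> "MCMCResults":
        """Sample the posterior with adaptive random-walk Metropolis.

        Keyword overrides (``n_chains``, ``n_iterations``, ``burn_in``,
        ``thinning``, ``seed``, ``init_scale``) update ``config``; the
        default is the full study protocol.
        """
        cfg = config or FULL_CONFIG
        if overrides:
            cfg = replace(cfg, **overrides)
        seed = cfg.seed
        if seed is None:
            seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
            cfg = replace(cfg, seed=seed)
        d = len(self.exog_names)
        draws = np.empty((cfg.n_chains, cfg.n_retained, d))
        lls = np.empty((cfg.n_chains, cfg.n_retained))
        lps = np.empty((cfg.n_chains, cfg.n_retained))
        acc = np.empty(cfg.n_chains)
        ninf = np.empty(cfg.n_chains, dtype=np.int64)
        for c in range(cfg.n_chains):
            rng = np.random.default_rng([seed, c])
            x0 = self._initial_point(rng)
            res = run_chain(self._log_post, x0, cfg.n_iterations, cfg.burn_in,
                            cfg.thinning, rng, init_scale=cfg.init_scale)
            draws[c] = res.draws
            lls[c] = res.logliks
            lps[c] = res.logpriors
            acc[c] = res.accept_rate
            ninf[c] = res.n_infeasible
        archive = ChainArchive(param_names=tuple(self.exog_names), draws=draws,
                               logliks=lls, logpriors=lps, accept_rates=acc,
                               n_infeasible=ninf, config=cfg)
        return MCMCResults(self, archive)

    def _initial_point(self, rng, max_tries: int = 50) -> np.ndarray:
        d = len(self.exog_names)
        base = np.zeros(d)
        base[-1] = np.log(self.priors.noise_mode)
        scale = 0.5
        for attempt in range(max_tries):
            x = base + rng.normal(0.0, scale, size=d)
            ll, lp = self._log_post(x)
            if np.isfinite(ll + lp):
                return x
            if attempt > max_tries // 2:
                scale = 0.1
        raise MCMCDiagnosticError(
            f"could not find a feasible starting point for {self.spec.name}")

    # ------------------------------------------------------------------
    def fit_ls(self, n_starts: int = 5, seed: int = 0) -> "LSResults":
        """Least-squares (maximum-likelihood) fit with Hessian-based CIs.

        Minimises the residual sum of squares over log parameters from
        several starting points; the unbiased noise estimate is
        ``RSS/(N - p)`` and 95% confidence intervals are
        ``theta_j +/- 1.96 SE_j`` from the Gauss-Newton Hessian.
        """
        rng = np.random.default_rng(seed)
        p = len(self.spec.param_names)

        def resid(xlog):
            theta = np.exp(xlog)
            r = np.concatenate([step.y_obs - pred for step, pred in
                                zip(self._steps, self._step_predictions(theta))])
            return np.where(np.isfinite(r), r, 1e6)

        best = None
        for k in range(n_starts):
            x0 = np.zeros(p) if k == 0 else rng.normal(0.0, 0.7, size=p)
            try:
                sol = least_squares(resid, x0, method="lm", max_nfev=4000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError(f"least-squares optimisation failed for {self.spec.name}")
        theta = np.exp(best.x)
        rss = float(2.0 * best.cost)
        dof = self.n_obs - p
        sigma2_hat = rss / dof if dof > 0 else np.nan
        # natural-scale Jacobian via the chain rule d r/d theta = (d r/d x)/theta
        jac_nat = best.jac / theta
        jtj = jac_nat.T @ jac_nat
        se = None
        try:
            cov = sigma2_hat * np.linalg.inv(jtj)
            diag = np.diag(cov)
            if np.all(diag >= 0):
                se = np.sqrt(diag)
        except np.linalg.LinAlgError:
            pass
        if se is None:
            warnings.warn("singular Hessian: confidence intervals unavailable",
                          RuntimeWarning)
        sigma2_ml = rss / self.n_obs
        max_ll = (-0.5 * self.n_obs * (_LOG_2PI + np.log(sigma2_ml))
                  - 0.5 * self.n_obs)
        return LSResults(model=self, params=dict(zip(self.spec.param_names, theta)),
                         sigma2=sigma2_hat, rss=rss, se=se, max_loglik=float(max_ll),
                         n_obs=self.n_obs)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def gelman_rubin(archive) -> dict[str, float]:
    """Per-parameter potential scale reduction factor of an archive."""
    if isinstance(archive, ChainArchive):
        vals = _psrf(archive.draws)
        return dict(zip(archive.param_names, vals))
    return dict(enumerate(np.atleast_1d(_psrf(np.asarray(archive)))))


def max_likelihood_from_chains(archive: ChainArchive):
    """Best stored draw: (natural-scale parameter dict, its log likelihood)."""
    lls = archive.pooled_logliks()
    idx = int(np.argmax(lls))
    best = np.exp(archive.pooled()[idx])
    return dict(zip(archive.param_names, best)), float(lls[idx])


class MCMCResults:
    """Posterior sample of one model/dataset pair, with comparison metrics."""

    def __init__(self, model: MotifModel, archive: ChainArchive):
        self.model = model
        self.archive = archive
        self._evidence = None
        self._dic = None

    # --- basic posterior summaries ------------------------------------
    @property
    def param_names(self) -> tuple[str, ...]:
        return self.archive.param_names

    @property
    def posterior_mean(self) -> dict[str, float]:
        """Natural-scale posterior means."""
        return dict(zip(self.param_names, self.archive.posterior_mean()))

    def ci(self, level: float = 0.95) -> pd.DataFrame:
        """Equal-tailed credible intervals from the pooled natural draws."""
        q = 100 * (1 - level) / 2
        nat = self.archive.pooled_natural()
        lo, hi = np.percentile(nat, [q, 100 - q], axis=0)
        return pd.DataFrame({"mean": nat.mean(axis=0), "lower": lo, "upper": hi},
                            index=list(self.param_names))

    def rhat(self) -> dict[str, float]:
        """Gelman-Rubin statistic per parameter (on the sampling scale)."""
        return gelman_rubin(self.archive)

    @property
    def accept_rates(self) -> np.ndarray:
        return self.archive.accept_rates

    # --- likelihood-based metrics -------------------------------------
    @property
    def max_loglik(self) -> float:
        """Highest stored log likelihood across all chains."""
        return float(self.archive.pooled_logliks().max())

    @property
    def ml_params(self) -> dict[str, float]:
        return max_likelihood_from_chains(self.archive)[0]

    @property
    def aic(self) -> float:
        from .compare import aic
        return aic(self.max_loglik, self.model.spec.aic_param_count)

    def log_evidence(self, t_dof: int = 4):
        """Gelfand-Dey reciprocal-importance-sampling evidence estimate."""
        if self._evidence is None or self._evidence.t_dof != t_dof:
            from .compare import log_evidence_gd
            self._evidence = log_evidence_gd(
                self.archive.pooled(), self.archive.pooled_logliks(),
                self.archive.pooled_logpriors(), t_dof=t_dof)
        return self._evidence

    def dic(self):
        """Deviance information criterion and effective parameter count."""
        if self._dic is None:
            from .compare import dic_pd
            self._dic = dic_pd(self)
        return self._dic

    @property
    def pd(self) -> float:
        return self.dic().pd

    # --- posterior predictive -----------------------------------------
    def predict_band(self, n_draws: int = 200, level: float = 0.95,
                     n_times: int = 101, seed: int = 0):
        """Mean solution and credible band of the observed trajectories.

        Returns ``{step: {variable: (times, mean, lower, upper)}}`` using
        ``n_draws`` posterior draws per step.
        """
        rng = np.random.default_rng(seed)
        pooled = self.archive.pooled_natural()
        idx = rng.choice(pooled.shape[0], size=min(n_draws, pooled.shape[0]),
                         replace=False)
        q = 100 * (1 - level) / 2
        spec = self.model.spec
        out = {}
        for step in self.model._steps:
            times = np.linspace(step.t_eval[0], step.t_eval[-1], n_times)
            sub = MotifModel(_grid_dataset(step, times, spec), spec,
                             priors=self.model.priors, dt=self.model.dt,
                             delay_dt=self.model.delay_dt)
            curves = np.array([sub.predict(pooled[i, :-1]) for i in idx])
            per_var = {}
            for var in spec.observed:
                sel = sub.dataset.data["variable"] == var
                vals = curves[:, sel.to_numpy()]
                per_var[var] = (times, vals.mean(axis=0),
                                np.percentile(vals, q, axis=0),
                                np.percentile(vals, 100 - q, axis=0))
            out[step.label] = per_var
        return out

    def summary(self) -> str:
        """Human-readable fit report."""
        spec = self.model.spec
        cfg = self.archive.config
        dic = self.dic()
        ev = self.log_evidence()
        lines = [
            f"Model {spec.name}: {self.model.n_obs} records, "
            f"{cfg.n_chains} chains x {cfg.n_iterations} iterations "
            f"(burn-in {cfg.burn_in}, thinning {cfg.thinning}) "
            f"-> {self.archive.n_draws} draws",
            "-" * 72,
            f"{'parameter':<12}{'mean':>10}{'sd':>10}{'2.5%':>10}{'97.5%':>10}{'R-hat':>8}",
        ]
        nat = self.archive.pooled_natural()
        rhat = self.rhat()
        lo, hi = np.percentile(nat, [2.5, 97.5], axis=0)
        for j, name in enumerate(self.param_names):
            lines.append(f"{name:<12}{nat[:, j].mean():>10.4f}{nat[:, j].std():>10.4f}"
                         f"{lo[j]:>10.4f}{hi[j]:>10.4f}{rhat[name]:>8.3f}")
        lines += [
            "-" * 72,
            f"max log-likelihood {self.max_loglik:>10.2f}    "
            f"AIC {self.aic:>10.2f}  (p = {spec.aic_param_count})",
            f"log evidence (GD) {ev.value:>11.2f}    MC se {ev.se:.3f}",
            f"DIC {dic.dic:>10.2f}    pD {dic.pd:>6.2f}    mean deviance {dic.mean_deviance:.2f}",
            f"acceptance rates: {np.array2string(self.accept_rates, precision=2)}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<MCMCResults {self.model.spec.name}: {self.archive.n_draws} draws, "
                f"max loglik {self.max_loglik:.2f}>")


def _grid_dataset(step, times, spec) -> TimeSeriesDataset:
    rows = [(step.label, float(t), var, np.nan)
            for var in spec.observed for t in times]
    return TimeSeriesDataset(
        data=pd.DataFrame(rows, columns=["step", "time", "variable", "value"]))


@dataclass
class LSResults:
    """Least-squares point fit: estimates, noise variance, confidence intervals."""

    model: MotifModel
    params: dict[str, float]
    sigma2: float          # unbiased RSS/(N - p)
    rss: float
    se: np.ndarray | None
    max_loglik: float      # profile likelihood at the optimum
    n_obs: int

    def ci(self, level: float = 0.95) -> pd.DataFrame | None:
        """Wald intervals theta_j +/- z * SE_j; None when the Hessian is singular."""
        if self.se is None:
            return None
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        theta = np.array(list(self.params.values()))
        return pd.DataFrame({"estimate": theta, "se": self.se,
                             "lower": theta - z * self.se,
                             "upper": theta + z * self.se},
                            index=list(self.params))

    @property
    def aic(self) -> float:
        from .compare import aic
        return aic(self.max_loglik, self.model.spec.aic_param_count)

    def summary(self) -> str:
        lines = [f"Least-squares fit of {self.model.spec.name} "
                 f"({self.n_obs} records)",
                 f"RSS {self.rss:.5f}   sigma2 (unbiased) {self.sigma2:.6f}   "
                 f"max log-likelihood {self.max_loglik:.2f}   AIC {self.aic:.2f}"]
        ci = self.ci()
        lines.append(ci.to_string() if ci is not None
                     else "confidence intervals unavailable (singular Hessian)")
        return "\n".join(lines)
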