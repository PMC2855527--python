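"""Dynamical models of transcription-network motifs.

Sixteen named models are provided, in three groups:

* the four two-gene motifs driven by a stepped input signal S --
  single-input motif (SIM), regulatory chain (RC), feed-forward loop (FF)
  and negative feedback (FB) -- with linear production terms, plus their
  cooperative variants (``.H`` suffix) in which every regulatory input
  acts through a Hill function;
* feed-forward-loop subtypes with explicit cis-regulatory logic:
  coherent type 1 with an AND gate (``FF.C1.AND``, arabinose-like),
  coherent type 1 with an OR gate (``FF.C1.OR.1``, flagella-like) and its
  two delayed refinements (``FF.C1.OR.2``/``FF.C1.OR.3``), and incoherent
  type 1 with an AND gate (``FF.I1.AND``, galactose-like);
* the matching non-feed-forward control circuits (``CONTROL.ARA``,
  ``CONTROL.FLA``, ``CONTROL.GAL``).

State variables are named uniformly: ``y`` is the intermediate regulator
and ``z`` the target product (one-state controls only have ``z``).
Inputs are ``S`` (the primary signal) and, for the two-input controls,
``S2`` (the secondary, independently controlled signal).  All Hill
functions use a fixed cooperativity h = 2; thresholds are fixed at 0.5
where a model does not estimate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .signals import STEP_PROTOCOL, SignalProfile

__all__ = [
    "HILL_COEF",
    "DEFAULT_THRESHOLD",
    "InvalidParameterError",
    "ConfigurationError",
    "ContractViolation",
    "hill_activation",
    "hill_repression",
    "gate",
    "StepInit",
    "ModelSpec",
    "Trajectory",
    "MODELS",
    "get_model",
    "eval_rhs",
    "integrate",
]

#: Hill cooperativity, fixed throughout (never estimated).
HILL_COEF = 2.0
#: Activation threshold used wherever a model does not estimate it.
DEFAULT_THRESHOLD = 0.5


class InvalidParameterError(ValueError):
    """A rate-law parameter violates its positivity constraint."""


class ConfigurationError(ValueError):
    """An unknown model, gate or step label was requested."""


class ContractViolation(RuntimeError):
    """An operation was called without a required ingredient (e.g. history)."""


# ---------------------------------------------------------------------------
# Hill rate laws and promoter logic gates
# ---------------------------------------------------------------------------

def hill_activation(s, theta, h=HILL_COEF):
    """Activating Hill function ``s^h / (theta^h + s^h)``.

    Strictly increasing in ``s``, 0 at ``s = 0``, 1/2 at ``s = theta`` and
    saturating to 1.  ``theta`` and ``h`` must be positive.
    """
    theta = np.asarray(theta, dtype=float)
    h = float(h)
    if np.any(theta <= 0) or h <= 0:
        raise InvalidParameterError("Hill threshold and coefficient must be positive")
    s = np.asarray(s, dtype=float)
    sh = s**h
    out = sh / (theta**h + sh)
    return float(out) if out.ndim == 0 else out


def hill_repression(s, theta, h=HILL_COEF):
    """Repressing Hill function ``theta^h / (theta^h + s^h)``.

    Complements :func:`hill_activation`: for shared ``(s, theta, h)`` the
    two functions sum to one.
    """
    theta = np.asarray(theta, dtype=float)
    h = float(h)
    if np.any(theta <= 0) or h <= 0:
        raise InvalidParameterError("Hill threshold and coefficient must be positive")
    s = np.asarray(s, dtype=float)
    th = theta**h
    out = th / (th + s**h)
    return float(out) if out.ndim == 0 else out


def gate(kind: str, f_s, f_y):
    """Combine two promoter occupancy fractions through a logic gate.

    ``AND`` multiplies the fractions; ``OR`` uses the probabilistic sum
    ``f_s + f_y - f_s*f_y``.  Both stay in [0, 1], are monotone in each
    argument and reduce to Boolean logic at saturation.
    """
    if kind == "AND":
        return f_s * f_y
    if kind == "OR":
        return f_s + f_y - f_s * f_y
    raise ConfigurationError(f"unknown gate kind: {kind!r}")


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepInit:
    """Canonical initialisation of one experimental step for a model.

    ``inputs`` maps input names to either a constant level or a
    :class:`SignalProfile`.  ``s_pre`` gives the input level that held
    *before* the step started; delayed models read it when ``t - tau``
    falls before the step origin.
    """

    inputs: Mapping[str, float | SignalProfile]
    x0: tuple[float, ...]
    duration: float = 10.0
    s_pre: Mapping[str, float] = field(default_factory=dict)

    def signal(self, name: str) -> SignalProfile:
        v = self.inputs[name]
        return v if isinstance(v, SignalProfile) else SignalProfile.constant(v)


@dataclass(frozen=True)
class ModelSpec:
    """Static description of one dynamical model."""

    name: str
    states: tuple[str, ...]
    param_names: tuple[str, ...]
    param_roles: tuple[str, ...]
    observed: tuple[str, ...]
    delayed: bool
    aic_param_count: int
    code: int
    inputs: tuple[str, ...]
    steps: Mapping[str, StepInit]
    rhs: Callable
    nests: tuple[str, ...] = ()
    description: str = ""

    def __post_init__(self):
        if not set(self.observed) <= set(self.states):
            raise ConfigurationError("observed variables must be model states")
        if len(self.param_names) != len(self.param_roles):
            raise ConfigurationError("every parameter needs exactly one role tag")
        n_penalised = sum(r in ("production", "degradation", "threshold", "delay")
                          for r in self.param_roles)
        if self.aic_param_count != n_penalised:
            raise ConfigurationError("aic_param_count must count rate/threshold/delay parameters")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def true_params(self) -> dict[str, float]:
        """Generating-parameter defaults: rates 1, thresholds 0.5, delay 0.5."""
        vals = {"production": 1.0, "degradation": 1.0,
                "threshold": DEFAULT_THRESHOLD, "delay": 0.5}
        return {n: vals[r] for n, r in zip(self.param_names, self.param_roles)}

    def params_to_dict(self, theta) -> dict[str, float]:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise InvalidParameterError(
                f"{self.name} expects {self.n_params} parameters, got {theta.shape}")
        return dict(zip(self.param_names, theta))

    def params_to_array(self, params: Mapping[str, float]) -> np.ndarray:
        missing = set(self.param_names) - set(params)
        if missing:
            raise InvalidParameterError(f"missing parameters: {sorted(missing)}")
        return np.array([params[n] for n in self.param_names], dtype=float)


@dataclass
class Trajectory:
    """Solution of a model on an output grid.

    ``values`` has shape ``(len(times), len(states))``.  ``ok`` is False
    when the solver failed or produced non-finite values; the failing
    parameter vector is kept in ``meta`` for diagnosis rather than being
    silently returned.
    """

    times: np.ndarray
    states: tuple[str, ...]
    values: np.ndarray
    ok: bool = True
    meta: dict = field(default_factory=dict)

    def __getitem__(self, state: str) -> np.ndarray:
        return self.values[:, self.states.index(state)]


# -- right-hand sides (reference implementations) ---------------------------
# Each takes (t, x, p, sig, hist): p maps parameter name -> value, sig maps
# input name -> callable of t, hist(t) returns the lagged state vector.

def _rhs_sim(t, x, p, sig, hist):
    s = sig["S"](t)
    return np.array([p["beta_y"] * s - p["alpha_y"] * x[0],
                     p["beta_z"] * s - p["alpha_z"] * x[1]])


def _rhs_rc(t, x, p, sig, hist):
    s = sig["S"](t)
    return np.array([p["beta_y"] * s - p["alpha_y"] * x[0],
                     p["beta_z"] * x[0] - p["alpha_z"] * x[1]])


def _rhs_ff(t, x, p, sig, hist):
    s = sig["S"](t)
    return np.array([p["beta_y"] * s - p["alpha_y"] * x[0],
                     p["beta_zs"] * s + p["beta_zy"] * x[0] - p["alpha_z"] * x[1]])


def _rhs_fb(t, x, p, sig, hist):
    # End-product feedback: z represses production of y.
    s = sig["S"](t)
    fr = hill_repression(x[1], p["theta_zy"])
    return np.array([p["beta_y"] * s * fr - p["alpha_y"] * x[0],
                     p["beta_z"] * x[0] - p["alpha_z"] * x[1]])


def _rhs_sim_h(t, x, p, sig, hist):
    fs = hill_activation(sig["S"](t), DEFAULT_THRESHOLD)
    return np.array([p["beta_y"] * fs - p["alpha_y"] * x[0],
                     p["beta_z"] * fs - p["alpha_z"] * x[1]])


def _rhs_rc_h(t, x, p, sig, hist):
    fs = hill_activation(sig["S"](t), DEFAULT_THRESHOLD)
    fy = hill_activation(x[0], DEFAULT_THRESHOLD)
    return np.array([p["beta_y"] * fs - p["alpha_y"] * x[0],
                     p["beta_z"] * fy - p["alpha_z"] * x[1]])


def _rhs_ff_h(t, x, p, sig, hist):
    fs = hill_activation(sig["S"](t), DEFAULT_THRESHOLD)
    fy = hill_activation(x[0], DEFAULT_THRESHOLD)
    return np.array([p["beta_y"] * fs - p["alpha_y"] * x[0],
                     p["beta_zs"] * fs + p["beta_zy"] * fy - p["alpha_z"] * x[1]])


def _rhs_fb_h(t, x, p, sig, hist):
    fs = hill_activation(sig["S"](t), DEFAULT_THRESHOLD)
    fr = hill_repression(x[1], p["theta_zy"])
    fy = hill_activation(x[0], DEFAULT_THRESHOLD)
    return np.array([p["beta_y"] * fs * fr - p["alpha_y"] * x[0],
                     p["beta_z"] * fy - p["alpha_z"] * x[1]])


def _rhs_ff_c1_and(t, x, p, sig, hist):
    s = sig["S"](t)
    g = gate("AND", hill_activation(s, p["theta_sz"]),
             hill_activation(x[0], p["theta_yz"]))
    return np.array([p["beta_y"] * hill_activation(s, p["theta_sy"]) - p["alpha_y"] * x[0],
                     p["beta_z"] * g - p["alpha_z"] * x[1]])


def _rhs_ff_c1_or(t, x, p, sig, hist):
    s = sig["S"](t)
    g = gate("OR", hill_activation(s, p["theta_sz"]),
             hill_activation(x[0], p["theta_yz"]))
    return np.array([p["beta_y"] * hill_activation(s, p["theta_sy"]) - p["alpha_y"] * x[0],
                     p["beta_z"] * g - p["alpha_z"] * x[1]])


def _rhs_ff_i1_and(t, x, p, sig, hist):
    s = sig["S"](t)
    g = gate("AND", hill_activation(s, p["theta_sz"]),
             hill_repression(x[0], p["theta_yz"]))
    return np.array([p["beta_y"] * hill_activation(s, p["theta_sy"]) - p["alpha_y"] * x[0],
                     p["beta_z"] * g - p["alpha_z"] * x[1]])


def _rhs_control_ara(t, x, p, sig, hist):
    g = gate("AND", hill_activation(sig["S"](t), p["theta_s"]),
             hill_activation(sig["S2"](t), p["theta_s2"]))
    return np.array([p["beta_z"] * g - p["alpha_z"] * x[0]])


def _rhs_control_fla(t, x, p, sig, hist):
    return np.array([p["beta_z"] * sig["S"](t) - p["alpha_z"] * x[0]])


def _rhs_control_gal(t, x, p, sig, hist):
    g = gate("AND", hill_activation(sig["S"](t), p["theta_s"]),
             hill_repression(sig["S2"](t), p["theta_s2"]))
    return np.array([p["beta_z"] * g - p["alpha_z"] * x[0]])


def _rhs_ff_c1_or2(t, x, p, sig, hist):
    # Delay on the intermediate regulator as read by the target promoter.
    if hist is None:
        raise ContractViolation("FF.C1.OR.2 is a delay model and needs a history accessor")
    s = sig["S"](t)
    y_lag = hist(t - p["tau"])[0]
    g = gate("OR", hill_activation(s, p["theta_sz"]),
             hill_activation(y_lag, p["theta_yz"]))
    return np.array([p["beta_y"] * hill_activation(s, p["theta_sy"]) - p["alpha_y"] * x[0],
                     p["beta_z"] * g - p["alpha_z"] * x[1]])


def _rhs_ff_c1_or3(t, x, p, sig, hist):
    # Delay on both regulatory reads: S as seen by y, and y as seen by z.
    if hist is None:
        raise ContractViolation("FF.C1.OR.3 is a delay model and needs a history accessor")
    s_lag = sig["S"](t - p["tau"])
    y_lag = hist(t - p["tau"])[0]
    g = gate("OR", hill_activation(sig["S"](t), p["theta_sz"]),
             hill_activation(y_lag, p["theta_yz"]))
    return np.array([p["beta_y"] * hill_activation(s_lag, p["theta_sy"]) - p["alpha_y"] * x[0],
                     p["beta_z"] * g - p["alpha_z"] * x[1]])


# -- canonical experimental steps -------------------------------------------

_MOTIF_STEPS = {"main": StepInit(inputs={"S": STEP_PROTOCOL}, x0=(0.0, 0.0), duration=10.0)}

def _onoff(two_state: bool, second_input: bool):
    x_on = (0.0, 0.0) if two_state else (0.0,)
    x_off = (1.0, 1.0) if two_state else (1.0,)
    extra_on = {"S2": 1.0} if second_input else {}
    return {
        "ON": StepInit(inputs={"S": 1.0, **extra_on}, x0=x_on, s_pre={"S": 0.0}),
        "OFF": StepInit(inputs={"S": 0.0, **extra_on}, x0=x_off, s_pre={"S": 1.0}),
    }


_RATES2 = ("beta_y", "alpha_y", "beta_z", "alpha_z")
_ROLES2 = ("production", "degradation", "production", "degradation")
_FF_PARAMS = ("beta_y", "alpha_y", "beta_z", "alpha_z",
              "theta_sy", "theta_sz", "theta_yz")
_FF_ROLES = _ROLES2 + ("threshold",) * 3


def _spec(name, states, params, roles, code, rhs, *, observed=None, delayed=False,
          inputs=("S",), steps=None, nests=(), description=""):
    return ModelSpec(
        name=name, states=states, param_names=params, param_roles=roles,
        observed=tuple(observed) if observed is not None else states,
        delayed=delayed, aic_param_count=len(params), code=code, inputs=inputs,
        steps=steps if steps is not None else _MOTIF_STEPS, rhs=rhs,
        nests=nests, description=description)


MODELS: dict[str, ModelSpec] = {m.name: m for m in [
    _spec("SIM", ("y", "z"), _RATES2, _ROLES2, 0, _rhs_sim,
          description="Single input motif: S drives y and z independently."),
    _spec("RC", ("y", "z"), _RATES2, _ROLES2, 1, _rhs_rc,
          description="Regulatory chain: S drives y, y drives z."),
    _spec("FF", ("y", "z"),
          ("beta_y", "alpha_y", "beta_zs", "beta_zy", "alpha_z"),
          ("production", "degradation", "production", "production", "degradation"),
          2, _rhs_ff, nests=("SIM", "RC"),
          description="Feed-forward loop with additive direct and indirect branches."),
    _spec("FB", ("y", "z"), _RATES2 + ("theta_zy",), _ROLES2 + ("threshold",),
          3, _rhs_fb, nests=("RC",),
          description="Negative feedback: the end product z represses production of y."),
    _spec("SIM.H", ("y", "z"), _RATES2, _ROLES2, 4, _rhs_sim_h,
          description="SIM with cooperative (Hill) production from S."),
    _spec("RC.H", ("y", "z"), _RATES2, _ROLES2, 5, _rhs_rc_h,
          description="RC with cooperative production terms."),
    _spec("FF.H", ("y", "z"),
          ("beta_y", "alpha_y", "beta_zs", "beta_zy", "alpha_z"),
          ("production", "degradation", "production", "production", "degradation"),
          6, _rhs_ff_h, nests=("SIM.H", "RC.H"),
          description="FF with cooperative production on both inputs of z."),
    _spec("FB.H", ("y", "z"), _RATES2 + ("theta_zy",), _ROLES2 + ("threshold",),
          7, _rhs_fb_h, nests=("RC.H",),
          description="FB with cooperative production terms."),
    _spec("FF.C1.AND", ("y", "z"), _FF_PARAMS, _FF_ROLES, 8, _rhs_ff_c1_and,
          observed=("z",), steps=_onoff(True, False),
          description="Coherent type-1 FF, AND gate (arabinose-like; y=AraC, z=AraBAD)."),
    _spec("FF.C1.OR.1", ("y", "z"), _FF_PARAMS, _FF_ROLES, 9, _rhs_ff_c1_or,
          observed=("z",), steps=_onoff(True, False),
          description="Coherent type-1 FF, OR gate (flagella-like; y=FliA, z=FliL)."),
    _spec("FF.I1.AND", ("y", "z"), _FF_PARAMS, _FF_ROLES, 10, _rhs_ff_i1_and,
          observed=("z",), steps=_onoff(True, False),
          description="Incoherent type-1 FF, AND gate (galactose-like; y=GalS, z=GalETK)."),
    _spec("CONTROL.ARA", ("z",), ("beta_z", "alpha_z", "theta_s", "theta_s2"),
          ("production", "degradation", "threshold", "threshold"),
          11, _rhs_control_ara, inputs=("S", "S2"), steps=_onoff(False, True),
          description="Non-FF control: two independent activators on z via an AND gate."),
    _spec("CONTROL.FLA", ("z",), ("beta_z", "alpha_z"),
          ("production", "degradation"),
          12, _rhs_control_fla, steps=_onoff(False, False),
          description="Non-FF control: single linear activation of z by S."),
    _spec("CONTROL.GAL", ("z",), ("beta_z", "alpha_z", "theta_s", "theta_s2"),
          ("production", "degradation", "threshold", "threshold"),
          13, _rhs_control_gal, inputs=("S", "S2"), steps=_onoff(False, True),
          description="Non-FF control: activation by S, repression by S2, AND gate."),
    _spec("FF.C1.OR.2", ("y", "z"), _FF_PARAMS + ("tau",), _FF_ROLES + ("delay",),
          14, _rhs_ff_c1_or2, observed=("z",), delayed=True, steps=_onoff(True, False),
          nests=("FF.C1.OR.1",),
          description="FF.C1.OR.1 with the target promoter reading y at time t - tau."),
    _spec("FF.C1.OR.3", ("y", "z"), _FF_PARAMS + ("tau",), _FF_ROLES + ("delay",),
          15, _rhs_ff_c1_or3, observed=("z",), delayed=True, steps=_onoff(True, False),
          nests=("FF.C1.OR.1",),
          description="FF.C1.OR.1 with delays on both the S->y and y->z reads."),
]}


def get_model(name: str | ModelSpec) -> ModelSpec:
    if isinstance(name, ModelSpec):
        return name
    try:
        return MODELS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown model {name!r}; available: {', '.join(MODELS)}") from None


def eval_rhs(model, state, t, params, signal, history=None) -> np.ndarray:
    """Evaluate the state derivative of ``model`` at one point.

    ``signal`` may be a single :class:`SignalProfile` (bound to input S),
    a mapping of input names to profiles/constants, or a scalar.
    ``history`` is required for delay models: a callable returning the
    state vector at an earlier time.
    """
    spec = get_model(model)
    sig = _as_signal_map(spec, signal)
    p = params if isinstance(params, Mapping) else spec.params_to_dict(params)
    if spec.delayed and history is None:
        raise ContractViolation(f"{spec.name} requires a history accessor")
    return spec.rhs(t, np.asarray(state, dtype=float), p, sig, history)


def _as_signal_map(spec, signal):
    if isinstance(signal, Mapping):
        return {k: (v if callable(v) else SignalProfile.constant(v))
                for k, v in signal.items()}
    if not callable(signal):
        signal = SignalProfile.constant(float(signal))
    sig = {"S": signal}
    for name in spec.inputs:
        sig.setdefault(name, SignalProfile.constant(1.0))
    return sig


def integrate(model, params, signal, times, initial_state=None, *,
              rtol=1e-8, atol=1e-10, delay_history=None) -> Trajectory:
    """Reference integration of a model on an output grid.

    Non-delay models are solved per signal segment with ``solve_ivp``
    (stiff-capable LSODA) so the step discontinuities never cross a solver
    step.  Delay models are handled by :mod:`motifcompare.delay`.  A failed
    or non-finite solve is returned flagged (``ok=False``) instead of
    raising, so samplers can treat it as an infeasible parameter draw.
    """
    spec = get_model(model)
    p = params if isinstance(params, Mapping) else spec.params_to_dict(params)
    # production rates may be exactly zero (that is how nested reductions
    # like FF -> SIM arise); degradation rates and thresholds must be positive
    bad = [n for n, r in zip(spec.param_names, spec.param_roles)
           if (r in ("degradation", "threshold") and p[n] <= 0)
           or (r == "production" and p[n] < 0)]
    if bad:
        raise InvalidParameterError(f"invalid (non-positive) parameters: {bad}")
    times = np.asarray(times, dtype=float)
    sig = _as_signal_map(spec, signal)
    if initial_state is None:
        initial_state = np.zeros(spec.n_states)
    x0 = np.asarray(initial_state, dtype=float)

    if spec.delayed:
        from .delay import integrate_delayed
        return integrate_delayed(spec, p, sig, times, x0,
                                 history=delay_history)

    profile = sig["S"]
    bps = profile.breakpoints if isinstance(profile, SignalProfile) else (times[0],)
    interior = [b for b in bps if times[0] < b < times[-1]]
    seg_edges = np.unique(np.concatenate([[times[0]], interior, [times[-1]]]))
    values = np.full((times.size, spec.n_states), np.nan)
    x = x0.copy()
    ok = True
    for i, (a, b) in enumerate(zip(seg_edges[:-1], seg_edges[1:])):
        lo = (times >= a) if i == 0 else (times > a)
        mask = lo & (times <= b)
        # always integrate through to b so the next segment starts exactly there
        t_out = np.unique(np.concatenate([times[mask], [b]]))
        sol = solve_ivp(lambda t, s: spec.rhs(t, s, p, sig, None), (a, b), x,
                        method="LSODA", t_eval=t_out, rtol=rtol, atol=atol)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            ok = False
            break
        interp = dict(zip(t_out, sol.y.T))
        values[mask] = np.array([interp[t] for t in times[mask]])
        x = sol.y[:, -1]
    if times[0] == seg_edges[0] and ok and np.isnan(values[0]).any():
        values[0] = x0  # grid starting exactly at t0
    meta = {"rtol": rtol, "atol": atol, "method": "LSODA", "params": dict(p)}
    return Trajectory(times=times, states=spec.states, values=values, ok=ok, meta=meta)
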