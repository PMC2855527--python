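import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import motifcompare as mc
from motifcompare._analytic import linear_motif_solution
from motifcompare.motifs import (
    ConfigurationError,
    ContractViolation,
    InvalidParameterError,
    MODELS,
)

GRID = np.linspace(0.0, 10.0, 30)


# ---------------------------------------------------------------------------
# Hill functions and gates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("s,theta,h,expected", [
    (0.0, 0.5, 2, 0.0),        # no input, no activation
    (0.5, 0.5, 2, 0.5),        # half saturation at the threshold
    (1.0, 0.5, 2, 0.8),        # 1/(1 + 0.25)
])
def test_hill_activation_values(s, theta, h, expected):
    assert mc.hill_activation(s, theta, h) == pytest.approx(expected, abs=1e-12)


def test_hill_repression_values():
    assert mc.hill_repression(0.0, 0.5, 2) == 1.0
    assert mc.hill_repression(0.5, 0.5, 2) == pytest.approx(0.5)


def test_hill_rejects_nonpositive_shape_parameters():
    for bad in ({"theta": 0.0}, {"theta": -1.0}, {"h": 0.0}, {"h": -2.0}):
        kwargs = {"theta": 0.5, "h": 2.0, **bad}
        with pytest.raises(InvalidParameterError):
            mc.hill_activation(1.0, kwargs["theta"], kwargs["h"])
        with pytest.raises(InvalidParameterError):
            mc.hill_repression(1.0, kwargs["theta"], kwargs["h"])


@settings(deadline=None, derandomize=True)
@given(st.floats(0.0, 50.0), st.floats(0.01, 10.0), st.floats(0.1, 6.0))
def test_activation_plus_repression_is_one(s, theta, h):
    total = mc.hill_activation(s, theta, h) + mc.hill_repression(s, theta, h)
    assert total == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("kind,a,b,expected", [
    ("AND", 1.0, 1.0, 1.0), ("AND", 0.7, 0.0, 0.0),
    ("OR", 0.0, 0.0, 0.0), ("OR", 1.0, 0.3, 1.0),
    ("AND", 0.8, 0.5, 0.4), ("OR", 0.8, 0.5, 0.9),
])
def test_gate_values(kind, a, b, expected):
    assert mc.gate(kind, a, b) == pytest.approx(expected, abs=1e-12)


def test_unknown_gate_is_configuration_error():
    with pytest.raises(ConfigurationError):
        mc.gate("XOR", 0.5, 0.5)


@settings(deadline=None, derandomize=True)
@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_gate_ordering_and_bounds(a, b):
    g_and = mc.gate("AND", a, b)
    g_or = mc.gate("OR", a, b)
    assert 0.0 <= g_and <= min(a, b) + 1e-12
    assert max(a, b) - 1e-12 <= g_or <= 1.0


# ---------------------------------------------------------------------------
# Registry and right-hand sides
# ---------------------------------------------------------------------------

def test_registry_contains_all_sixteen_models():
    assert len(MODELS) == 16
    for spec in MODELS.values():
        assert set(spec.observed) <= set(spec.states)
        assert len(spec.param_names) == len(set(spec.param_names))


def test_unknown_model_name():
    with pytest.raises(ConfigurationError):
        mc.get_model("SIM2")


def test_sim_derivative_examples():
    p = {"beta_y": 1.0, "alpha_y": 1.0, "beta_z": 1.0, "alpha_z": 1.0}
    d0 = mc.eval_rhs("SIM", (0.0, 0.0), 0.0, p, 1.0)
    assert d0 == pytest.approx([1.0, 1.0])
    # (1, 1) is the steady state of the unit-parameter system at S = 1
    d1 = mc.eval_rhs("SIM", (1.0, 1.0), 0.0, p, 1.0)
    assert d1 == pytest.approx([0.0, 0.0], abs=1e-14)


def test_ff_with_zero_indirect_branch_reduces_to_sim():
    p_ff = {"beta_y": 1.3, "alpha_y": 0.8, "beta_zs": 0.9, "beta_zy": 0.0,
            "alpha_z": 1.1}
    p_sim = {"beta_y": 1.3, "alpha_y": 0.8, "beta_z": 0.9, "alpha_z": 1.1}
    for state in [(0.0, 0.0), (0.4, 1.2), (2.0, 0.3)]:
        d_ff = mc.eval_rhs("FF", state, 1.0, p_ff, 2.0)
        d_sim = mc.eval_rhs("SIM", state, 1.0, p_sim, 2.0)
        assert d_ff == pytest.approx(d_sim)


def test_delay_model_requires_history():
    spec = mc.get_model("FF.C1.OR.2")
    with pytest.raises(ContractViolation):
        mc.eval_rhs(spec, (0.0, 0.0), 1.0, spec.true_params(), 1.0)


# ---------------------------------------------------------------------------
# Integration vs the closed-form oracle
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", ["SIM", "RC", "FF"])
def test_linear_motifs_match_closed_form(name):
    """Numerical trajectories equal the piecewise-exponential solution."""
    rng = np.random.default_rng(42)
    spec = mc.get_model(name)
    for _ in range(4):
        params = dict(zip(spec.param_names, np.exp(rng.normal(0, 0.7, spec.n_params))))
        traj = mc.integrate(name, params, mc.STEP_PROTOCOL, GRID)
        exact = linear_motif_solution(name, params, mc.STEP_PROTOCOL, GRID)
        assert traj.ok
        scale = np.maximum(np.abs(exact), 1e-3)
        assert np.max(np.abs(traj.values - exact) / scale) < 1e-6


def test_equal_degradation_rates_limit():
    params = {"beta_y": 1.0, "alpha_y": 1.2, "beta_z": 0.7, "alpha_z": 1.2}
    traj = mc.integrate("RC", params, mc.STEP_PROTOCOL, GRID)
    exact = linear_motif_solution("RC", params, mc.STEP_PROTOCOL, GRID)
    assert np.max(np.abs(traj.values - exact)) < 1e-6


def test_zero_signal_zero_state_stays_zero():
    traj = mc.integrate("SIM", mc.get_model("SIM").true_params(),
                        mc.SignalProfile.constant(0.0), GRID)
    assert np.allclose(traj.values, 0.0, atol=1e-12)


def test_nesting_on_trajectories():
    """FF collapses to SIM (beta_zy = 0) and RC (beta_zs = 0)."""
    base = {"beta_y": 1.0, "alpha_y": 1.0, "alpha_z": 1.0}
    ff_sim = mc.integrate("FF", dict(base, beta_zs=1.0, beta_zy=0.0),
                          mc.STEP_PROTOCOL, GRID)
    sim = mc.integrate("SIM", dict(base, beta_z=1.0), mc.STEP_PROTOCOL, GRID)
    assert np.max(np.abs(ff_sim.values - sim.values)) < 1e-7
    ff_rc = mc.integrate("FF", dict(base, beta_zs=0.0, beta_zy=1.0),
                         mc.STEP_PROTOCOL, GRID)
    rc = mc.integrate("RC", dict(base, beta_z=1.0), mc.STEP_PROTOCOL, GRID)
    assert np.max(np.abs(ff_rc.values - rc.values)) < 1e-7


@pytest.mark.parametrize("name", ["FB", "SIM.H", "RC.H", "FF.H", "FB.H"])
def test_nonlinear_motifs_stay_nonnegative_and_finite(name):
    spec = mc.get_model(name)
    traj = mc.integrate(name, spec.true_params(), mc.STEP_PROTOCOL, GRID)
    assert traj.ok
    assert np.all(traj.values >= -1e-9)


def test_invalid_parameters_rejected():
    p = mc.get_model("SIM").true_params()
    p["alpha_y"] = -1.0
    with pytest.raises(InvalidParameterError):
        mc.integrate("SIM", p, mc.STEP_PROTOCOL, GRID)


def test_kernel_agrees_with_reference_for_all_nondelay_models():
    """The jitted RK4 path equals solve_ivp for every registry model."""
    from motifcompare import _kernels
    rng = np.random.default_rng(3)
    for spec in MODELS.values():
        if spec.delayed:
            continue
        step = spec.steps["main"] if "main" in spec.steps else spec.steps["ON"]
        profile = step.signal("S")
        sig = {name: step.signal(name) for name in spec.inputs}
        theta = spec.params_to_array(spec.true_params()) * np.exp(rng.normal(0, 0.2, spec.n_params))
        ref = mc.integrate(spec, dict(zip(spec.param_names, theta)), sig, GRID,
                           initial_state=step.x0)
        interior = [b for b in profile.breakpoints if 0.0 < b < GRID[-1]]
        nodes = np.unique(np.concatenate([GRID, interior]))
        levels = np.atleast_1d(profile(nodes[:-1])).astype(float)
        nsub = np.maximum(np.ceil(np.diff(nodes) / 0.02), 1).astype(np.int64)
        x0 = tuple(step.x0) + (0.0,) * (2 - len(step.x0))
        s2 = step.inputs.get("S2", 1.0)
        out = np.empty((nodes.size, 2))
        _kernels.integrate_nodes(spec.code, theta, float(s2), nodes, levels,
                                 nsub, x0[0], x0[1], out)
        got = out[np.searchsorted(nodes, GRID)][:, :spec.n_states]
        assert np.max(np.abs(got - ref.values)) < 1e-6, spec.name
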