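"""Integration of the delayed feed-forward models (FF.C1.OR.2 / FF.C1.OR.3).

Both delay models have cascade structure: the intermediate regulator y
never depends on the target z, and under a piecewise-constant input its
equation is linear with a piecewise-constant production term, so y(t) is
available in closed form segment by segment.  The target equation

    dz/dt = beta_z * g(t) - alpha_z * z,
    g(t) = OR( f+(S(t), theta_sz), f+(y(t - tau), theta_yz) )

is then a scalar linear ODE with a known forcing term.  It is integrated
on a uniform fine grid by the exact one-step map
``z_{n+1} = r z_n + P(t_mid) (1 - r)/alpha_z`` with ``r = exp(-alpha_z dt)``,
i.e. the forcing is frozen at the sub-step midpoint.  The recurrence is
evaluated in C via ``scipy.signal.lfilter``, so delayed trajectories cost
a few vectorised array operations rather than a Python time-stepping loop.

Pre-history: for t < 0 the regulator concentration is held constant at
its initial value, and the input signal is held at the level that
preceded the step (``s_pre``), which is what makes a delayed read
informative under ON/OFF step protocols.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .motifs import ModelSpec, Trajectory, hill_activation
from .signals import SignalProfile

__all__ = ["integrate_delayed"]


def _shift_profile(profile: SignalProfile, tau: float, pre_level: float) -> SignalProfile:
    """The profile seen through a delay tau, with ``pre_level`` before t0 + tau."""
    if tau <= 0:
        return profile
    bp = profile.breakpoints
    new_bp = (bp[0],) + tuple(b + tau for b in bp)
    new_lv = (float(pre_level),) + tuple(profile.levels)
    return SignalProfile(new_bp, new_lv)


class _PiecewiseY:
    """Closed-form y(t) for dy/dt = beta * f+(S_y(t)) - alpha * y, t >= 0."""

    def __init__(self, beta, alpha, theta, profile: SignalProfile, t_end, y0, y_pre):
        nodes, levels = profile.segment_levels(0.0, float(t_end))
        prod = beta * hill_activation(levels, theta)
        self.alpha = alpha
        self.starts = nodes[:-1]
        self.y_inf = prod / alpha
        y_start = np.empty_like(self.starts)
        y = float(y0)
        for i, (a, b) in enumerate(zip(nodes[:-1], nodes[1:])):
            y_start[i] = y
            y = self.y_inf[i] + (y - self.y_inf[i]) * np.exp(-alpha * (b - a))
        self.y_start = y_start
        self.y_pre = float(y_pre)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.starts, t, side="right") - 1, 0, None)
        yi = self.y_inf[idx]
        y = yi + (self.y_start[idx] - yi) * np.exp(-self.alpha * (t - self.starts[idx]))
        return np.where(t < 0.0, self.y_pre, y)


def integrate_delayed(spec: ModelSpec, p, sig, times, x0, *, history=None,
                      dt=0.002, s_pre=None) -> Trajectory:
    """Trajectory of a delayed FF model on ``times`` (all >= 0).

    ``history`` optionally gives the constant pre-initial state (defaults
    to ``x0``); ``s_pre`` the input level before the step start.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("delay models are integrated forward from t = 0")
    x0 = np.asarray(x0, dtype=float)
    tau = max(float(p["tau"]), 0.0)
    profile = sig["S"]
    if not isinstance(profile, SignalProfile):
        profile = SignalProfile.constant(float(profile(0.0) if callable(profile) else profile))
    pre = float(s_pre if s_pre is not None else profile.levels[0])
    hist = np.asarray(history if history is not None else x0, dtype=float)
    t_end = float(times.max()) if times.size else 0.0

    # --- intermediate regulator ------------------------------------------
    shifted = _shift_profile(profile, tau, pre) if spec.code == 15 else profile
    y = _PiecewiseY(p["beta_y"], p["alpha_y"], p["theta_sy"], shifted,
                    t_end, x0[0], hist[0])

    # --- target ----------------------------------------------------------
    n = max(int(np.ceil(t_end / dt)), 1)
    grid = np.linspace(0.0, t_end, n + 1)
    step = grid[1] - grid[0] if n else dt
    mid = grid[:-1] + 0.5 * step
    fsz = hill_activation(profile(mid), p["theta_sz"])
    fyz = hill_activation(y(mid - tau), p["theta_yz"])
    g = fsz + fyz - fsz * fyz  # OR gate
    forcing = p["beta_z"] * g
    az = p["alpha_z"]
    if az * step < 1e-10:
        r, q = 1.0, forcing * step
    else:
        r = np.exp(-az * step)
        q = forcing * (1.0 - r) / az
    z_nodes = np.empty(n + 1)
    z_nodes[0] = x0[1]
    z_nodes[1:], _ = lfilter([1.0], [1.0, -r], q, zi=np.array([r * x0[1]]))
    values = np.column_stack([y(times), np.interp(times, grid, z_nodes)])
    ok = bool(np.all(np.isfinite(values)))
    return Trajectory(times=times, states=spec.states, values=values, ok=ok,
                      meta={"dt": dt, "tau": tau, "params": dict(p)})
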