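"""Closed-form trajectories for the linear motifs (SIM, RC, FF).

Under a piecewise-constant input the three linear motifs form a lower
triangular linear system

    dy/dt = b_y * S - a_y * y
    dz/dt = c_s * S + c_y * y - a_z * z

which solves segment-by-segment in exponentials:

    y(t) = y_inf + (y0 - y_inf) e^{-a_y dt},      y_inf = b_y S / a_y
    z(t) = z_inf + (z0 - z_inf - k) e^{-a_z dt} + k e^{-a_y dt}

with ``z_inf = (c_s S + c_y y_inf)/a_z`` and
``k = c_y (y0 - y_inf)/(a_z - a_y)``.  When the two degradation rates
coincide the ``k`` term degenerates to ``c_y (y0 - y_inf) dt e^{-a dt}``.

These formulas are the independent oracle for the numerical integrators;
they are exact up to floating point.
"""

from __future__ import annotations

import numpy as np

from .signals import SignalProfile

__all__ = ["linear_coefficients", "linear_motif_solution"]

_EQUAL_RATE_TOL = 1e-9


def linear_coefficients(name: str, p) -> tuple[float, float, float, float, float]:
    """Map a linear motif's named parameters to (b_y, a_y, c_s, c_y, a_z)."""
    if name == "SIM":
        return p["beta_y"], p["alpha_y"], p["beta_z"], 0.0, p["alpha_z"]
    if name == "RC":
        return p["beta_y"], p["alpha_y"], 0.0, p["beta_z"], p["alpha_z"]
    if name == "FF":
        return p["beta_y"], p["alpha_y"], p["beta_zs"], p["beta_zy"], p["alpha_z"]
    raise ValueError(f"{name} is not one of the linear motifs")


def linear_motif_solution(name, params, signal: SignalProfile, times,
                          initial_state=(0.0, 0.0)) -> np.ndarray:
    """Exact (y, z) values at ``times`` for SIM/RC/FF under a step signal."""
    b_y, a_y, c_s, c_y, a_z = linear_coefficients(name, params)
    times = np.asarray(times, dtype=float)
    nodes, levels = signal.segment_levels(times[0], times[-1] + 1e-12)
    out = np.empty((times.size, 2))
    y0, z0 = float(initial_state[0]), float(initial_state[1])
    equal = abs(a_z - a_y) < _EQUAL_RATE_TOL
    def _eval(dt_arr, s):
        y_inf = b_y * s / a_y
        z_inf = (c_s * s + c_y * y_inf) / a_z
        dy0 = y0 - y_inf
        ey = np.exp(-a_y * dt_arr)
        ez = np.exp(-a_z * dt_arr)
        y = y_inf + dy0 * ey
        if equal:
            z = z_inf + (z0 - z_inf) * ez + c_y * dy0 * dt_arr * ez
        else:
            k = c_y * dy0 / (a_z - a_y)
            z = z_inf + (z0 - z_inf - k) * ez + k * ey
        return y, z

    for a, b, s in zip(nodes[:-1], nodes[1:], levels):
        mask = (times >= a) & (times < b) if b < nodes[-1] else (times >= a)
        if mask.any():
            y, z = _eval(times[mask] - a, s)
            out[mask, 0] = y
            out[mask, 1] = z
        y_end, z_end = _eval(np.array([b - a]), s)
        y0, z0 = float(y_end[0]), float(z_end[0])
    return out
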