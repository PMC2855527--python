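"""Piecewise-constant input signals.

The experimentally controlled input S(t) is modelled as a step function:
a sorted list of breakpoints and the signal level that holds on each
half-open interval [t_i, t_{i+1}).  The level beyond the last breakpoint
is the last entry of ``levels``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SignalProfile", "STEP_PROTOCOL"]


@dataclass(frozen=True)
class SignalProfile:
    """A piecewise-constant signal S(t).

    Parameters
    ----------
    breakpoints
        Strictly increasing times at which the signal switches level.
    levels
        Signal value on each interval ``[breakpoints[i], breakpoints[i+1])``;
        ``levels[-1]`` holds for all times beyond the last breakpoint.
        Evaluation below the first breakpoint returns ``levels[0]``.
    """

    breakpoints: tuple[float, ...]
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.breakpoints) != len(self.levels):
            raise ValueError("breakpoints and levels must have equal length")
        if len(self.breakpoints) == 0:
            raise ValueError("signal needs at least one breakpoint")
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp.size > 1 and not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing")

    @classmethod
    def constant(cls, level: float, t0: float = 0.0) -> "SignalProfile":
        return cls((t0,), (float(level),))

    def __call__(self, t):
        """Evaluate the signal; accepts scalars or arrays."""
        bp = np.asarray(self.breakpoints)
        lv = np.asarray(self.levels)
        idx = np.searchsorted(bp, np.asarray(t, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, lv.size - 1)
        out = lv[idx]
        return float(out) if np.ndim(t) == 0 else out

    def segment_levels(self, t_start: float, t_end: float):
        """Segment nodes and per-segment levels covering [t_start, t_end].

        Returns ``(nodes, levels)`` where ``nodes`` contains t_start, every
        interior breakpoint and t_end, and ``levels[i]`` is the constant
        signal value on ``[nodes[i], nodes[i+1])``.
        """
        bp = np.asarray(self.breakpoints, dtype=float)
        interior = bp[(bp > t_start) & (bp < t_end)]
        nodes = np.concatenate(([t_start], interior, [t_end]))
        levels = self(nodes[:-1])
        return nodes, np.atleast_1d(levels).astype(float)


#: The step protocol used throughout the four-motif study:
#: S = 0 on [0, 2), 1 on [2, 6), 2 on [6, 10), 0 afterwards.
STEP_PROTOCOL = SignalProfile((0.0, 2.0, 6.0, 10.0), (0.0, 1.0, 2.0, 0.0))
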