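"""Trajectory and posterior-predictive plotting."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_fit", "plot_trajectory"]


def plot_trajectory(traj, ax=None):
    """Plot every state of a :class:`~motifcompare.motifs.Trajectory`."""
    if ax is None:
        _, ax = plt.subplots()
    for state in traj.states:
        ax.plot(traj.times, traj[state], label=state)
    ax.set_xlabel("time")
    ax.set_ylabel("concentration")
    ax.legend()
    return ax


def plot_fit(results, n_draws: int = 200, level: float = 0.95, seed: int = 0):
    """Data, posterior-mean solution and credible band for a fitted model.

    One panel per (step, observed variable): dots are the observations,
    the solid line the mean posterior solution and the dashed lines the
    equal-tailed credible band.
    """
    bands = results.predict_band(n_draws=n_draws, level=level, seed=seed)
    spec = results.model.spec
    panels = [(s, v) for s in bands for v in bands[s]]
    fig, axes = plt.subplots(1, len(panels), figsize=(4 * len(panels), 3.2),
                             squeeze=False)
    data = results.model.dataset.data
    for ax, (step, var) in zip(axes[0], panels):
        times, mean, lo, hi = bands[step][var]
        ax.plot(times, mean, color="green", label="mean solution")
        ax.plot(times, lo, "k--", lw=0.8, label=f"{level:.0%} credible band")
        ax.plot(times, hi, "k--", lw=0.8)
        obs = data[(data["step"] == step) & (data["variable"] == var)]
        ax.plot(obs["time"], obs["value"], "r.", ms=5, label="data")
        ax.set_title(f"{spec.name}: {var} ({step})")
        ax.set_xlabel("time")
    axes[0, 0].set_ylabel("concentration")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    return fig
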