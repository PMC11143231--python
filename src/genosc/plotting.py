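"""Minimal plotting helpers for trajectories and regulatory curves."""

from __future__ import annotations

import numpy as np

from .delays import Trajectory

__all__ = ["plot_timecourse", "plot_phase_plane", "plot_regulation"]


def plot_timecourse(trajs, variable: str | None = None, ax=None, labels=None):
    """Overlay one variable of one or more trajectories against time."""
    import matplotlib.pyplot as plt

    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if ax is None:
        _, ax = plt.subplots()
    for i, traj in enumerate(trajs):
        var = variable or getattr(traj.model, "tf_variable", None) or traj.state_names[-1]
        label = labels[i] if labels else var
        ax.plot(traj.t, traj.series(var), label=label)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(variable or "TF level (molecules)")
    ax.legend()
    return ax


def plot_phase_plane(traj: Trajectory, x: str, y: str, ax=None, **kwargs):
    """Trajectory projected on the (x, y) state plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(traj.series(x), traj.series(y), **kwargs)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    return ax


def plot_regulation(reg, c_max: float = 200.0, ax=None, hill_plot=False, label=None):
    """A regulatory curve R(c), optionally in Hill-plot coordinates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    c = np.linspace(1e-3, c_max, 500)
    r = reg(c)
    if hill_plot:
        mask = (r > 0) & (r < 1)
        ax.plot(np.log10(c[mask]), np.log10(r[mask] / (1 - r[mask])), label=label)
        ax.set_xlabel("log10 c")
        ax.set_ylabel("log10 [R/(1-R)]")
    else:
        ax.plot(c, r, label=label)
        ax.set_xlabel("c (molecules)")
        ax.set_ylabel("R(c)")
    return ax
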