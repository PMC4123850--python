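"""Static figure helpers: ternary policy maps and belief time paths."""

from __future__ import annotations

import numpy as np
import matplotlib.pyplot as plt
import pandas as pd

from .belief_mdp import BeliefPolicy

__all__ = ["ternary_coordinates", "plot_policy_ternary", "plot_belief_paths"]

#: Corner annotations in belief order (model 1, model 2, model 3).
_CORNERS = ("no disturbance", "moderate", "strong")


def ternary_coordinates(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project belief vectors onto the plane of an equilateral triangle.

    Model 1 sits at the lower-left corner, model 2 at the lower-right and
    model 3 at the top.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    x = B[:, 1] + 0.5 * B[:, 2]
    y = (np.sqrt(3.0) / 2.0) * B[:, 2]
    return x, y


def plot_policy_ternary(policy: BeliefPolicy, S: int, ax=None, cmap="viridis"):
    """Scatter the optimal action over the belief simplex at occupancy S."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.6))
    x, y = ternary_coordinates(policy.grid.points)
    n = policy.actions.max()
    sc = ax.scatter(x, y, c=policy.actions[S], s=8, cmap=cmap,
                    vmin=0, vmax=max(int(n), 1), marker="h", linewidths=0)
    for (cx, cy), lab in zip([(0, -0.04), (1, -0.04), (0.5, np.sqrt(3) / 2 + 0.02)],
                             _CORNERS):
        ax.text(cx, cy, lab, ha="center", fontsize=8)
    ax.set_title(f"restrictions at S = {S} ({policy.strategy})", fontsize=9)
    ax.set_aspect("equal")
    ax.axis("off")
    plt.colorbar(sc, ax=ax, label="restricted sites")
    return ax


def plot_belief_paths(curves: dict[str, pd.DataFrame], true_model: int, ax=None):
    """Overlay expected-belief time paths for several signal modes.

    ``curves`` maps a label (e.g. the signal mode) to the output of
    :func:`eagleadapt.simulate.expected_belief_paths`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    styles = ("-", "-.", "--", ":")
    col = f"b{true_model + 1}_mean"
    for (label, df), ls in zip(curves.items(), styles):
        ax.plot(df["year"], df[col], ls, label=label)
    ax.set_xlabel("year")
    ax.set_ylabel("mean belief in true model")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    return ax
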