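"""Active versus passive strategies and the value of the signal.

Solves the belief MDP for the p_r-known case at a moderate grid, compares
active and passive rules (probing), and reports the percent value gained
by updating beliefs with the unrestricted-success signal.  Writes ternary
policy maps to active_policy.png when matplotlib can render.
"""

import numpy as np

import eagleadapt as ea

GRID_ORDER = 25  # keep the demonstration quick; studies use >= 50

base = ea.SiteParams()
case = ea.get_preset("pr_known")
grid = ea.BeliefGrid(GRID_ORDER)

active = ea.solve_case(case, base, grid=grid)
passive = ea.solve_case(case, base, grid=grid, strategy="passive")
nosignal = ea.solve_case(case, base, mode="none", grid=grid)

probe = active.actions.astype(int) - passive.actions
gain = ea.value_gain(active.values, nosignal.values)
print(f"case {case.name}, signal {case.signal_mode}, grid order {GRID_ORDER}")
print(f"probing (active - passive): min {probe.min()}, max {probe.max()};"
      f" {100 * (probe < 0).mean():.1f}% of (S, belief) points relax restrictions")
print(f"value gain from the signal: max {gain.max():.2f}% of discounted value")
i = np.unravel_index(gain.argmax(), gain.shape)
print(f"largest gain at S = {i[0]}, belief {np.round(grid.points[i[1]], 2)}")
print(
    "\nWhen p_r is known, learning comes from unrestricted sites, so the"
    " active rule restricts fewer sites than the passive rule (negative"
    " probing); the signal is worth a few percent of discounted utility,"
    " most where beliefs split between the no- and strong-disturbance models."
)

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from eagleadapt.plotting import plot_policy_ternary

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6))
    plot_policy_ternary(active, S=15, ax=axes[0])
    plot_policy_ternary(active, S=25, ax=axes[1])
    fig.savefig("active_policy.png", dpi=150, bbox_inches="tight")
    print("wrote active_policy.png")
except Exception as exc:  # rendering is optional
    print(f"(skipping figure: {exc})")
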