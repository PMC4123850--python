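"""Blackwell comparison: success outcome versus action as a signal.

Shows that conditioning next-year occupancy on this year's fledging
outcome is at least as informative as conditioning on the action, by
finding a garbling matrix with a linear program and verifying the
closed-form witness.
"""

import numpy as np

import eagleadapt as ea
from eagleadapt.informativeness import action_garbling

base = ea.SiteParams()
probs = ea.get_preset("pr_known").models[1].success_probs(base)

P_outcome = ea.signal_conditional_transition(base)
P_action = ea.state_transition(probs, base)
ok, T = ea.at_least_as_informative(P_outcome, P_action)
print("outcome-conditional occupancy (columns: empty, occ/unsucc, occ/succ):")
print(np.round(P_outcome, 4))
print("action-conditional occupancy (columns: empty/unr, occ/unr, occ/restr):")
print(np.round(P_action, 4))
print("\ngarbling exists:", ok)
print("LP witness T:\n", np.round(T, 4))
T_explicit = action_garbling(probs)
print("explicit witness residual:", np.abs(P_outcome @ T_explicit - P_action).max())
print(
    "\nA garbling certifies that the fledging outcome Blackwell-dominates"
    " the action: any decision value achievable from occupancy histories"
    " alone is achievable from success records, but not conversely."
)
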