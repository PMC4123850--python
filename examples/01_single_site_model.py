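"""Single-site success model and joint event table.

Prints the fledging-success probabilities of every candidate disturbance
model at the mean hare level, then the joint (signal, next-state) law of a
single site under the moderate-disturbance model.
"""

import numpy as np
import pandas as pd

import eagleadapt as ea
from eagleadapt.model_core import EVENT_COLS, EVENT_ROWS

base = ea.SiteParams()
rows = []
for name in ("pr_known", "both_uncertain", "pu_known"):
    for model in ea.get_preset(name).models:
        pr = model.success_probs(base)
        rows.append((name, model.label, round(pr.p_u, 3), round(pr.p_r, 3)))
print(pd.DataFrame(rows, columns=["case", "model", "p_u", "p_r"]).to_string(index=False))

probs = ea.get_preset("pr_known").models[1].success_probs(base)
table = ea.site_event_table(probs, base)
print("\njoint P(Y1, Y2, S_next | S, A), moderate disturbance:")
print(pd.DataFrame(np.round(table, 3),
                   index=[f"Y1={a} Y2={b} S+={c}" for a, b, c in EVENT_ROWS],
                   columns=EVENT_COLS).to_string())

print(
    "\np_u < p_r: hiker disturbance lowers unrestricted success"
    f" ({probs.p_u:.3f} vs {probs.p_r:.3f}); each column sums to one, and"
    " success signals are impossible at empty sites."
)
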