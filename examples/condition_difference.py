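"""Contrast cytotoxic and control conditions in space and time.

Generates a small synthetic study and computes the aggregate difference in
binned cell counts between the cytotoxic (D66-ESK) and control (DP47)
conditions at each time point and position — the two-phase signature:
nearly identical early dynamics, divergence after the leading cells reach
the epithelial interface.
"""

import numpy as np

from chemofit import StudyDesign, generate_dataset, group_difference

design = StudyDesign(n_control=4, n_toxic=4, seed=2)
_, binned = generate_dataset(design)
diff = group_difference(binned)

pivot = diff.pivot(index="time_h", columns="bin_index", values="difference")
per_time = pivot.abs().max(axis=1)
# counting noise floor: the early dynamics of the two conditions are
# identical, so the first few frames calibrate the Poisson fluctuation level
floor = 3.0 * per_time[per_time.index <= 8.0].mean()
print("time_h  max |D66-ESK - DP47| over bins")
for t, v in per_time.items():
    marker = " <-- above noise floor" if v > floor else ""
    print(f"{t:6.0f}  {v:10.1f}{marker}")
print("\nThe difference stays near the counting-noise floor for the first "
      "~12 h and grows once infiltrating cells engage the epithelium and "
      "trigger target-induced cytokine release.")
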