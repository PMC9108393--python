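"""Generate a synthetic 16-experiment study and summarise it like the assay.

Creates 8 control (DP47) and 8 cytotoxic (D66-ESK) experiments imaged every
2 h for 48 h, converts the particle tables to declumped cell counts, and
prints the per-condition summary statistics at 48 h.
"""

from chemofit import StudyDesign, generate_dataset, summarize_infiltration

design = StudyDesign(seed=1)
table, binned = generate_dataset(design)

print(f"{table['experiment_id'].nunique()} experiments, "
      f"{len(table)} segmented regions in total")
summary = summarize_infiltration(table, at_time_h=48.0)
print(summary.to_string(index=False))
print("\nMean declumped totals per experiment and mean per-cell distance "
      "travelled (um from the seeding-channel interface), per condition. "
      "The cytotoxic compound recruits roughly 2.5x as many cells as the "
      "control while the distance distributions remain broadly similar.")
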