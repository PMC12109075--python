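"""Classify venous drainage dominance over a phantom cohort.

Runs the full pipeline on 12 extracranial subjects, prints each subject's
jugular share of arterial inflow and its 40%/60% classification, then the
sensitivity of the class counts to shifting both thresholds by +/-5 points.
"""

from cineflow.pipeline import RunConfig, run_cohort

config = RunConfig(plane="extracranial", preset="extracranial", seed=7)
result = run_cohort(config, 12)

table = result["table"]
print(table[["subject", "ratio", "category", "remaining_flow"]]
      .round(3).to_string(index=False))
print("\nclass counts at (0.40, 0.60):", result["counts"].to_dict())
print("\nsensitivity to the thresholds:")
print(result["sensitivity"])
print("\nratio = mean jugular flow / mean arterial compartment flow;")
print("remaining_flow (mL/min) = arterial inflow - measured venous outflow,")
print("the share drained by pathways the acquisition does not capture.")
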