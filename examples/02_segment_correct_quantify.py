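"""Segment, correct and quantify every vessel of one phantom subject.

Runs the per-vessel chain — cardiac-spectrum region growing from one seed,
aliasing correction, local background-offset subtraction, ROI flow
integration — and compares recovered mean flows with the generator's truth.
"""

from cineflow.phantom import make_cohort
from cineflow.pipeline import quantify_vessels, seeds_from_truth

(series, truth), = make_cohort(1, "extracranial", seed=7)
curves, qc = quantify_vessels(series, seeds_from_truth(truth))

print(f"{'vessel':26s} {'measured':>9s} {'truth':>9s} {'err%':>6s} "
      f"{'PI':>5s}  criterion")
for label, curve in curves.items():
    q_true = truth.true_mean_flow(label)
    err = 100.0 * (curve.mean - q_true) / q_true
    print(f"{label:26s} {curve.mean:9.1f} {q_true:9.1f} {err:+6.2f} "
          f"{curve.pulsatility_index:5.2f}  {qc[label]['grown_on']}")
for label, entry in qc.items():
    if entry.get("detected") is False:
        print(f"{label:26s} undetected (velocity below the floor at this Venc)")
print("\nFlows are in mL/min; err% is the end-to-end recovery error against")
print("the known ground truth, dominated by partial-volume edge pixels.")
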