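"""Compare Poiseuille resistances of venous drainage configurations.

Shows why a network of small peripheral veins can drain as effectively as
two large jugular trunks: parallel conductances add, and resistance falls
with the fourth power of the radius.
"""

from cineflow.resistance import VesselConfig, equivalent_resistance

ETA = 3.5e-3   # blood viscosity, Pa*s
LENGTH = 0.15  # vessel length, m

configs = {
    "two jugulars (r = 4 mm)": [(0.004, 2)],
    "one dominant jugular (r = 4 mm)": [(0.004, 1)],
    "32 peripheral veins (r = 1 mm)": [(0.001, 32)],
    "jugular + 16 peripherals": [(0.004, 1), (0.001, 16)],
}
reference = equivalent_resistance(
    VesselConfig(ETA, LENGTH, configs["two jugulars (r = 4 mm)"]))
for name, branches in configs.items():
    r_eq = equivalent_resistance(VesselConfig(ETA, LENGTH, branches))
    print(f"{name:34s} R_eq = {r_eq:10.3e} Pa*s/m^3 "
          f"({r_eq / reference:5.2f} x two-jugular reference)")
print("\n16 vessels of half radius equal one full-radius vessel (2^4 = 16),")
print("so peripheral rerouting need not raise total drainage resistance much.")
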