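"""Cell-assay computations: viability %, doubling time, and IC50.

Reproduces the assay arithmetic on its published inputs (cell counts) and
on a simulated WST-1 style dose-response table.
"""

from relkin import (
    GrowthObservation,
    doubling_time,
    fit_ic50,
    normalize_to_vehicle,
    simulate_dose_response,
    viability_percent,
)

# doubling times from 48 h growth of 10,000 seeded cells
for line, final in (("CT26", 42_410), ("HT29", 37_112)):
    td = doubling_time(GrowthObservation(10_000, final, 48.0))
    print(f"{line}: counted {final} cells after 48 h -> doubling time {td:.2f} h")

# viability from optical densities, normalised to the DMSO vehicle group
v = viability_percent(od_treated=0.42, od_control=0.80)
print(f"\nOD 0.42 vs control 0.80 -> viability {v:.1f} %")
print(f"normalised to a 95 % vehicle group: {normalize_to_vehicle([v], 95.0)[0]:.1f} %")

# IC50 from a 4PL dose-response at the 0.4-12.8 uM design
table = simulate_dose_response(
    ic50=1.5, hill=1.0, top=100.0, bottom=0.0, noise_sd=5.0, seed=11
)
res = fit_ic50(table)
print(
    f"\n4PL fit on 6 concentrations: IC50 = {res.ic50:.3f} uM "
    f"(truth 1.5), hill = {res.hill_slope:.2f}, "
    f"top = {res.top:.1f} %, bottom = {res.bottom:.1f} %"
)
print("IC50 is the concentration halving viability between the two asymptotes.")
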