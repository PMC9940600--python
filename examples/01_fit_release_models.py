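"""Fit the eight kinetic models to a GI-segmented release profile.

Simulates one formulation's cumulative-release curve (Higuchi burst in
gastric fluid, super-case-II power law in intestinal fluid, first-order
tail in colonic fluid), fits every registry model per medium segment, and
prints the per-segment R2/AIC/MSC grid.
"""

from relkin import ReleaseSimConfig, SegmentModel, fit_all, simulate_release

config = ReleaseSimConfig(
    segment_models=(
        SegmentModel("higuchi", {"kH": 14.0}),
        SegmentModel("korsmeyer_peppas", {"kKP": 6.0, "n": 1.3}),
        SegmentModel("first_order", {"k1": 0.015}),
    ),
    seed=42,
    noise_sd=1.0,
    formulation_id="demo-NP",
)

profile = simulate_release(config)
grid = fit_all(profile)

table = grid.to_frame()[["segment", "model", "r_squared", "aic", "msc", "exponent"]]
print(table.round(3).to_string(index=False))
print(
    "\nEach row is one model fitted to one medium window (SGF 0-2 h, SIF"
    "\n2-5 h, SCoF 5-48 h). Lower AIC / higher MSC = better fit; the"
    "\nexponent column holds the mechanism-bearing n, m or beta."
)
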