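# relkin

Release-kinetics modelling for gastrointestinal-transit dissolution
studies of drug-loaded nanoparticles, plus the companion cell-assay
computations.

Oral colon-targeted nanoparticles are characterised by cumulative-release
profiles measured sequentially in simulated gastric fluid (SGF, pH 1.2,
0–2 h), simulated intestinal fluid (SIF, pH 4.5, 2–5 h) and simulated
colonic fluid (SCoF, pH 7.4, 5–48 h). `relkin` is for formulation
scientists who want that analysis scripted and reproducible instead of
spreadsheet-bound:

* **Kinetic model fitting** — the eight classical empirical models
  (zero order, first order, Higuchi, Korsmeyer–Peppas F = k·tⁿ,
  Peppas–Sahlin F = k1·tᵐ + k2·t²ᵐ, Hopfenberg, Hixson–Crowell, Weibull
  F = 100·(1 − e^(−(t−Ti)^β/α))) fitted per medium segment by
  deterministic multi-start least squares.
* **Model selection** — the R²/AIC/MSC goodness stack with
  AIC = n·ln SS_res + 2p and MSC = ln(SS_tot/SS_res) − 2p/n; models within
  ΔAIC ≤ 2 of the minimum are reported as co-best.
* **Mechanism classification** — diffusional-exponent rules (n or m:
  ≤ 0.45 Fickian, 0.45–0.85 anomalous, 0.85 case II, > 0.85 super case II)
  and Weibull-β rules (≤ 0.75 Fickian, 0.75–1 combined, 1 first-order,
  > 1 complex).
* **Profile similarity** — the FDA difference/similarity factors
  f1 = 100·Σ|R−T|/ΣR and f2 = 50·log₁₀(100/√(1 + MSD)), with the
  similar verdict iff f1 ≤ 15 and f2 ≥ 50.
* **Cell assays** — viability % from optical densities, doubling time
  t_d = Δt·log2/(log N_f − log N_i), and IC50 via a four-parameter
  logistic fit.
* **Synthetic data** — seeded generators for release profiles (continuous
  across medium switches, replicate noise), dose-response tables and
  growth counts, so every pipeline stage is testable end to end.

## Worked example

```python
from relkin import (ReleaseSimConfig, SegmentModel, fit_all,
                    mechanism_report, rank, simulate_release)

profile = simulate_release(ReleaseSimConfig(
    segment_models=(
        SegmentModel("higuchi", {"kH": 14.0}),            # gastric burst
        SegmentModel("korsmeyer_peppas", {"kKP": 6.0, "n": 1.3}),  # SIF
        SegmentModel("first_order", {"k1": 0.015}),        # colonic tail
    ),
    seed=42, noise_sd=1.0, formulation_id="demo-NP",
))
grid = fit_all(profile)                       # 8 models x 3 segments
print(rank(grid.for_segment("SIF")).best)
print(mechanism_report(grid).to_string(index=False))
```

prints

```
('korsmeyer_peppas', 'weibull')
formulation segment                            best_models          exponents            mechanisms
    demo-NP     SGF peppas_sahlin;korsmeyer_peppas;higuchi    m=0.385;n=0.516 fickian;non_fickian;-
    demo-NP     SIF               korsmeyer_peppas;weibull n=1.341;beta=1.441 super_case_II;complex
    demo-NP    SCoF                          peppas_sahlin            m=1.053         super_case_II
```

The intestinal window is correctly called super case II (its generating
exponent n = 1.3 exceeds 0.85, i.e. relaxation/erosion-driven release
rather than Fickian diffusion), with the Weibull model co-best at ΔAIC ≤ 2
— the situation where one profile is genuinely compatible with two models.
The fitted exponent 1.341 sits within noise of the true 1.3.

The `examples/` directory holds one short script per capability
(fitting, mechanism calls, f1/f2 similarity, cell assays, full pipeline);
each prints the numbers it computes and a line on what they mean. A thin
CLI mirrors the library: `relkin fit|classify|compare|ic50|doubling-time|
simulate|run|models`.

Release-profile CSVs use columns `time_h, release_pct[, sd_pct]` (header
required, decimal commas normalised at ingest). See `docs/methods.md` for
model equations, bounds, conventions and limitations.

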