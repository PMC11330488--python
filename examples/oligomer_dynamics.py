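"""Oligomer population dynamics: origin of oligomers by model selection.

Generates paired unseeded and 1%-seeded oligomer time series from the
fibril-catalysed rate law (10% noise, 8 replicates), fits both candidate
rate laws jointly across conditions, and reports the selected mechanism,
the peak timing relative to the aggregation half-time, and the fitted
formation rate.
"""

import fibrilkin as fk

cfg = fk.GeneratorConfig(seed=3, seed_pcts=(0.0, 1.0))
series, bulks, truth = fk.gen_oligomer_series(cfg)

for label in series:
    s, b = series[label], bulks[label]
    peak = fk.oligomer_peak_time(s.times, s.S, b.normalized())
    print(f"{label:<14} peak at {peak.peak_time:5.1f} h = "
          f"{peak.ratio_to_half_time:.2f} x half-time")

sel = fk.select_oligomer_model(series, bulks, seed=0)
print(f"\nselected oligomer origin: {sel.selected}")
for mode, fit in sel.fits.items():
    print(f"  {mode:<10} objective {fit.objective:10.1f}")

fit = sel.fits["secondary"]
lo, hi = fit.formation_rate_ci
print(f"\nformation rate at 100 uM monomer: {fit.formation_rate_per_s:.2e} 1/s "
      f"per uM fibril mass (95% CI {lo:.2e}-{hi:.2e})")
print("(the peak sits just before the half-time and shifts with seeding --")
print(" the fingerprint of oligomers born on fibril surfaces; a detection")
print(" scale below 1 makes the fitted rate a lower bound)")
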