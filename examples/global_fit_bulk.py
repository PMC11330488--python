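"""Global fitting of noisy aggregation curves with model comparison.

Generates plate-reader-like quench traces (1% noise) at 100 uM monomer
with 0 / 0.25 / 1% seeds, fits them globally with and without secondary
processes, and pins the fragmentation-only model to the length-derived
proliferation bound to show it cannot explain the kinetics.
"""

import fibrilkin as fk

cfg = fk.GeneratorConfig(seed=1)
traces, truth = fk.gen_kinetic_traces(cfg)
normalized = [fk.normalize_trace(t) for t in traces]

fit = fk.global_fit(normalized, model="primary_plus_secondary",
                    n_starts=5, seed=0, kappa_reference_m=100.0)
print(f"fitted kappa at 100 uM: {fit.kappa:.3f} 1/h   (generated at 0.400 1/h)")

report = fk.compare_primary_vs_secondary(normalized, n_starts=3, seed=1)
print(f"primary-only misfit is {report.objective_ratio:.0f}x worse "
      f"-> {report.verdict}")

pinned = fk.fit_with_fragmentation_fixed(normalized, kappa_frag=0.01,
                                         n_starts=3, seed=2)
print(f"fragmentation pinned to 0.01 1/h: objective {pinned.objective:.2f} vs "
      f"{fit.objective:.3f} unconstrained "
      f"({pinned.objective / fit.objective:.0f}x worse)")
print("(a model whose fibril multiplication is capped at the fragmentation")
print(" bound cannot reproduce the observed acceleration)")
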