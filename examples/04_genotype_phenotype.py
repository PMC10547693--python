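"""Genotype-phenotype association at a dwarfing locus.

Simulates plant heights with a -50 cm additive effect for dw1 homozygotes
(sigma = 10 cm), fits the one-way group-means model with wildtype as the
reference level, and prints the coefficient table plus the normality and
rank-test diagnostics.
"""

from madw import (
    SimulationConfig,
    builtin_catalog,
    classify_effect,
    fit_allele_means,
    genotype_panel,
    simulate_panel,
    simulate_phenotypes,
    simulate_reference,
)
from madw.phenostats import allele_levels_from_calls

cfg = SimulationConfig(seed=7, n_accessions=300)
reference, models = simulate_reference(cfg)
panel = simulate_panel(cfg, reference, models)

effects = {d.name: 0.0 for d in builtin_catalog() if d.matchable}
effects.update({"dw1": -50.0, "novel": 0.0})
pheno = simulate_phenotypes(
    panel.manifest, effects, sigma=10.0, seed=8, baseline=250.0,
    trait="plant_height", unit="cm",
)

categories = {
    k: classify_effect(rec, panel.scores.get(k))
    for k, rec in panel.consequences.items()
}
calls = genotype_panel(
    panel.matrix,
    panel.catalog,
    categories,
    {v.key: v for v in panel.variants},
    panel.consequences,
    loci=["Dw1"],
)
levels = allele_levels_from_calls(calls, "Dw1")
values = dict(zip(pheno["accession"], pheno["value"]))
res = fit_allele_means(
    [values[a] for a in levels], [levels[a] for a in levels],
    locus="Dw1", trait="plant_height",
)
print("coefficient table (treatment coding vs wildtype):")
print(res.coefficients.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print(f"\nn per level: {res.n_per_level}")
print(f"Shapiro-Wilk on residuals: W = {res.shapiro_w:.5f}, p = {res.shapiro_p:.3g}")
print(f"Kruskal-Wallis: H = {res.kruskal_h:.2f}, df = {res.kruskal_df}, "
      f"p = {res.kruskal_p:.3g}")
print("\nThe dw1 coefficient estimates the planted -50 cm height effect;")
print("its t-test p-value answers the alpha = 0.05 significance question.")
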