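"""Matched tumor/stroma compartment analysis.

Laser-capture-style paired profiles from the same patients: paired
differential expression with a 2-fold / q < 0.01 gate, tumor-vs-stroma
subtype concordance, and the exact two-sided Wilcoxon signed-rank test
of the per-pair MSL descriptor scores (stroma is expected to score
higher on the mesenchymal stem-like centroid).
"""

from tnbctype import (generate_paired_lcm, differential_expression,
                      paired_subtype_concordance, subtype_samples,
                      wilcoxon_signed_rank_exact)

sim = generate_paired_lcm(n_pairs=10, n_spiked=50, compartment_fc=2.0,
                          stroma_msl_boost=1.0, seed=5)
expr, pairs, centroids = sim["expression"], sim["pairs"], sim["centroids"]
tumor = [p.tumor_profile for p in pairs]
stroma = [p.stroma_profile for p in pairs]

de = differential_expression(expr, tumor, stroma, paired=True)
hits = set(de.loc[de["passes"], "gene_id"])
spiked = set(sim["spiked_genes"])
print(f"Differential expression: {len(hits)} genes pass "
      f"(|log2FC| >= 1, q < 0.01); {len(hits & spiked)}/{len(spiked)} "
      "are true spiked compartment genes")

# the remaining hits are not false positives: they carry the stromal
# mesenchymal (MSL) signal added to every stroma profile
msl_w = sim["centroids"].weights["MSL"].abs()
extra = hits - spiked
print(f"Mean |MSL centroid weight|: {msl_w[list(extra)].mean():.2f} for the "
      f"{len(extra)} extra hits vs {msl_w[~msl_w.index.isin(hits)].mean():.2f} "
      "for non-hits (stroma-specific MSL signal, not noise)")

results = {r.sample_id: r for r in subtype_samples(expr, centroids)}
for p in pairs:
    p.tumor_call = results[p.tumor_profile].call6
    p.stroma_call = results[p.stroma_profile].call6
conc = paired_subtype_concordance(pairs)
print(f"\nSubtype concordance across {conc['n_pairs']} pairs: "
      f"{conc['n_concordant']} concordant, {conc['n_discordant']} discordant "
      f"({conc['n_discordant_stroma_msl']} discordant with stromal MSL)")

tumor_msl = [results[p.tumor_profile].msl_score for p in pairs]
stroma_msl = [results[p.stroma_profile].msl_score for p in pairs]
sr = wilcoxon_signed_rank_exact(tumor_msl, stroma_msl)
print(f"\nMSL score, stroma vs tumor: exact signed-rank "
      f"p = {sr['p_value']:.6f} over n = {sr['n_used']} pairs")
print("(ten one-sided differences give the minimal two-sided exact "
      "p of 2/1024 = 0.001953)")
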