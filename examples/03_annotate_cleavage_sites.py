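"""Classify cleavage sites in proteins against a selectome.

Plants cleavage sites in a random proteome — half with tetramers from the
top of the specificity landscape (genuine targets, high isotopic
enrichment), half with arbitrary tetramers (bystander events) — then
projects each site's P3-P1' tetramer, scores it with the selection's RP
table and classifies it as selectome / sub-threshold / absent.
"""

import selectome as sl

land = sl.make_landscape(seed=7)
cfg = sl.SelectionConfig(seed=7)
exp = sl.simulate_experiment(land, cfg)
rp, result = sl.selection_pipeline(exp.selection, exp.control, exp.naive)

proteome, sites_df = sl.plant_cleavage_sites(
    land, n_proteins=25, protein_length=400, n_sites=100, seed=7
)
sites = sl.sites_from_table(sites_df, proteome)
sites, fractions = sl.classify_sites(sites, rp.rp_of, result.rp_threshold)

print(f"{len(sites)} sites in {len(proteome)} proteins, "
      f"RP threshold {result.rp_threshold:.2f}")
for cat, frac in fractions.items():
    print(f"  {cat:>13}: {100 * frac:5.1f}%")

stats = sl.enrichment_stats([s.ie_log2 for s in sites])
enriched = [s for s, z in zip(sites, stats.z) if sl.ie_positive(z)]
in_sel = sum(s.category == "selectome" for s in enriched)
print(f"\nIE > 1 sigma above the population mean: {len(enriched)} sites, "
      f"{in_sel} of them in the selectome")
# Sites with strong isotopic enrichment (genuine cleavages) should be the
# ones whose tetramers sit above the selectome threshold; sub-threshold
# or absent tetramers flag likely bystander events.
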