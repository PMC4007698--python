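"""Codon-position GC of an ortholog set and major-axis regressions.

Simulates ~2,000 ortholog pairs between a GC-richer and a GC-poorer species
(the second species' GC3 shifted down by 25 points, as between a
compositionally heterogeneous malaria parasite and its extremely GC-poor
congener), cleans the coding sequences, and reports per-position means,
between-species GC3 histogram overlap and the within-species major-axis
fits.
"""

from gcmosaic import (
    OrthologSetSpec,
    build_ortholog_pairs,
    clean_cds,
    gc_distributions,
    pairwise_position_fits,
    simulate_orthologs,
)

spec = OrthologSetSpec(
    n_genes=2000,
    means=(50.0, 40.0, 45.0),  # species A gc1/gc2/gc3 means (% GC)
    sds=(8.0, 8.0, 5.0),
    between_position_correlation=0.5,
    gc3_shift_b=-25.0,
    codons_per_gene=400,
    seed=11,
)
cds_a, cds_b, pairing, _ = simulate_orthologs(spec)

accepted_a, rejected_a = clean_cds(cds_a)
accepted_b, rejected_b = clean_cds(cds_b)
print(f"cleanup: {len(accepted_a)}/{len(cds_a)} and {len(accepted_b)}/{len(cds_b)} CDS accepted")

pairs, dropped = build_ortholog_pairs(accepted_a, accepted_b, pairing)
dist = gc_distributions(pairs)
print("\nstatistic   mean(A)  mean(B)  histogram overlap")
for stat in ("gc", "gc1", "gc2", "gc3"):
    print(f"{stat:<10} {dist['means'][('a', stat)]:8.1f} {dist['means'][('b', stat)]:8.1f}"
          f" {dist['overlap'][stat]:12.3f}")

fits = pairwise_position_fits(pairs)
within_a = fits[fits.scope == "species_a"]
print("\nspecies A major-axis fits (y = slope*x + intercept):")
print(within_a.round(3).to_string(index=False))
# GC3 shows essentially no overlap between the species (the shifted
# position), while GC1 vs GC2 carries the simulated r ~ 0.5 correlation.
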