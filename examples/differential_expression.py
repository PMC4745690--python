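"""Three-level negative-binomial differential expression on a synthetic cohort.

Tests tumor vs normal at gene, transcript and exonic-region level with the
shared NB Wald engine, then maps the transcript/exon hits to their parent
genes and measures the overlap with the gene-level hits (hypergeometric
upper tail) — the cross-level comparison that distinguishes gene-wide
dysregulation from isoform- or exon-specific events.
"""

import trilayer as tl

spec = tl.CohortSpec(
    n_patients=20,
    n_genes=100,
    seed=7,
    planted_events=[
        tl.PlantedEvent("gene_de", 4.0),
        tl.PlantedEvent("gene_de", 0.25),
        tl.PlantedEvent("transcript_switch", 4.0),
        tl.PlantedEvent("exon_de", 3.0),
    ],
)
cohort = tl.generate_cohort(spec)
annot = cohort.annotation

significant = {}
for level in ("gene", "transcript", "exonic_region"):
    results = tl.test_level(cohort.counts[level], cohort.metadata, level)
    significant[level] = tl.significant_features(results, 0.05)
    top = sorted(results, key=lambda r: r.p_value)[:3]
    print(f"{level}: {len(results)} features tested, "
          f"{len(significant[level])} significant at Bonferroni 0.05")
    for r in top:
        print(f"   {r.feature_id:12s} log2FC={r.log2_fold_change:+.2f} "
              f"p_bonf={r.p_bonferroni:.2e}")

det_g = tl.map_to_genes(significant["transcript"], "transcript", annot)
dee_g = tl.map_to_genes(significant["exonic_region"], "exonic_region", annot)
universe = set(annot.genes)

print("\ncross-level overlap with the DEG set (hypergeometric upper tail):")
for name, mapped in (("DET-G", det_g), ("DEE-G", dee_g)):
    ov = tl.hypergeometric_overlap(significant["gene"], mapped, universe)
    print(f"  DEG ∩ {name}: {ov.overlap_size} of |DEG|={ov.set_a_size}, "
          f"|{name}|={ov.set_b_size}  (p = {ov.hypergeometric_p:.2e})")

switch_gene = next(e.gene_id for e in cohort.truth.events if e.kind == "transcript_switch")
print(f"\nswitch gene {switch_gene}: in DEG set? {switch_gene in significant['gene']}; "
      f"in DET-G set? {switch_gene in det_g}")
print("A low overlap p means the gene-mapped transcript/exon hits are far from")
print("independent of the DEGs; the switch gene shows why the sets still differ —")
print("it is detectable only below gene level.")
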