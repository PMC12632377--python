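"""LysoIP co-enrichment: which compartments co-purify with lysosomes?

Simulates a three-group lysosome immunopurification (untagged background,
tagged control, tagged knockout) with a 3 log2-unit lysosomal enrichment
and a planted +1 ER shift in the knockout, then computes enrichment over
the untagged cells, the mean-lysosomal-enrichment co-enrichment threshold,
and per-organelle Wilcoxon shift tests between knockout and control.
"""

import olscape as ol

cfg = ol.SimConfig(
    n_proteins=2000,
    genotypes=("Control", "ASAH1_KO"),
    cell_types=("HeLa",),
    annotations=(("lysosome", 250, None), ("ER", 300, None),
                 ("recycling_endosome", 120, None), ("mito", 250, None)),
    noise_sd=0.25, missing_rate=0.03, seed=4,
    groups={}, disease_classes={},
)
matrix, design, catalog, truth = ol.simulate_lysoip(
    cfg,
    lyso_enrichment=3.0,
    ko_organelle_shifts=(("ER", 1.0), ("recycling_endosome", -0.8)),
)

e_ctrl = ol.enrichment_vs_untagged(matrix, design, "Control")
e_ko = ol.enrichment_vs_untagged(matrix, design, "ASAH1_KO")

for name, e in (("Control", e_ctrl), ("ASAH1_KO", e_ko)):
    res = ol.coenrichment_flags(e, catalog)
    print(f"{name}: co-enrichment threshold = {res.threshold:.3f} "
          f"(mean lysosomal enrichment, log2)")
    print("  co-enriched proteins per annotation:",
          dict(res.counts), "\n")
# The knockout's ER count rises and its recycling-endosome count falls,
# tracking the planted shifts; lysosomal proteins sit near the threshold
# by construction (it is their mean).

shifts = ol.organelle_shift_test(e_ctrl, e_ko, catalog)
print("Per-organelle enrichment shift, KO vs control "
      "(Wilcoxon rank-sum, BH-corrected):")
print(shifts.round(4))
# ER and recycling endosome carry planted shifts and should reach q < 0.05;
# mito overlaps the shifted sets only by chance.
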