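"""Ratio-of-ratios spatial proteomics: where do proteins move?

Simulates whole-cell / soma / projection fractions for a control and a
knockout. A synaptic annotation is projection-enriched in BOTH genotypes
(shared compartment composition), and a mitochondrial annotation carries a
knockout-specific -0.75 log2 depletion in projections. The ratio of ratios
(KO projection/whole-cell over control projection/whole-cell, in log2)
cancels the shared term and isolates the genotype-specific redistribution.
"""

import olscape as ol

cfg = ol.SimConfig(
    n_proteins=2000,
    genotypes=("Control", "ASAH1_KO"),
    cell_types=("iN",),
    annotations=(("mitochondria", 300, None), ("SynapseSV", 200, None),
                 ("lysosome", 150, None)),
    noise_sd=0.25, missing_rate=0.02, seed=8,
    groups={}, disease_classes={},
)
matrix, design, catalog, truth = ol.simulate_spatial(
    cfg,
    compartment_profiles={"SynapseSV": (0.0, 2.0), "lysosome": (1.0, -0.5)},
    ko_projection_shifts=(("mitochondria", -0.75),),
)

ko = ol.fraction_log_ratio(matrix, design, "ASAH1_KO")
ctrl = ol.fraction_log_ratio(matrix, design, "Control")
print("Control projection/whole-cell log2 ratio, SynapseSV mean: "
      f"{ctrl.ratio_log2.loc[sorted(catalog.members('SynapseSV'))].mean():.3f}")
# ~2.0: synaptic proteins are projection-enriched in the control...

ror = ol.ratio_of_ratios(ko, ctrl, q_max=0.05)
syn = sorted(set(catalog.members("SynapseSV")) & set(ror.index))
mito = sorted(set(catalog.members("mitochondria")) & set(ror.index))
print(f"SynapseSV mean log2 RoR: {ror.loc[syn, 'log2_ror'].mean():.3f} "
      "(shared enrichment cancels; the residual is chance overlap "
      "with the depleted mitochondrial set)")
print(f"mitochondria mean log2 RoR: {ror.loc[mito, 'log2_ror'].mean():.3f} "
      "(the knockout-specific depletion survives)")
print("significant classes:",
      ror["class"].value_counts().to_dict(), "\n")

ranking = ol.annotation_effect_ranking(ror, catalog)
print("Annotation effects ranked by delta mean, Cohen's d and RoR "
      "magnitude:")
print(ranking.round(3))
# mitochondria should rank 1 with delta_mean near -0.75 and a strongly
# negative Cohen's d; the other annotations sit near zero.
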