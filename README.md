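# olscape

Organelle proteome landscapes from multi-genotype quantitative proteomics.

`olscape` is a Python library for asking, across a panel of knockout cell
lines, *which organelles are remodeled, how similarly, and where proteins
move*. It was built for lysosomal-disease knockout panels profiled in
induced neurons (whole-cell proteomes, lysosome immunopurifications, and
soma/projection fractionations), but applies to any design with a wide
protein-abundance table, a sample design, and an annotation catalog of
subcellular/functional protein sets.

## What it computes

Given per-protein log2 fold changes (knockout vs control, Student's t with
Benjamini–Hochberg correction), the library provides:

- **Annotation-restricted correlation landscape.** For an annotation *A*
  and conditions *g*, *h* (genotype × cell type), the Pearson correlation
  r over proteins p ∈ A of the fold-change vectors,
  r(g, h | A) = corr( log2FC_g(p), log2FC_h(p) ), on pairwise-complete
  observations. Thresholded entries (r > 0.7 or r < −0.2) give
  circos-style link lists.
- **Composite organelle correlation map.** Per condition and annotation,
  the mean of r(g, h | A) over all same-cell-type peers h — a single
  correlation factor summarizing how the knockout reshapes that
  compartment — with disease-class mean ± SD summaries and hierarchical
  clustering of correlation profiles.
- **Ranked impact score.** Per annotation group: z-score the per-condition
  mean |log2FC| across conditions, average z over the group's annotations,
  and rank — a deterministic ordering of genotypes by how strongly they
  perturb a compartment system.
- **LysoIP co-enrichment.** Enrichment of each tagged group over untagged
  background cells; a co-enrichment threshold equal to the mean enrichment
  of lysosome-annotated proteins (inclusive ≥); per-organelle co-enriched
  counts; and knockout-vs-control Wilcoxon rank-sum shift tests (exact by
  enumeration at small n) with BH correction.
- **Ratio-of-ratios (RoR) spatial proteomics.**
  log2 RoR = (projection/whole-cell)_KO − (projection/whole-cell)_Control
  in log2 space, which cancels genotype-shared compartment composition;
  annotation effects ranked by delta mean, Cohen's d, and RoR magnitude.
- **Set utilities** — strict-threshold membership, exact Euler region
  counts, hypergeometric over-representation — and a **synthetic-data
  generator** that plants known annotation-level shifts into a realistic
  multi-genotype design so every statistic can be validated against ground
  truth.

See `docs/methods.md` for the model, conventions, and their rationale.

## Worked example

`examples/correlation_landscape.py` simulates a four-genotype panel in
which `GBA1_KO` and `ASAH1_KO` share a planted −1 log2 mitochondrial
depletion while `HEXA_KO` carries the opposite shift, then computes the
landscape:

```
Mitochondrial fold-change correlations between genotypes:
                (GBA1_KO, iN)  (ASAH1_KO, iN)  (HEXA_KO, iN)
(GBA1_KO, iN)           1.000           0.940         -0.842
(ASAH1_KO, iN)          0.940           1.000         -0.829
(HEXA_KO, iN)          -0.842          -0.829          1.000

Links retained at the display thresholds (r < -0.2 or r > 0.7):
      condition_a     condition_b      r
0   (GBA1_KO, iN)  (ASAH1_KO, iN)  0.940
1   (GBA1_KO, iN)   (HEXA_KO, iN) -0.842
2  (ASAH1_KO, iN)   (HEXA_KO, iN) -0.829
```

The two genotypes sharing the depletion correlate at r ≈ 0.94 — their
mitochondrial proteins move together — while each anti-correlates with the
opposite-shifted genotype at r ≈ −0.84; all three pairs survive the
display thresholds and would be drawn as links. The remaining examples
(`lysoip_coenrichment.py`, `spatial_ratio_of_ratios.py`,
`differential_and_qc.py`) walk the co-enrichment, ratio-of-ratios, and
QC/contrast/overlap capabilities the same way, each printing the numbers
it computes together with what they mean.

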