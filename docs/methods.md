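# Methods

## Scope and data model

`olscape` analyzes protein-level quantitative proteomics across a panel of
knockout genotypes, one or more cell types, and optionally several
subcellular fractions. It starts from three inputs: a proteins × samples
abundance matrix (raw intensities or log2; missing entries allowed and
never imputed), a sample design (genotype, cell type, fraction, replicate,
LysoIP tag status), and an annotation catalog of possibly overlapping,
possibly nested protein sets (e.g. OXPHOS inside mitochondria) with
optional annotation groups and a genotype → disease-class map. All
downstream statistics use pairwise-complete observations; missing values
propagate, they are never zero-filled.

## Preprocessing

Raw intensities are log2 transformed and each sample column is centered on
its median of present values — the single supported normalization
(total-intensity scaling reduces to the same operation after summation).
Row-z scaling (mean 0, sample sd 1 per protein) is provided for heatmap
style summaries; zero-variance rows map to zeros rather than missing so
summaries stay dense. QC reports, per (genotype, cell type): the number of
proteins quantified at least once and the median relative standard
deviation across replicates. RSD is computed on linear intensities
(100·sd/mean, the standard definition), over proteins present in every
replicate of the group; a single-replicate group has no RSD.

## Differential statistics

A contrast compares a test genotype against the reference genotype within
one cell type and fraction. Per protein, log2FC is the difference of group
means over present values; the p-value is a two-sided Student's
pooled-variance t-test (Welch available via `test_kind="welch"`), with at
least two values required per group for a p-value while log2FC is still
reported from a single value per group. Zero-variance rows use the
limiting behavior of the t statistic: equal constant groups give p = 1,
unequal constant groups give p = 0 (documented sentinels, not NaN).
Benjamini–Hochberg correction is applied within each contrast across
proteins, matching per-volcano q-values; it is delegated to
`statsmodels.stats.multitest` and verified in the test suite against a
hand-written step-up oracle on all permutations of small inputs. Cohen's d
uses the Bessel-corrected pooled standard deviation, with signed-infinity
sentinels when the pooled sd is zero. No moderation or shrinkage is
applied: fold changes are plain means.

## Correlation landscape

The core computation restricts each condition's (genotype, cell type)
log2FC vector to one annotation's proteins and computes Pearson
correlations between conditions on pairwise-complete entries (Spearman is
available behind a flag but never the default). Cells with fewer than
`min_proteins` (default 10) complete pairs are missing — Pearson on fewer
points is noise; the value is configurable.

The scalar "organelle correlation" of a condition is the mean of its
pairwise correlations to all other conditions of the same cell type,
restricted to the annotation; peers never mix cell types, and cross-cell-
type comparisons pair the same genotype's two cell-type conditions. The
composite map tabulates this scalar for every condition × annotation and
records the convention in a method tag (`mean-pairwise-within-celltype`).
An alternative orientation (annotation × annotation correlation of mean
log2FC profiles) exists; it is noted but not implemented. Disease-class
summaries report mean ± sample SD of composite entries per (class,
annotation, cell type); weighted class means recombine exactly to the
grand mean.

Link filtering retains upper-triangle entries with r < −0.2 or r > 0.7
(the defaults used for circos-style display), never the diagonal, with an
optional filter for links touching named conditions.

The ranked impact score summarizes how strongly each genotype perturbs an
annotation group: for each annotation A and condition g, m_A(g) is the
mean |log2FC| over A's quantified proteins; m_A is z-scored across the
cell type's conditions (sample sd; an sd below 1e-12 relative to the scale
of m maps all z to zero); the impact of g is the mean z over the group's
annotations, and conditions are ranked descending with ties broken by
genotype label so output is deterministic. This formula is a stated
convention recorded in the result's method tag so alternates can be
swapped in.

Hierarchical clustering of correlation profiles uses 1 − Pearson distance
between rows (pairwise-complete), average or complete linkage via
`scipy.cluster.hierarchy`, scipy's deterministic leaf order, and a
Newick-style text export with merge heights as branch lengths. Rows with
fewer than three non-missing entries are excluded with a warning.

## LysoIP co-enrichment

Enrichment of a tagged group is its log2 fold change over the untagged
background samples (the same contrast machinery); the untagged background
is required, never silently recentered. The co-enrichment threshold is the
mean enrichment of quantified lysosome-annotated proteins, computed within
each tagged group separately — the only choice that keeps a
control-vs-knockout comparison of co-enrichment meaningful — and the
boundary is inclusive (≥). Per-annotation counts are the numbers of
co-enriched members. Organelle shift tests compare an annotation's
enrichment values between knockout and control with a two-sided
Wilcoxon/Mann–Whitney rank-sum test: exact by full enumeration over group
assignments (midranks, so ties are handled) when the combined n is at most
12 (configurable), otherwise the tie-corrected normal approximation with
continuity correction from scipy; BH across annotations.

## Ratio-of-ratios spatial proteomics

Within a genotype, the fraction ratio is mean log2(projection) − mean
log2(whole cell) per protein; the log2 ratio of ratios subtracts the
control's fraction ratio from the knockout's. Compartment composition
shared by both genotypes cancels exactly, isolating genotype-specific
spatial redistribution. For significance, replicates are paired by index
within genotype (replicate i projection with replicate i whole cell,
the minimal choice when all samples share one TMT plex), and a Student's t
compares knockout vs control replicate-level ratios; classification is
up/down when q ≤ q_max (default 0.05) and |log2 RoR| ≥ min_abs (default
0). With triplicates this per-protein test is deliberately conservative;
annotation-level statistics carry the power. Annotation effects are
scored by three metrics — delta mean (annotation minus complement of
quantified proteins), Cohen's d, and mean |log2 RoR| — and ranked by the
unweighted mean of the three per-metric descending-magnitude ranks (ties
by label); each set also gets a two-sided Wilcoxon against its complement
with BH across sets.

## Set-level utilities

Threshold membership uses strict inequalities (e.g. log2FC > −0.75), with
missing values excluded. Euler overlap analysis returns exact region
counts for up to six sets (layout is presentation, not analysis). The
minimal over-representation test is a right-tail hypergeometric per
annotation against a caller-supplied background — by default all proteins
quantified in the contrast, standard practice — with BH across
annotations.

## Synthetic data generator

The generator emulates the structure of the target experimental design
rather than any raw dataset: a 23-knockout panel plus control (grouped into sphingolipidoses,
NCL, and integral-membrane-protein disorder classes), two induced-neuron
cell types, biological triplicates, 20 nested/overlapping organelle
annotations, log2 baselines ~Normal(10, 2), i.i.d. Gaussian replicate
noise in log2 space (0.25 log2 units by default, equivalently log-normal
intensities), and completely-at-random missingness (5% by default).
Effects are additive annotation-level mean log2 shifts per (genotype, cell
type), composing by summation when sets overlap. Three designs are
provided: the whole-cell landscape panel; a three-group LysoIP (untagged /
tagged control / tagged knockout) with a lysosomal enrichment factor and
optional knockout-specific organelle shifts; and a three-fraction spatial
design (whole cell / soma / projection) with genotype-shared compartment
profiles and knockout-specific projection shifts.

`effect_heterogeneity_sd` controls protein-intrinsic responsiveness:
each planted delta is spread across an annotation's members as
delta·(1 + h) with h ~ Normal(0, sd), recentred to mean 0 within the
annotation and shared across conditions. At the default 0 every member
shifts by exactly delta, so noiseless simulations recover planted values
exactly per protein. A homogeneous shift, however, makes an
annotation-restricted fold-change vector constant plus noise, whose
between-genotype correlation is driven only by the shared control term
(~0.5 at triplicate noise); shared per-protein responsiveness is the
minimal mechanism under which annotation correlations carry signal, and
the landscape-recovery validations therefore set it to 0.5.

Everything is a pure function of the config: one integer seed drives
separate documented streams (baselines, memberships, heterogeneity, noise,
missingness) derived by stable hashing of (purpose, seed), so identical
configs are bit-identical and adding one randomness source never perturbs
another.

### What the generator does and does not emulate

It reproduces replicate structure, annotation nesting/overlap, planted
organelle-level shifts, enrichment designs, and missingness rates. It does
not model peptide-level quantification, intensity-dependent missingness,
batch effects, TMT channel interference, or correlated biological
variation beyond the planted structure. Passing recovery tests therefore
demonstrates that the statistics measure what they claim under their own
assumptions — not that those assumptions hold in any particular real
dataset.

## Validation conditions and problem sizes

The acceptance checks (mirrored in `scripts/acceptance.py`) run at the
study's design scale: 5,000 proteins, 23 knockouts + control × 2 cell
types × 3 replicates for recovery and null calibration (planted
annotation-mean deltas recovered within ±0.05 for sets of ≥300 proteins;
null BH false-discovery fraction ≤5% over 20 seeds; mean
Kolmogorov–Smirnov statistic of null p-values <0.02 over 10 seeds);
100-seed panels at 1,000–2,000 proteins for correlation-link recovery
(r > 0.7 shared / r < −0.2 opposed), impact-ranking recovery, and
ratio-of-ratios recovery (planted −0.75 within ±0.1 with correct effect
sign). Shared-compartment cancellation is asserted on the pooled mean over
10 seeds within 3 pooled standard errors — a per-seed 3·SEM assertion
rejects an exactly calibrated null ~0.3% of the time by construction, so
the pooled estimate (a tighter absolute tolerance) is the primary check,
with the first seed also asserted individually. Co-enrichment flags,
thresholds and counts are compared against exhaustive recomputation on a
1,000-protein LysoIP instance.

## Known limitations

- The composite-map and impact-score conventions are defined choices among
  several defensible summaries; both are recorded in output method tags.
- The per-protein RoR t-test at n = 3 vs 3 is underpowered by design;
  interpret per-protein classes alongside the annotation-level ranking.
- Correlations below `min_proteins` complete pairs are reported missing
  and silently excluded from means — small annotations can drop out of
  the composite map entirely.
- No batch correction, cross-plex normalization, imputation, or moderated
  statistics; inputs are assumed to be single-plex or already harmonized.
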