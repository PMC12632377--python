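"""Synthetic multi-genotype proteome generator with planted ground truth.

Emulates the structure of the study data the pipeline is built for: a panel
of knockout genotypes plus a control, differentiated into one or two neuron
types, quantified in replicate with log-normal intensities (i.i.d. Gaussian
noise in log2 space), overlapping subcellular annotation sets, planted
annotation-level mean log2 shifts per genotype x cell type, completely-at-
random missingness, a three-group LysoIP design (untagged / tagged control /
tagged KO) with a lysosomal enrichment factor, and a three-fraction spatial
design (whole cell / soma / projection).

Every generator is a pure function of its ``SimConfig``: the same seed gives
bit-identical output. Sub-streams are derived by stable hashing of
(purpose, seed) so adding one source of randomness never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    AbundanceMatrix,
    AnnotationCatalog,
    SampleRecord,
    StudyDesign,
    ValidationError,
)

#: The study's knockout panel: 23 lysosomal-disease genes grouped into
#: sphingolipidoses, NCL, and integral-membrane-protein disorder classes.
LSD_GENOTYPES = (
    "GBA1_KO", "ASAH1_KO", "HEXA_KO", "HEXB_KO", "PSAP_KO", "SMPD1_KO",
    "CLN1_KO", "CLN2_KO", "CLN3_KO", "DNAJC5_KO", "CLN5_KO", "CLN6_KO",
    "CLN7_KO", "CLN8_KO", "ATP13A2_KO", "GRN_KO", "CTSD_KO", "CTSF_KO",
    "MCOLN1_KO", "NPC1_KO", "NPC2_KO", "LIPA_KO", "GAA_KO",
)

DISEASE_CLASSES = {
    "Control": "Control",
    **{g: "Sphingolipidoses" for g in
       ("GBA1_KO", "ASAH1_KO", "HEXA_KO", "HEXB_KO", "PSAP_KO", "SMPD1_KO")},
    **{g: "NCL" for g in
       ("CLN1_KO", "CLN2_KO", "CLN3_KO", "DNAJC5_KO", "CLN5_KO", "CLN6_KO",
        "CLN7_KO", "CLN8_KO", "GRN_KO", "CTSD_KO", "CTSF_KO")},
    **{g: "IMPD" for g in
       ("ATP13A2_KO", "MCOLN1_KO", "NPC1_KO", "NPC2_KO", "LIPA_KO", "GAA_KO")},
}

#: 20 organelle/functional annotations (label, size, parent) with nesting
#: mirroring common subcellular catalogs (OXPHOS inside mitochondria, etc.).
DEFAULT_ANNOTATIONS: tuple[tuple[str, int, str | None], ...] = (
    ("nucleus", 800, None),
    ("ER", 600, None),
    ("mitochondria", 600, None),
    ("OXPHOS", 140, "mitochondria"),
    ("mtComplexI", 40, "OXPHOS"),
    ("mito_matrix", 180, "mitochondria"),
    ("Golgi", 250, None),
    ("plasma_membrane", 500, None),
    ("cytoskeleton", 350, None),
    ("ribosome", 150, None),
    ("proteasome", 60, None),
    ("peroxisome", 80, None),
    ("lysosome", 250, None),
    ("endosome", 200, None),
    ("early_endosome", 90, "endosome"),
    ("recycling_endosome", 70, "endosome"),
    ("SynapseSV", 150, None),
    ("SynGO", 220, None),
    ("SV_fusion", 50, "SynapseSV"),
    ("vATPase", 22, None),
)

DEFAULT_GROUPS = {
    "vesicular": ("lysosome", "endosome", "early_endosome",
                  "recycling_endosome", "SynapseSV", "SynGO", "SV_fusion"),
    "mitochondrial": ("mitochondria", "OXPHOS", "mtComplexI", "mito_matrix"),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the emulated study: a 23-knockout panel plus control,
    both neuron types, biological triplicates, log2 intensity baselines
    around 10 with spread 2, replicate noise of 0.25 log2 units, and 5%
    missing values. ``effects`` plants annotation-level mean log2 shifts as
    (genotype, cell_type, annotation, delta). ``effect_heterogeneity_sd``
    spreads each planted delta across an annotation's proteins as
    delta * (1 + h), h ~ Normal(0, sd) recentred to mean 0 within the
    annotation, shared across conditions — the protein-intrinsic
    responsiveness that makes annotation-restricted correlations between
    genotypes informative. At 0 (default) every member shifts by exactly
    delta.
    """

    n_proteins: int = 5000
    genotypes: tuple[str, ...] = ("Control",) + LSD_GENOTYPES
    control_genotype: str = "Control"
    cell_types: tuple[str, ...] = ("iN", "iDA")
    n_replicates: int = 3
    annotations: tuple[tuple[str, int, str | None], ...] = DEFAULT_ANNOTATIONS
    effects: tuple[tuple[str, str, str, float], ...] = ()
    noise_sd: float = 0.25
    baseline_mean: float = 10.0
    baseline_sd: float = 2.0
    missing_rate: float = 0.05
    effect_heterogeneity_sd: float = 0.0
    seed: int = 0
    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    disease_classes: dict[str, str] = field(
        default_factory=lambda: dict(DISEASE_CLASSES)
    )

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValidationError("noise_sd and baseline_sd must be >= 0")
        if self.control_genotype not in self.genotypes:
            raise ValidationError("control genotype missing from genotypes")
        labels = [a[0] for a in self.annotations]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate annotation labels")
        for label, size, parent in self.annotations:
            if size > self.n_proteins:
                raise ValidationError(
                    f"annotation {label!r} larger than the proteome"
                )
            if parent is not None and parent not in labels:
                raise ValidationError(
                    f"annotation {label!r} has unknown parent {parent!r}"
                )
        seen = set()
        for g, ct, a, _ in self.effects:
            if a not in labels:
                raise ValidationError(f"effect on unknown annotation {a!r}")
            if g == self.control_genotype:
                raise ValidationError("effects cannot target the control")
            if g not in self.genotypes or ct not in self.cell_types:
                raise ValidationError(f"effect on unknown condition ({g}, {ct})")
            key = (g, ct, a)
            if key in seen:
                raise ValidationError(f"contradictory effects for {key}")
            seen.add(key)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth: planted deltas, memberships, and per-protein shifts.

    ``shifts`` has one column per condition key (e.g. ``"GBA1_KO|iDA"``) and
    records each protein's total planted log2 shift in that condition; the
    per-annotation mean shift equals the planted delta by construction.
    """

    effects: dict[tuple[str, str, str], float]
    membership: dict[str, frozenset[str]]
    shifts: pd.DataFrame

    def annotation_mean_shift(self, genotype: str, cell_type: str,
                              annotation: str) -> float:
        col = f"{genotype}|{cell_type}"
        members = sorted(self.membership[annotation])
        return float(self.shifts.loc[members, col].mean())


def _rng(seed: int, purpose: str) -> np.random.Generator:
    return np.random.default_rng(
        [int(seed) % (2**31), zlib.crc32(purpose.encode("utf-8"))]
    )


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _build_catalog(cfg: SimConfig) -> tuple[dict[str, frozenset[str]], AnnotationCatalog]:
    """Draw annotation memberships (children nested inside parents)."""
    rng = _rng(cfg.seed, "membership")
    proteins = np.array(_protein_ids(cfg.n_proteins))
    sets: dict[str, frozenset[str]] = {}
    for label, size, parent in cfg.annotations:
        pool = np.array(sorted(sets[parent])) if parent else proteins
        if size > len(pool):
            raise ValidationError(
                f"annotation {label!r} larger than its parent pool"
            )
        chosen = rng.choice(pool, size=size, replace=False)
        sets[label] = frozenset(chosen.tolist())
    catalog = AnnotationCatalog(
        sets=sets, groups=cfg.groups, disease_class=cfg.disease_classes
    )
    return sets, catalog


def _heterogeneity(cfg: SimConfig, sets: dict[str, frozenset[str]],
                   index: pd.Index) -> dict[str, pd.Series]:
    """Per-annotation protein response multipliers (mean exactly 1)."""
    rng = _rng(cfg.seed, "heterogeneity")
    out: dict[str, pd.Series] = {}
    for label, _, _ in cfg.annotations:
        members = sorted(sets[label])
        if cfg.effect_heterogeneity_sd > 0 and len(members) > 1:
            h = rng.normal(0.0, cfg.effect_heterogeneity_sd, size=len(members))
            h = h - h.mean()
        else:
            h = np.zeros(len(members))
        out[label] = pd.Series(1.0 + h, index=members)
    return out


def _apply_missing(values: np.ndarray, cfg: SimConfig,
                   purpose: str) -> np.ndarray:
    if cfg.missing_rate > 0:
        mask = _rng(cfg.seed, purpose).random(values.shape) < cfg.missing_rate
        values = np.where(mask, np.nan, values)
    return values


def simulate_landscape(
    cfg: SimConfig,
) -> tuple[AbundanceMatrix, StudyDesign, AnnotationCatalog, PlantedTruth]:
    """Whole-cell abundance panel across genotypes x cell types x replicates.

    sample value = protein baseline + planted shift (KO conditions only)
    + Normal(0, noise_sd), then masked missing at ``missing_rate``.
    """
    proteins = _protein_ids(cfg.n_proteins)
    index = pd.Index(proteins, name="protein_id")
    sets, catalog = _build_catalog(cfg)
    mult = _heterogeneity(cfg, sets, index)

    baselines = _rng(cfg.seed, "baseline").normal(
        cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_proteins
    )

    conditions = [
        (g, ct) for g in cfg.genotypes for ct in cfg.cell_types
    ]
    shifts = pd.DataFrame(
        0.0, index=index, columns=[f"{g}|{ct}" for g, ct in conditions]
    )
    effects = {}
    for g, ct, a, delta in cfg.effects:
        effects[(g, ct, a)] = float(delta)
        contrib = delta * mult[a]
        shifts.loc[contrib.index, f"{g}|{ct}"] += contrib.to_numpy()

    records: list[SampleRecord] = []
    columns: list[str] = []
    cols_values: list[np.ndarray] = []
    noise_rng = _rng(cfg.seed, "noise")
    for g, ct in conditions:
        shift = shifts[f"{g}|{ct}"].to_numpy()
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"{g}.{ct}.r{rep}"
            records.append(
                SampleRecord(
                    sample_id=sid, genotype=g, cell_type=ct,
                    fraction="whole_cell", replicate=rep,
                )
            )
            noise = (
                noise_rng.normal(0.0, cfg.noise_sd, size=cfg.n_proteins)
                if cfg.noise_sd > 0 else 0.0
            )
            columns.append(sid)
            cols_values.append(baselines + shift + noise)

    values = _apply_missing(np.column_stack(cols_values), cfg, "missing")
    matrix = AbundanceMatrix(
        data=pd.DataFrame(values, index=index, columns=columns), scale="log2"
    )
    design = StudyDesign(samples=tuple(records),
                         control_genotype=cfg.control_genotype)
    truth = PlantedTruth(
        effects=effects,
        membership=dict(sets),
        shifts=shifts,
    )
    return matrix, design, catalog, truth


def simulate_lysoip(
    cfg: SimConfig,
    lyso_enrichment: float = 3.0,
    ko_organelle_shifts: tuple[tuple[str, float], ...] = (),
    lysosome_label: str = "lysosome",
) -> tuple[AbundanceMatrix, StudyDesign, AnnotationCatalog, PlantedTruth]:
    """Three-group LysoIP design: untagged / tagged control / tagged KO.

    Tagged samples add ``lyso_enrichment`` log2 units to lysosome-annotated
    proteins; the tagged KO additionally applies each (annotation, delta) in
    ``ko_organelle_shifts``. The untagged group is the parental (control
    genotype, untagged) background; the KO genotype is the first
    non-control genotype of the config.
    """
    labels = [a[0] for a in cfg.annotations]
    if lysosome_label not in labels:
        raise ValidationError(
            f"catalog must contain a {lysosome_label!r} annotation"
        )
    for a, _ in ko_organelle_shifts:
        if a not in labels:
            raise ValidationError(f"KO shift on unknown annotation {a!r}")
    ko = next(
        (g for g in cfg.genotypes if g != cfg.control_genotype), None
    )
    if ko is None:
        raise ValidationError("config needs at least one non-control genotype")

    proteins = _protein_ids(cfg.n_proteins)
    index = pd.Index(proteins, name="protein_id")
    sets, catalog = _build_catalog(cfg)
    mult = _heterogeneity(cfg, sets, index)
    baselines = _rng(cfg.seed, "baseline").normal(
        cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_proteins
    )

    lyso = pd.Series(0.0, index=index)
    contrib = lyso_enrichment * mult[lysosome_label]
    lyso.loc[contrib.index] += contrib.to_numpy()

    ko_shift = pd.Series(0.0, index=index)
    effects: dict[tuple[str, str, str], float] = {}
    for a, delta in ko_organelle_shifts:
        effects[(ko, "HeLa", a)] = float(delta)
        contrib = delta * mult[a]
        ko_shift.loc[contrib.index] += contrib.to_numpy()

    group_shifts = {
        (cfg.control_genotype, "untagged"): np.zeros(cfg.n_proteins),
        (cfg.control_genotype, "tagged"): lyso.to_numpy(),
        (ko, "tagged"): lyso.to_numpy() + ko_shift.to_numpy(),
    }

    records, columns, cols_values = [], [], []
    noise_rng = _rng(cfg.seed, "noise")
    for (genotype, tag), shift in group_shifts.items():
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"{genotype}.{tag}.r{rep}"
            records.append(
                SampleRecord(
                    sample_id=sid, genotype=genotype, cell_type="HeLa",
                    fraction="lysoip", replicate=rep, tag_status=tag,
                )
            )
            noise = (
                noise_rng.normal(0.0, cfg.noise_sd, size=cfg.n_proteins)
                if cfg.noise_sd > 0 else 0.0
            )
            columns.append(sid)
            cols_values.append(baselines + shift + noise)

    values = _apply_missing(np.column_stack(cols_values), cfg, "missing")
    matrix = AbundanceMatrix(
        data=pd.DataFrame(values, index=index, columns=columns), scale="log2"
    )
    design = StudyDesign(samples=tuple(records),
                         control_genotype=cfg.control_genotype)
    shifts = pd.DataFrame(
        {f"{g}|{tag}": s for (g, tag), s in group_shifts.items()}, index=index
    )
    truth = PlantedTruth(effects=effects, membership=dict(sets), shifts=shifts)
    return matrix, design, catalog, truth


def simulate_spatial(
    cfg: SimConfig,
    compartment_profiles: dict[str, tuple[float, float]] | None = None,
    ko_projection_shifts: tuple[tuple[str, float], ...] = (),
    cell_type: str = "iN",
) -> tuple[AbundanceMatrix, StudyDesign, AnnotationCatalog, PlantedTruth]:
    """Three-fraction spatial design: whole cell, soma, projection.

    ``compartment_profiles`` maps annotation -> (soma delta, projection
    delta), applied identically in every genotype (shared compartment
    composition, which cancels in the ratio-of-ratios);
    ``ko_projection_shifts`` are genotype-specific projection deltas applied
    only in the KO (the first non-control genotype).
    """
    labels = [a[0] for a in cfg.annotations]
    compartment_profiles = compartment_profiles or {}
    for a in compartment_profiles:
        if a not in labels:
            raise ValidationError(f"profile for unknown annotation {a!r}")
    for a, _ in ko_projection_shifts:
        if a not in labels:
            raise ValidationError(f"KO shift on unknown annotation {a!r}")
    ko = next((g for g in cfg.genotypes if g != cfg.control_genotype), None)
    if ko is None:
        raise ValidationError("config needs at least one non-control genotype")
    genotypes = (cfg.control_genotype, ko)

    proteins = _protein_ids(cfg.n_proteins)
    index = pd.Index(proteins, name="protein_id")
    sets, catalog = _build_catalog(cfg)
    mult = _heterogeneity(cfg, sets, index)
    baselines = _rng(cfg.seed, "baseline").normal(
        cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_proteins
    )

    soma = pd.Series(0.0, index=index)
    proj = pd.Series(0.0, index=index)
    for a, (d_soma, d_proj) in compartment_profiles.items():
        soma.loc[sorted(sets[a])] += d_soma * mult[a].to_numpy()
        proj.loc[sorted(sets[a])] += d_proj * mult[a].to_numpy()
    ko_proj = pd.Series(0.0, index=index)
    effects: dict[tuple[str, str, str], float] = {}
    for a, delta in ko_projection_shifts:
        effects[(ko, cell_type, a)] = float(delta)
        ko_proj.loc[sorted(sets[a])] += delta * mult[a].to_numpy()

    fraction_shift = {
        "whole_cell": pd.Series(0.0, index=index),
        "soma": soma,
        "projection": proj,
    }

    records, columns, cols_values = [], [], []
    noise_rng = _rng(cfg.seed, "noise")
    shift_cols = {}
    for genotype in genotypes:
        for fraction in ("whole_cell", "soma", "projection"):
            shift = fraction_shift[fraction].to_numpy().copy()
            if genotype == ko and fraction == "projection":
                shift = shift + ko_proj.to_numpy()
            shift_cols[f"{genotype}|{cell_type}|{fraction}"] = shift
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{genotype}.{fraction}.r{rep}"
                records.append(
                    SampleRecord(
                        sample_id=sid, genotype=genotype, cell_type=cell_type,
                        fraction=fraction, replicate=rep,
                    )
                )
                noise = (
                    noise_rng.normal(0.0, cfg.noise_sd, size=cfg.n_proteins)
                    if cfg.noise_sd > 0 else 0.0
                )
                columns.append(sid)
                cols_values.append(baselines + shift + noise)

    values = _apply_missing(np.column_stack(cols_values), cfg, "missing")
    matrix = AbundanceMatrix(
        data=pd.DataFrame(values, index=index, columns=columns), scale="log2"
    )
    design = StudyDesign(samples=tuple(records),
                         control_genotype=cfg.control_genotype)
    truth = PlantedTruth(
        effects=effects,
        membership=dict(sets),
        shifts=pd.DataFrame(shift_cols, index=index),
    )
    return matrix, design, catalog, truth


def null_config(**overrides) -> SimConfig:
    """A no-effect configuration (global null) with optional overrides."""
    return replace(SimConfig(), effects=(), **overrides)
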