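"""Per-protein contrasts: fold changes, t-tests, BH correction, effect sizes.

A contrast compares one genotype against the reference genotype within a
cell type and fraction. The result — a long "fold-change table" with one row
per protein per contrast (log2fc, p, q, replicate counts, -log10 transforms)
— is the substrate for every landscape statistic downstream. The default
test is a Student's pooled-variance t (Welch available via ``test_kind``),
with Benjamini-Hochberg correction applied within each contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust as _bh
from ._stats import two_sample_t
from .model import AbundanceMatrix, AnnotationCatalog, StudyDesign, ValidationError

logger = logging.getLogger(__name__)

FC_COLUMNS = [
    "protein_id",
    "genotype",
    "cell_type",
    "fraction",
    "log2fc",
    "p",
    "q",
    "n_test",
    "n_ref",
    "neglog10p",
    "neglog10q",
]


@dataclass(frozen=True)
class ContrastSpec:
    """test genotype vs reference genotype within one cell type / fraction."""

    test_genotype: str
    reference_genotype: str
    cell_type: str
    fraction: str = "whole_cell"

    def __post_init__(self) -> None:
        if self.test_genotype == self.reference_genotype:
            raise ValidationError("test and reference genotypes must differ")


@dataclass(frozen=True)
class EffectSize:
    delta_mean: float
    cohens_d: float


def compute_contrast(
    m: AbundanceMatrix,
    design: StudyDesign,
    contrast: ContrastSpec,
    test_kind: str = "student",
) -> pd.DataFrame:
    """Fold-change table for one contrast (columns ``FC_COLUMNS``).

    log2fc = mean(test) - mean(ref) over present values; p only where both
    groups have >= 2 values; rows missing in both groups are dropped.
    """
    if m.scale != "log2":
        raise ValidationError("compute_contrast requires a log2-scale matrix")
    test_cols = design.select(
        genotype=contrast.test_genotype,
        cell_type=contrast.cell_type,
        fraction=contrast.fraction,
    )
    ref_cols = design.select(
        genotype=contrast.reference_genotype,
        cell_type=contrast.cell_type,
        fraction=contrast.fraction,
    )
    if not test_cols or not ref_cols:
        raise ValidationError(
            f"empty group for contrast {contrast}: "
            f"test n={len(test_cols)}, ref n={len(ref_cols)}"
        )
    test = m.data[test_cols].to_numpy()
    ref = m.data[ref_cols].to_numpy()
    log2fc, p, nt, nr = two_sample_t(test, ref, kind=test_kind)
    keep = (nt >= 1) | (nr >= 1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("compute_contrast: dropped %d all-missing protein(s)", dropped)
    fc = pd.DataFrame(
        {
            "protein_id": np.asarray(m.protein_ids)[keep],
            "genotype": contrast.test_genotype,
            "cell_type": contrast.cell_type,
            "fraction": contrast.fraction,
            "log2fc": np.where((nt >= 1) & (nr >= 1), log2fc, np.nan)[keep],
            "p": p[keep],
            "n_test": nt[keep],
            "n_ref": nr[keep],
        }
    )
    fc["q"] = _bh(fc["p"].to_numpy())
    with np.errstate(divide="ignore"):
        fc["neglog10p"] = -np.log10(fc["p"])
        fc["neglog10q"] = -np.log10(fc["q"])
    return fc[FC_COLUMNS]


def compute_all_contrasts(
    m: AbundanceMatrix,
    design: StudyDesign,
    cell_types: list[str] | None = None,
    fraction: str = "whole_cell",
    test_kind: str = "student",
) -> pd.DataFrame:
    """Every KO-vs-control contrast present in the design, concatenated."""
    frames = []
    seen_ct = cell_types or sorted({s.cell_type for s in design.samples})
    for genotype in design.genotypes:
        if genotype == design.control_genotype:
            continue
        for ct in seen_ct:
            if not design.select(genotype=genotype, cell_type=ct, fraction=fraction):
                continue
            spec = ContrastSpec(genotype, design.control_genotype, ct, fraction)
            frames.append(compute_contrast(m, design, spec, test_kind=test_kind))
    if not frames:
        raise ValidationError("no contrasts resolvable from the design")
    return pd.concat(frames, ignore_index=True)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (missing entries pass through)."""
    return _bh(p)


def cohens_d(test, ref) -> EffectSize:
    """Standardized mean difference with Bessel-corrected pooled sd.

    Zero pooled sd yields a signed infinity when the means differ and 0 when
    they agree (documented sentinels rather than NaN).
    """
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if len(test) < 2 or len(ref) < 2:
        raise ValidationError("cohens_d requires >= 2 values per group")
    delta = float(test.mean() - ref.mean())
    nt, nr = len(test), len(ref)
    pooled = np.sqrt(
        ((nt - 1) * test.var(ddof=1) + (nr - 1) * ref.var(ddof=1)) / (nt + nr - 2)
    )
    if pooled == 0:
        d = 0.0 if delta == 0 else float(np.sign(delta) * np.inf)
    else:
        d = delta / float(pooled)
    return EffectSize(delta_mean=delta, cohens_d=d)


def count_significant(
    fc: pd.DataFrame,
    catalog: AnnotationCatalog,
    q_max: float = 0.05,
    min_abs_log2fc: float = 0.0,
) -> pd.DataFrame:
    """Per-annotation counts of significant up / down proteins.

    up: q <= q_max and log2fc >= min_abs_log2fc; down: q <= q_max and
    log2fc <= -min_abs_log2fc. A protein in k annotations contributes to
    all k.
    """
    sig = fc[fc["q"].notna() & (fc["q"] <= q_max)]
    up_ids = set(sig.loc[sig["log2fc"] >= min_abs_log2fc, "protein_id"])
    down_ids = set(sig.loc[sig["log2fc"] <= -min_abs_log2fc, "protein_id"])
    rows = []
    for label, members in catalog.sets.items():
        rows.append(
            {
                "annotation": label,
                "up": len(members & up_ids),
                "down": len(members & down_ids),
            }
        )
    return pd.DataFrame(rows).set_index("annotation")
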