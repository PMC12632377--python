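"""LysoIP analysis: enrichment over untagged cells and co-enrichment.

Lysosomes are immunopurified via a tagged lysosomal membrane protein;
parental untagged cells define the non-specific background. Per tagged
group, each protein's enrichment is its log2 fold change over the untagged
samples. The co-enrichment threshold of a tagged group is the mean
enrichment of its lysosome-annotated proteins; proteins at or above that
mean are "co-enriched", and counting co-enriched members per annotation
asks which compartments co-purify with lysosomes. Organelle shift tests
compare an annotation's enrichment distribution between KO and control
LysoIPs with a two-sided Wilcoxon rank-sum test and BH correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, ranksum_test, two_sample_t
from .differential import count_significant
from .model import AbundanceMatrix, AnnotationCatalog, StudyDesign, ValidationError

logger = logging.getLogger(__name__)

EXACT_MAX_COMBINED_N = 12


@dataclass
class CoEnrichmentResult:
    group: str
    threshold: float
    flags: pd.Series  # protein_id -> bool (enrich_log2fc >= threshold)
    counts: pd.Series  # annotation -> co-enriched member count
    enrichment: pd.Series  # protein_id -> enrich_log2fc (the inputs)


def enrichment_vs_untagged(
    m: AbundanceMatrix,
    design: StudyDesign,
    tagged_genotype: str,
    test_kind: str = "student",
) -> pd.DataFrame:
    """Per-protein tagged-vs-untagged enrichment for one genotype's LysoIP.

    Returns columns protein_id, group, enrich_log2fc, p, q, n_test, n_ref.
    The untagged background group is required.
    """
    if m.scale != "log2":
        raise ValidationError("enrichment requires a log2-normalized matrix")
    tagged = design.select(
        genotype=tagged_genotype, fraction="lysoip", tag_status="tagged"
    )
    untagged = design.select(fraction="lysoip", tag_status="untagged")
    if len(tagged) < 2 or len(untagged) < 2:
        raise ValidationError(
            "both tagged and untagged LysoIP groups need >= 2 replicates"
        )
    test = m.data[tagged].to_numpy()
    ref = m.data[untagged].to_numpy()
    log2fc, p, nt, nr = two_sample_t(test, ref, kind=test_kind)
    keep = (nt >= 1) & (nr >= 1)
    out = pd.DataFrame(
        {
            "protein_id": np.asarray(m.protein_ids)[keep],
            "group": tagged_genotype,
            "enrich_log2fc": log2fc[keep],
            "p": p[keep],
            "n_test": nt[keep],
            "n_ref": nr[keep],
        }
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def coenrichment_flags(
    enrichment: pd.DataFrame,
    catalog: AnnotationCatalog,
    lysosome_label: str = "lysosome",
) -> CoEnrichmentResult:
    """Flag proteins at or above the group's mean lysosomal enrichment.

    threshold = mean enrich_log2fc over quantified lysosome-annotated
    proteins; the boundary is inclusive (>=). Per-annotation counts are the
    numbers of co-enriched members.
    """
    e = enrichment.set_index("protein_id")["enrich_log2fc"].dropna()
    lyso = catalog.restrict(lysosome_label, e.index)
    if not lyso:
        raise ValidationError(
            f"no quantified proteins in annotation {lysosome_label!r}"
        )
    threshold = float(e.loc[sorted(lyso)].mean())
    flags = e >= threshold
    counts = pd.Series(
        {
            label: int(flags.reindex(sorted(members)).fillna(False).sum())
            for label, members in catalog.sets.items()
        },
        name="co_enriched",
    )
    group = str(enrichment["group"].iloc[0]) if "group" in enrichment else ""
    return CoEnrichmentResult(
        group=group, threshold=threshold, flags=flags, counts=counts,
        enrichment=e,
    )


def organelle_shift_test(
    e_control: pd.DataFrame,
    e_ko: pd.DataFrame,
    catalog: AnnotationCatalog,
    min_members: int = 3,
    exact_max_n: int = EXACT_MAX_COMBINED_N,
) -> pd.DataFrame:
    """Wilcoxon rank-sum of per-annotation enrichment, KO vs control.

    Two-sided; exact by enumeration when the combined number of values is
    <= ``exact_max_n``, else the tie-corrected normal approximation. BH
    across tested annotations. Annotations with fewer than ``min_members``
    quantified members in either table are skipped with a warning.
    """
    ctrl = e_control.set_index("protein_id")["enrich_log2fc"].dropna()
    ko = e_ko.set_index("protein_id")["enrich_log2fc"].dropna()
    shared = ctrl.index.intersection(ko.index)
    ctrl, ko = ctrl.loc[shared], ko.loc[shared]
    rows = []
    for label, members in catalog.sets.items():
        ids = sorted(frozenset(members) & frozenset(shared))
        if len(ids) < min_members:
            logger.warning(
                "organelle_shift_test: annotation %r skipped (<%d members)",
                label, min_members,
            )
            continue
        x = ko.loc[ids].to_numpy()
        y = ctrl.loc[ids].to_numpy()
        stat, p = ranksum_test(x, y, exact_max_n=exact_max_n)
        rows.append(
            {"annotation": label, "statistic": stat, "p": p, "n": len(ids)}
        )
    out = pd.DataFrame(rows, columns=["annotation", "statistic", "p", "n"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out.set_index("annotation")


def per_organelle_significance(
    fc_lysoip: pd.DataFrame,
    catalog: AnnotationCatalog,
    q_max: float = 0.05,
    min_abs_log2fc: float = 0.0,
) -> pd.DataFrame:
    """Significant up/down counts per annotation on a LysoIP contrast."""
    fc = fc_lysoip.rename(columns={"enrich_log2fc": "log2fc"})
    return count_significant(
        fc, catalog, q_max=q_max, min_abs_log2fc=min_abs_log2fc
    )
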