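"""The correlation landscape: annotation-restricted fold-change correlations.

Core idea: restrict each condition's (genotype, cell type) log2 fold-change
vector to the proteins of one annotation and correlate it against other
conditions. This yields, per annotation, a condition x condition Pearson
matrix; summarizing each condition against its same-cell-type peers gives
the composite condition x annotation "organelle correlation map"; thresholded
entries of the per-annotation matrices give the circos link lists; z-scored
mean |log2FC| over an annotation group gives the ranked impact score; and
hierarchical clustering of correlation profiles groups genotypes by how
similarly their organelles respond.

Pearson is the correlation throughout (Spearman behind a flag); all
correlations use pairwise-complete proteins and require ``min_proteins``
(default 10) complete pairs per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._stats import pairwise_complete_corr
from .model import AnnotationCatalog, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_PROTEINS = 10
COMPOSITE_METHOD = "mean-pairwise-within-celltype"


class Condition(NamedTuple):
    genotype: str
    cell_type: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.genotype}|{self.cell_type}"


@dataclass
class AnnotationCorrelationMatrix:
    annotation: str
    conditions: list[Condition]
    r: pd.DataFrame
    n_pairs: pd.DataFrame
    empty: bool = False


@dataclass
class CompositeMap:
    """Condition x annotation matrix of organelle correlation factors."""

    values: pd.DataFrame  # index: Condition tuples, columns: annotations
    method: str = COMPOSITE_METHOD


@dataclass
class ImpactRanking:
    """Per-condition impact (z units) over an annotation group, ranked."""

    impact: pd.DataFrame  # genotype, impact, rank
    components: pd.DataFrame  # genotype x annotation z-scores
    group: str
    cell_type: str
    method: str = "z-scored mean |log2FC| averaged over group annotations"


@dataclass
class ClusterResult:
    labels: list[str]
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    heights: list[float]

    def to_newick(self) -> str:
        """Nested-parenthesis text with merge heights as branch lengths."""
        n = len(self.labels)
        nodes: dict[int, tuple[str, float]] = {
            i: (self.labels[i], 0.0) for i in range(n)
        }
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            (sa, ha), (sb, hb) = nodes[int(a)], nodes[int(b)]
            text = f"({sa}:{h - ha:.6g},{sb}:{h - hb:.6g})"
            nodes[n + k] = (text, float(h))
        return nodes[n + len(self.linkage_matrix) - 1][0] + ";"


def conditions_in(fc: pd.DataFrame,
                  exclude_genotype: str | None = None) -> list[Condition]:
    """Distinct (genotype, cell_type) conditions present in a fold-change table."""
    seen = fc[["genotype", "cell_type"]].drop_duplicates()
    out = [
        Condition(g, ct)
        for g, ct in seen.itertuples(index=False)
        if g != exclude_genotype
    ]
    return out


def pivot_log2fc(fc: pd.DataFrame,
                 conditions: Sequence[Condition] | None = None) -> pd.DataFrame:
    """Proteins x conditions wide table of log2fc values."""
    wide = fc.pivot_table(
        index="protein_id",
        columns=["genotype", "cell_type"],
        values="log2fc",
        aggfunc="first",
    )
    if conditions is not None:
        wide = wide.reindex(columns=pd.MultiIndex.from_tuples(conditions))
    wide.columns = _cond_index([Condition(*c) for c in wide.columns])
    return wide


def _cond_index(conds: Sequence[Condition]) -> pd.Index:
    # plain object index of Condition tuples (not a MultiIndex)
    return pd.Index(list(conds), dtype=object, tupleize_cols=False)


def annotation_correlation(
    fc: pd.DataFrame,
    catalog: AnnotationCatalog,
    annotation: str,
    conditions: Sequence[Condition] | None = None,
    min_proteins: int = DEFAULT_MIN_PROTEINS,
    method: str = "pearson",
) -> AnnotationCorrelationMatrix:
    """Condition x condition correlation of annotation-restricted log2fc.

    Pairwise-complete Pearson (unit diagonal); cells with fewer than
    ``min_proteins`` complete pairs are missing. An annotation with too few
    quantified proteins overall yields a matrix flagged ``empty``.
    """
    conds = list(conditions) if conditions is not None else conditions_in(fc)
    wide = pivot_log2fc(fc, conds)
    members = catalog.restrict(annotation, wide.index)
    sub = wide.loc[sorted(members)]
    quantified = int(sub.notna().any(axis=1).sum())
    k = len(conds)
    if quantified < min_proteins:
        nanmat = pd.DataFrame(
            np.nan, index=_cond_index(conds), columns=_cond_index(conds)
        )
        return AnnotationCorrelationMatrix(
            annotation=annotation, conditions=conds, r=nanmat,
            n_pairs=nanmat.fillna(0).astype(int), empty=True,
        )
    r, n_pairs = pairwise_complete_corr(
        sub.to_numpy(), min_n=min_proteins, method=method
    )
    np.fill_diagonal(r, 1.0)
    idx = _cond_index(conds)
    return AnnotationCorrelationMatrix(
        annotation=annotation,
        conditions=conds,
        r=pd.DataFrame(r, index=idx, columns=idx),
        n_pairs=pd.DataFrame(n_pairs, index=idx, columns=idx),
    )


def organelle_correlation(
    fc: pd.DataFrame,
    catalog: AnnotationCatalog,
    annotation: str,
    condition: Condition,
    peers: Sequence[Condition],
    min_proteins: int = DEFAULT_MIN_PROTEINS,
    method: str = "pearson",
) -> float:
    """Mean pairwise correlation of one condition against its peers.

    The scalar behind each composite-map entry: the mean over ``peers`` of
    the annotation-restricted pairwise-complete Pearson r between the
    condition's and each peer's log2fc vector; cells failing
    ``min_proteins`` are skipped from the mean.
    """
    peers = [p for p in peers if p != condition]
    if not peers:
        return float("nan")
    acm = annotation_correlation(
        fc, catalog, annotation, [condition, *peers],
        min_proteins=min_proteins, method=method,
    )
    vals = acm.r.iloc[0, 1:].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def composite_map(
    fc: pd.DataFrame,
    catalog: AnnotationCatalog,
    conditions: Sequence[Condition] | None = None,
    annotations: Sequence[str] | None = None,
    min_proteins: int = DEFAULT_MIN_PROTEINS,
    method: str = "pearson",
) -> CompositeMap:
    """Condition x annotation organelle correlation map.

    Each entry is the condition's mean annotation-restricted correlation to
    all other conditions of the same cell type.
    """
    conds = list(conditions) if conditions is not None else conditions_in(fc)
    labels = list(annotations) if annotations is not None else catalog.labels
    if len(conds) < 2 or len(labels) < 2:
        raise ValidationError("composite_map needs >= 2 conditions and annotations")
    out = pd.DataFrame(np.nan, index=_cond_index(conds), columns=labels)
    for label in labels:
        acm = annotation_correlation(
            fc, catalog, label, conds, min_proteins=min_proteins, method=method
        )
        if acm.empty:
            continue
        r = acm.r.to_numpy(dtype=float).copy()
        np.fill_diagonal(r, np.nan)
        col = out.columns.get_loc(label)
        for i, cond in enumerate(conds):
            same_ct = np.array([c.cell_type == cond.cell_type for c in conds])
            row = r[i, same_ct]
            row = row[~np.isnan(row)]
            if row.size:
                out.iloc[i, col] = row.mean()
    return CompositeMap(values=out)


def class_variance(
    cm: CompositeMap,
    disease_class: dict[str, str],
) -> pd.DataFrame:
    """Mean +/- sample SD of composite entries per (class, annotation, cell type)."""
    rows = []
    for annotation in cm.values.columns:
        series = cm.values[annotation]
        for cond, value in series.items():
            if cond.genotype not in disease_class:
                raise ValidationError(
                    f"genotype {cond.genotype!r} has no disease class"
                )
        frame = pd.DataFrame(
            {
                "value": series.to_numpy(dtype=float),
                "cls": [disease_class[c.genotype] for c in series.index],
                "cell_type": [c.cell_type for c in series.index],
            }
        ).dropna(subset=["value"])
        for (cls, ct), grp in frame.groupby(["cls", "cell_type"]):
            n = len(grp)
            rows.append(
                {
                    "disease_class": cls,
                    "annotation": annotation,
                    "cell_type": ct,
                    "mean": float(grp["value"].mean()),
                    "sd": float(grp["value"].std(ddof=1)) if n > 1 else 0.0,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def filter_links(
    matrices: dict[str, AnnotationCorrelationMatrix] | AnnotationCorrelationMatrix,
    neg_max: float = -0.2,
    pos_min: float = 0.7,
    origin: Sequence[Condition] | None = None,
) -> pd.DataFrame:
    """Retain correlation links with r < neg_max or r > pos_min.

    Upper-triangle scan (no self-links); ``origin`` keeps only links
    touching the named conditions. Defaults are the circos display
    thresholds (-0.2 / 0.7).
    """
    if neg_max >= pos_min:
        raise ValidationError("neg_max must be smaller than pos_min")
    if isinstance(matrices, AnnotationCorrelationMatrix):
        matrices = {matrices.annotation: matrices}
    origin_set = set(origin) if origin is not None else None
    rows = []
    for label, acm in matrices.items():
        conds = acm.conditions
        r = acm.r.to_numpy(dtype=float)
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                val = r[i, j]
                if np.isnan(val) or not (val < neg_max or val > pos_min):
                    continue
                if origin_set is not None and not (
                    conds[i] in origin_set or conds[j] in origin_set
                ):
                    continue
                rows.append(
                    {
                        "annotation": label,
                        "condition_a": conds[i],
                        "condition_b": conds[j],
                        "r": float(val),
                        "neg_max": neg_max,
                        "pos_min": pos_min,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["annotation", "condition_a", "condition_b", "r",
                 "neg_max", "pos_min"],
    )


def impact_score(
    fc: pd.DataFrame,
    catalog: AnnotationCatalog,
    group: str,
    cell_type: str,
    conditions: Sequence[Condition] | None = None,
    min_proteins: int = DEFAULT_MIN_PROTEINS,
) -> ImpactRanking:
    """Ranked impact score of each genotype over an annotation group.

    For each annotation A in the group and condition g: m_A(g) = mean over
    quantified proteins in A of |log2fc|; z-score m_A across the cell
    type's conditions; impact(g) = mean over A of z_A(g). Rank 1 = highest
    impact; ties break by genotype label.
    """
    if group in catalog.groups:
        labels = list(catalog.groups[group])
    elif group in catalog.sets:
        labels = [group]
    else:
        raise ValidationError(f"unknown annotation group {group!r}")
    conds = (
        [c for c in conditions if c.cell_type == cell_type]
        if conditions is not None
        else [c for c in conditions_in(fc) if c.cell_type == cell_type]
    )
    if len(conds) < 2:
        raise ValidationError("impact_score needs >= 2 conditions in the cell type")
    wide = pivot_log2fc(fc, conds)
    z_cols = {}
    for label in labels:
        members = catalog.restrict(label, wide.index)
        sub = wide.loc[sorted(members)].abs()
        n_quant = sub.notna().sum(axis=0)
        m = sub.mean(axis=0, skipna=True)
        m[n_quant < min_proteins] = np.nan
        if m.notna().sum() < 2:
            logger.warning(
                "impact_score: annotation %r dropped (too few proteins)",
                label,
            )
            continue
        sd = m.std(ddof=1)
        if sd <= 1e-12 * max(1.0, float(m.abs().max())):
            z_cols[label] = m * 0.0  # no variability across conditions
        else:
            z_cols[label] = (m - m.mean()) / sd
    if not z_cols:
        raise ValidationError("no usable annotation in the group")
    components = pd.DataFrame(z_cols)
    impact = components.mean(axis=1, skipna=True)
    table = pd.DataFrame(
        {
            "genotype": [c.genotype for c in impact.index],
            "cell_type": [c.cell_type for c in impact.index],
            "impact": impact.to_numpy(dtype=float),
        }
    )
    table = table.sort_values(
        ["impact", "genotype"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ImpactRanking(
        impact=table, components=components, group=group, cell_type=cell_type
    )


def hcluster_correlations(
    profiles: pd.DataFrame,
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of rows by 1 - Pearson distance.

    ``profiles`` is a rows x features matrix (e.g. conditions x annotation
    correlations); rows with fewer than 3 non-missing entries are excluded
    with a warning. Leaf order is scipy's deterministic dendrogram order.
    """
    if linkage not in ("average", "complete"):
        raise ValidationError("linkage must be 'average' or 'complete'")
    keep = profiles.notna().sum(axis=1) >= 3
    if (~keep).any():
        logger.warning(
            "hcluster_correlations: excluded rows %s (<3 non-missing entries)",
            list(profiles.index[~keep]),
        )
    prof = profiles[keep]
    if len(prof) < 2:
        raise ValidationError("need >= 2 usable rows to cluster")
    r, _ = pairwise_complete_corr(prof.to_numpy().T, min_n=2)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        raise ValidationError(
            "undefined pairwise correlation between some rows"
        )
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    labels = [str(i) for i in prof.index]
    order = [labels[i] for i in hierarchy.leaves_list(z)]
    return ClusterResult(
        labels=labels,
        linkage_matrix=z,
        leaf_order=order,
        heights=[float(h) for h in z[:, 2]],
    )
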