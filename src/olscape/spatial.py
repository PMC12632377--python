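"""Spatial proteomics: fraction ratios and the ratio-of-ratios (RoR) metric.

Neuronal projection fractions are normalized to the whole-cell fraction of
the same genotype (per-protein log2 ratio), and the KO ratio is then
normalized to the control ratio: log2 RoR = (KO projection/whole-cell) -
(Control projection/whole-cell) in log2 space. Genotype-shared compartment
composition cancels, isolating genotype-specific spatial redistribution.
Significance comes from a Student's t-test on replicate-level ratios
(replicates paired by index within genotype, the minimal choice under a
single TMT plex); annotation-level effects are ranked by delta mean,
Cohen's d, and RoR magnitude with a Wilcoxon set test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, two_sample_t
from .differential import cohens_d as _cohens_d
from .model import AbundanceMatrix, AnnotationCatalog, StudyDesign, ValidationError


@dataclass
class FractionRatioTable:
    """Per-protein log2(num fraction / den fraction) for one genotype."""

    genotype: str
    num_fraction: str
    den_fraction: str
    ratio_log2: pd.Series  # protein_id -> mean(num) - mean(den)
    replicate_ratios: pd.DataFrame  # protein_id x replicate (paired by index)


def fraction_log_ratio(
    m: AbundanceMatrix,
    design: StudyDesign,
    genotype: str,
    num_fraction: str = "projection",
    den_fraction: str = "whole_cell",
    cell_type: str | None = None,
) -> FractionRatioTable:
    """log2 ratio of two fractions within one genotype.

    ratio_log2 = mean over num replicates - mean over den replicates per
    protein; replicate-level ratios pair replicate i of the numerator with
    replicate i of the denominator.
    """
    if m.scale != "log2":
        raise ValidationError("fraction_log_ratio requires a log2 matrix")

    def _cols(fraction: str) -> list[str]:
        ids = design.select(
            genotype=genotype, fraction=fraction, cell_type=cell_type
        )
        if len(ids) < 2:
            raise ValidationError(
                f"genotype {genotype!r} needs >= 2 replicates in {fraction!r}"
            )
        reps = {
            s.replicate: s.sample_id
            for s in design.samples
            if s.sample_id in ids
        }
        return [reps[r] for r in sorted(reps)]

    num_cols = _cols(num_fraction)
    den_cols = _cols(den_fraction)
    num = m.data[num_cols]
    den = m.data[den_cols]
    ratio = num.mean(axis=1, skipna=True) - den.mean(axis=1, skipna=True)
    k = min(len(num_cols), len(den_cols))
    rep = pd.DataFrame(
        num.iloc[:, :k].to_numpy() - den.iloc[:, :k].to_numpy(),
        index=m.data.index,
        columns=[f"r{i + 1}" for i in range(k)],
    )
    return FractionRatioTable(
        genotype=genotype,
        num_fraction=num_fraction,
        den_fraction=den_fraction,
        ratio_log2=ratio,
        replicate_ratios=rep,
    )


def ratio_of_ratios(
    ko: FractionRatioTable,
    ctrl: FractionRatioTable,
    q_max: float = 0.05,
    min_abs: float = 0.0,
) -> pd.DataFrame:
    """log2 RoR = KO ratio - control ratio, with t-test classification.

    Columns: log2_ror, p, q, class (up / down / ns). p is a Student's t on
    the two genotypes' replicate-level ratios; class is up/down when
    q <= q_max and |log2_ror| >= min_abs, with the sign of log2_ror.
    """
    shared = ko.ratio_log2.index.intersection(ctrl.ratio_log2.index)
    if shared.empty:
        raise ValidationError("no shared proteins between the two genotypes")
    log2_ror = ko.ratio_log2.loc[shared] - ctrl.ratio_log2.loc[shared]
    _, p, _, _ = two_sample_t(
        ko.replicate_ratios.loc[shared].to_numpy(),
        ctrl.replicate_ratios.loc[shared].to_numpy(),
        kind="student",
    )
    out = pd.DataFrame(
        {"log2_ror": log2_ror.to_numpy(), "p": p}, index=shared
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    sig = (out["q"] <= q_max) & (out["log2_ror"].abs() >= min_abs)
    out["class"] = np.where(
        sig & (out["log2_ror"] > 0), "up",
        np.where(sig & (out["log2_ror"] < 0), "down", "ns"),
    )
    out.index.name = "protein_id"
    return out


def annotation_effect_ranking(
    ror: pd.DataFrame,
    catalog: AnnotationCatalog,
    min_proteins: int = 10,
) -> pd.DataFrame:
    """Rank annotations by delta mean, Cohen's d, and RoR magnitude.

    Per annotation A (vs the complement of quantified proteins):
    delta_mean = mean log2_ror(A) - mean log2_ror(complement); cohens_d is
    the standardized version; mean_abs_ror = mean |log2_ror| over A. The
    final rank is the ascending mean of the three per-metric descending
    magnitude ranks (ties by label), and each set also gets a two-sided
    Wilcoxon rank-sum p (A vs complement) with BH across annotations.
    """
    vals = ror["log2_ror"].dropna()
    rows = []
    for label, members in catalog.sets.items():
        ids = sorted(frozenset(members) & frozenset(vals.index))
        if len(ids) < min_proteins:
            continue
        inside = vals.loc[ids].to_numpy()
        outside = vals.drop(ids).to_numpy()
        if len(outside) < 2:
            continue
        eff = _cohens_d(inside, outside)
        w = stats.mannwhitneyu(
            inside, outside, alternative="two-sided", method="asymptotic"
        )
        rows.append(
            {
                "annotation": label,
                "n": len(ids),
                "delta_mean": eff.delta_mean,
                "cohens_d": eff.cohens_d,
                "mean_abs_ror": float(np.abs(inside).mean()),
                "wilcoxon_p": float(w.pvalue),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["annotation", "n", "delta_mean", "cohens_d",
                 "mean_abs_ror", "wilcoxon_p"],
    ).set_index("annotation")
    if out.empty:
        out["wilcoxon_q"] = []
        out["rank"] = []
        return out
    out["wilcoxon_q"] = bh_adjust(out["wilcoxon_p"].to_numpy())
    metric_ranks = pd.DataFrame(
        {
            "delta": out["delta_mean"].abs().rank(ascending=False),
            "d": out["cohens_d"].abs().rank(ascending=False),
            "ror": out["mean_abs_ror"].rank(ascending=False),
        }
    )
    out["mean_rank"] = metric_ranks.mean(axis=1)
    order = out.reset_index().sort_values(
        ["mean_rank", "annotation"], kind="mergesort"
    )
    rank = pd.Series(
        np.arange(1, len(order) + 1), index=order["annotation"]
    )
    out["rank"] = rank.reindex(out.index).astype(int)
    return out
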