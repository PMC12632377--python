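"""Normalization and QC transforms on abundance matrices.

Protein intensities are log2 transformed, per-sample median centered (the
single supported normalization), and optionally row-z scaled for heatmap
style summaries. QC reports per-group protein counts and the median relative
standard deviation (RSD) across replicates, computed on linear intensities.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .model import AbundanceMatrix, QCReport, StudyDesign, ValidationError

logger = logging.getLogger(__name__)


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """log2 each present value; requires a raw-intensity matrix."""
    if m.scale != "raw_intensity":
        raise ValidationError("log2_transform requires scale='raw_intensity'")
    # positivity is enforced by the AbundanceMatrix invariant
    return AbundanceMatrix(data=np.log2(m.data), scale="log2")


def normalize_median(m: AbundanceMatrix) -> AbundanceMatrix:
    """Subtract each sample column's median of present values (log2 scale)."""
    if m.scale != "log2":
        raise ValidationError("normalize_median requires scale='log2'")
    empty = m.data.notna().sum(axis=0) == 0
    if empty.any():
        raise ValidationError(
            f"sample(s) with no present values: {list(m.data.columns[empty])}"
        )
    centered = m.data - m.data.median(axis=0, skipna=True)
    return AbundanceMatrix(data=centered, scale="log2")


def row_z(m: AbundanceMatrix) -> AbundanceMatrix:
    """Center each row to mean 0 and scale to sample sd 1.

    Zero-variance rows map to all-zeros; rows with fewer than two present
    values are emitted all-missing with a warning.
    """
    if m.scale != "log2":
        raise ValidationError("row_z requires scale='log2'")
    vals = m.data.to_numpy(copy=True)
    n = np.sum(~np.isnan(vals), axis=1)
    thin = n < 2
    if thin.any():
        logger.warning(
            "row_z: %d row(s) with < 2 present values emitted as missing",
            int(thin.sum()),
        )
        vals[thin, :] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(thin[:, None], np.nan, vals), axis=1)
        sd = np.nanstd(vals, axis=1, ddof=1)
    mean = np.where(thin, np.nan, mean)
    out = vals - mean[:, None]
    scale = np.where(sd > 0, sd, 1.0)
    out = out / scale[:, None]
    out[(sd == 0) & ~thin, :] = np.where(
        np.isnan(vals[(sd == 0) & ~thin, :]), np.nan, 0.0
    )
    return AbundanceMatrix(
        data=pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        scale="log2",
    )


def qc_metrics(m: AbundanceMatrix, design: StudyDesign) -> QCReport:
    """Protein counts and median % RSD per (genotype, cell_type).

    RSD = 100 * sd / mean over replicates, on linear intensities, over
    proteins quantified in every replicate of the group. Groups with one
    replicate get a missing median RSD.
    """
    if m.scale != "raw_intensity":
        raise ValidationError("qc_metrics expects raw intensities for RSD")
    m.check_against(design)
    groups: dict[tuple[str, str], list[str]] = {}
    for s in design.samples:
        if s.sample_id in m.data.columns:
            groups.setdefault((s.genotype, s.cell_type), []).append(s.sample_id)
    rows = []
    for (genotype, cell_type), cols in groups.items():
        sub = m.data[cols].to_numpy()
        present = ~np.isnan(sub)
        protein_count = int((present.any(axis=1)).sum())
        if len(cols) < 2:
            median_rsd = np.nan
        else:
            full = present.all(axis=1)
            if full.any():
                x = sub[full]
                rsd = 100.0 * x.std(axis=1, ddof=1) / x.mean(axis=1)
                median_rsd = float(np.median(rsd))
            else:
                median_rsd = np.nan
        rows.append(
            {
                "genotype": genotype,
                "cell_type": cell_type,
                "protein_count": protein_count,
                "median_rsd": median_rsd,
            }
        )
    return QCReport(
        per_group=pd.DataFrame(rows),
        per_sample=m.n_present(),
    )
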