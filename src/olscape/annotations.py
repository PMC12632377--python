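"""Set-level utilities: threshold membership, Euler overlaps, minimal ORA.

These back the overlap (Euler) analyses of threshold-defined protein sets
(e.g. proteins with log2FC > -0.75 across mutants) and provide a minimal
hypergeometric over-representation test against the catalog.
"""

from __future__ import annotations

from itertools import product

import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .model import AnnotationCatalog, ValidationError

MAX_OVERLAP_SETS = 6


def threshold_membership(
    fc: pd.DataFrame,
    genotype: str,
    cell_type: str,
    rule: tuple[str, float],
    fraction: str | None = None,
) -> frozenset[str]:
    """Proteins whose log2fc in one contrast passes a strict threshold.

    ``rule`` is ("greater", cutoff) or ("less", cutoff); the boundary is
    excluded (strict inequality) and missing log2fc values never qualify.
    """
    direction, cutoff = rule
    sel = (fc["genotype"] == genotype) & (fc["cell_type"] == cell_type)
    if fraction is not None:
        sel &= fc["fraction"] == fraction
    sub = fc[sel]
    if sub.empty:
        raise ValidationError(
            f"no contrast for genotype={genotype!r}, cell_type={cell_type!r}"
        )
    vals = sub[sub["log2fc"].notna()]
    if direction in ("greater", ">"):
        hit = vals[vals["log2fc"] > cutoff]
    elif direction in ("less", "<"):
        hit = vals[vals["log2fc"] < cutoff]
    else:
        raise ValidationError(f"unknown rule direction {direction!r}")
    return frozenset(hit["protein_id"])


def overlap_counts(sets: dict[str, set] | list[set]) -> pd.DataFrame:
    """Exact Venn-region counts over up to 6 sets.

    Returns one row per non-empty region, with one boolean column per input
    set (the region signature) and a ``count`` column. Region counts sum to
    the size of the union.
    """
    if isinstance(sets, dict):
        names = list(sets)
        collections = [frozenset(sets[n]) for n in names]
    else:
        names = [f"set{i + 1}" for i in range(len(sets))]
        collections = [frozenset(s) for s in sets]
    k = len(collections)
    if not 1 <= k <= MAX_OVERLAP_SETS:
        raise ValidationError(f"overlap_counts supports 1..{MAX_OVERLAP_SETS} sets")
    rows = []
    for signature in product([False, True], repeat=k):
        if not any(signature):
            continue
        region = None
        for inside, s in zip(signature, collections):
            if inside:
                region = s if region is None else region & s
        for inside, s in zip(signature, collections):
            if not inside:
                region = region - s
        if region:
            rows.append({**dict(zip(names, signature)), "count": len(region)})
    return pd.DataFrame(rows, columns=[*names, "count"])


def ora_hypergeometric(
    query: set,
    catalog: AnnotationCatalog,
    background: set,
) -> pd.DataFrame:
    """Right-tail hypergeometric over-representation of the query per set.

    Each annotation is intersected with the background first; p = P(X >=
    overlap) with population |background|, successes |set & background|,
    draws |query|; q by BH across annotations; fold = overlap / expected.
    """
    query = frozenset(query)
    background = frozenset(background)
    offenders = query - background
    if offenders:
        raise ValidationError(
            f"query proteins outside background: {sorted(offenders)[:10]}"
        )
    m = len(background)
    n_draw = len(query)
    rows = []
    for label, members in catalog.sets.items():
        in_bg = members & background
        k_succ = len(in_bg)
        overlap = len(in_bg & query)
        expected = n_draw * k_succ / m if m else 0.0
        p = float(stats.hypergeom.sf(overlap - 1, m, k_succ, n_draw))
        fold = overlap / expected if expected > 0 else float("nan")
        rows.append(
            {
                "annotation": label,
                "overlap": overlap,
                "expected": expected,
                "fold": fold,
                "p": min(1.0, p),
            }
        )
    out = pd.DataFrame(rows).set_index("annotation")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
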