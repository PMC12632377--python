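"""Readers and writers for the three plain-text formats.

* design: TSV with header ``sample_id genotype cell_type fraction replicate
  tag_status`` (extra columns preserved as opaque metadata);
* abundance: wide TSV/CSV, first column ``protein_id``, empty cell = missing;
* catalog: GMT (``label<TAB>description<TAB>member...``) with optional
  two-column TSV sidecars for annotation groups and disease classes.

All formats round-trip losslessly (UTF-8, tab separated, '.' decimal).
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Mapping

import pandas as pd

from .model import (
    AbundanceMatrix,
    AnnotationCatalog,
    SampleRecord,
    StudyDesign,
    ValidationError,
)

_DESIGN_COLUMNS = (
    "sample_id",
    "genotype",
    "cell_type",
    "fraction",
    "replicate",
    "tag_status",
)


def read_design(path: str | Path, control_genotype: str = "Control") -> StudyDesign:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"design file missing columns: {missing}")
    extra_cols = [c for c in df.columns if c not in _DESIGN_COLUMNS and c != "batch"]
    records = []
    for i, row in df.iterrows():
        try:
            rec = SampleRecord(
                sample_id=row["sample_id"],
                genotype=row["genotype"],
                cell_type=row["cell_type"],
                fraction=row["fraction"],
                replicate=int(row["replicate"]),
                tag_status=row["tag_status"],
                batch=(row["batch"] or None) if "batch" in df.columns else None,
                extra={c: row[c] for c in extra_cols},
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"design row {i}: {exc}") from exc
        records.append(rec)
    return StudyDesign(samples=tuple(records), control_genotype=control_genotype)


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_abundance(
    path: str | Path,
    scale: str = "log2",
    design: StudyDesign | None = None,
) -> AbundanceMatrix:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.index.name != "protein_id":
        raise ValidationError(
            f"first column must be 'protein_id', got {df.index.name!r}"
        )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            cell = f"protein {bad.index[0]!r}, sample {col!r}" if len(bad) else col
            raise ValidationError(f"non-numeric abundance value at {cell}")
    df.index = df.index.astype(str)
    m = AbundanceMatrix(data=df, scale=scale)
    if design is not None:
        m.check_against(design)
    return m


def write_abundance(m: AbundanceMatrix, path: str | Path) -> None:
    df = m.data.copy()
    df.index.name = "protein_id"
    # 17 significant digits keep the float round-trip exact
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_catalog(
    gmt_path: str | Path,
    groups_path: str | Path | None = None,
    classes_path: str | Path | None = None,
) -> AnnotationCatalog:
    sets: dict[str, frozenset[str]] = {}
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p for p in parts[2:]):
                raise ValidationError(
                    f"GMT line {lineno}: annotation {parts[0]!r} has no members"
                )
            label = parts[0]
            if label in sets:
                raise ValidationError(f"duplicate annotation label {label!r}")
            sets[label] = frozenset(p for p in parts[2:] if p)
    groups: dict[str, tuple[str, ...]] = {}
    if groups_path is not None:
        for g, a in _read_two_column(groups_path):
            groups.setdefault(g, ())
            groups[g] = groups[g] + (a,)
    classes: dict[str, str] = {}
    if classes_path is not None:
        classes = dict(_read_two_column(classes_path))
    return AnnotationCatalog(sets=sets, groups=groups, disease_class=classes)


def write_catalog(
    catalog: AnnotationCatalog,
    gmt_path: str | Path,
    groups_path: str | Path | None = None,
    classes_path: str | Path | None = None,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for label, members in catalog.sets.items():
            desc = (descriptions or {}).get(label, "")
            fh.write("\t".join([label, desc, *sorted(members)]) + "\n")
    if groups_path is not None:
        with open(groups_path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            for g, labels in catalog.groups.items():
                for a in labels:
                    w.writerow([g, a])
    if classes_path is not None:
        with open(classes_path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            for genotype, cls in catalog.disease_class.items():
                w.writerow([genotype, cls])


def _read_two_column(path: str | Path) -> list[tuple[str, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            a, b = line.split("\t")[:2]
            out.append((a, b))
    return out


def write_truth(truth, path: str | Path) -> None:
    """Serialize a PlantedTruth to JSON (keys flattened to strings)."""
    import json

    payload = {
        "effects": [
            {"genotype": g, "cell_type": ct, "annotation": a, "delta": d}
            for (g, ct, a), d in truth.effects.items()
        ],
        "membership": {a: sorted(m) for a, m in truth.membership.items()},
        "shift_columns": list(truth.shifts.columns),
        "shift_proteins": list(truth.shifts.index),
        "shifts": [
            [None if math.isnan(v) else v for v in row]
            for row in truth.shifts.to_numpy().tolist()
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)
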