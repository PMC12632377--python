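"""Shared data model: study designs, abundance matrices, annotation catalogs.

The pipeline starts at protein-level quantities: a wide proteins x samples
intensity table (raw or log2), a per-sample design table (genotype, cell
type, fraction, replicate, LysoIP tag status), and a catalog of possibly
overlapping subcellular/functional annotation sets. Everything downstream
(contrasts, correlation landscapes, co-enrichment, ratio-of-ratios) consumes
these three containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CELL_TYPES = ("iN", "iDA", "HeLa")
FRACTIONS = ("whole_cell", "soma", "projection", "lysoip")
TAG_STATUSES = ("tagged", "untagged", "not_applicable")
SCALES = ("raw_intensity", "log2")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class SampleRecord:
    """One mass-spec sample: which cells, which fraction, which replicate."""

    sample_id: str
    genotype: str
    cell_type: str
    fraction: str
    replicate: int
    tag_status: str = "not_applicable"
    batch: str | None = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown cell_type {self.cell_type!r}"
            )
        if self.fraction not in FRACTIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown fraction {self.fraction!r}"
            )
        if self.tag_status not in TAG_STATUSES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown tag_status {self.tag_status!r}"
            )
        if int(self.replicate) < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )
        if self.fraction != "lysoip" and self.tag_status != "not_applicable":
            raise ValidationError(
                f"sample {self.sample_id!r}: tag_status must be not_applicable "
                f"outside lysoip fractions"
            )


@dataclass(frozen=True)
class StudyDesign:
    """Ordered collection of samples plus the reference (control) genotype."""

    samples: tuple[SampleRecord, ...]
    control_genotype: str = "Control"

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
        if self.control_genotype not in {s.genotype for s in self.samples}:
            raise ValidationError(
                f"control genotype {self.control_genotype!r} absent from design"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def genotypes(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.genotype not in out:
                out.append(s.genotype)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.sample_id,
                "genotype": s.genotype,
                "cell_type": s.cell_type,
                "fraction": s.fraction,
                "replicate": s.replicate,
                "tag_status": s.tag_status,
                **({"batch": s.batch} if s.batch is not None else {}),
                **dict(s.extra),
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows)

    def select(
        self,
        genotype: str | None = None,
        cell_type: str | None = None,
        fraction: str | None = None,
        tag_status: str | None = None,
    ) -> list[str]:
        """Sample ids matching every given (non-None) field."""
        out = []
        for s in self.samples:
            if genotype is not None and s.genotype != genotype:
                continue
            if cell_type is not None and s.cell_type != cell_type:
                continue
            if fraction is not None and s.fraction != fraction:
                continue
            if tag_status is not None and s.tag_status != tag_status:
                continue
            out.append(s.sample_id)
        return out


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensity table; NaN marks a missing quantification.

    ``scale`` records whether values are linear intensities
    (``raw_intensity``, strictly positive where present) or log2.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups}")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in abundance matrix")
        self.data = self.data.astype(float)
        if self.scale == "raw_intensity":
            vals = self.data.to_numpy()
            bad = (vals <= 0) & ~np.isnan(vals)
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-positive raw intensity at protein "
                    f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
                )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def n_present(self) -> pd.Series:
        """Per-sample count of quantified proteins."""
        return self.data.notna().sum(axis=0)

    def check_against(self, design: StudyDesign) -> None:
        missing = set(self.sample_ids) - set(design.sample_ids)
        if missing:
            raise ValidationError(
                f"samples absent from design: {sorted(missing)}"
            )


@dataclass(frozen=True)
class AnnotationCatalog:
    """Label -> protein-set map with optional groups and disease classes.

    Sets may overlap and nest (e.g. OXPHOS inside mitochondria); ``groups``
    bundles annotations for group-level scores (e.g. "vesicular"), and
    ``disease_class`` maps genotypes to disease classes for class-level
    variance summaries.
    """

    sets: Mapping[str, frozenset[str]]
    groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    disease_class: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for label, members in self.sets.items():
            fs = frozenset(members)
            if not fs:
                raise ValidationError(f"annotation {label!r} has no members")
            norm[label] = fs
        object.__setattr__(self, "sets", norm)
        groups = {g: tuple(labels) for g, labels in self.groups.items()}
        for g, labels in groups.items():
            unknown = [a for a in labels if a not in norm]
            if unknown:
                raise ValidationError(
                    f"group {g!r} references unknown annotations {unknown}"
                )
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "disease_class", dict(self.disease_class))

    @property
    def labels(self) -> list[str]:
        return list(self.sets)

    def members(self, label: str) -> frozenset[str]:
        try:
            return self.sets[label]
        except KeyError:
            raise KeyError(f"unknown annotation {label!r}") from None

    def restrict(self, label: str, universe: Iterable[str]) -> frozenset[str]:
        """Members of ``label`` present in ``universe``."""
        return self.members(label) & frozenset(universe)


@dataclass(frozen=True)
class QCReport:
    """Per-group protein counts and median RSD; per-sample presence counts."""

    per_group: pd.DataFrame  # genotype, cell_type, protein_count, median_rsd
    per_sample: pd.Series  # sample_id -> n_present


def make_design(records: Sequence[SampleRecord] | Sequence[dict],
                control_genotype: str = "Control") -> StudyDesign:
    """Build a StudyDesign from records or plain dicts."""
    samples = tuple(
        r if isinstance(r, SampleRecord) else SampleRecord(**r) for r in records
    )
    return StudyDesign(samples=samples, control_genotype=control_genotype)
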