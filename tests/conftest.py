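import numpy as np
import pandas as pd
import pytest

import olscape as ol


@pytest.fixture
def tiny_design() -> ol.StudyDesign:
    records = []
    for genotype in ("Control", "KO_A"):
        for rep in (1, 2, 3):
            records.append(
                {
                    "sample_id": f"{genotype}.iN.r{rep}",
                    "genotype": genotype,
                    "cell_type": "iN",
                    "fraction": "whole_cell",
                    "replicate": rep,
                    "tag_status": "not_applicable",
                }
            )
    return ol.make_design(records)


@pytest.fixture
def tiny_matrix(tiny_design) -> ol.AbundanceMatrix:
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.normal(10, 1, size=(5, 6)),
        index=pd.Index([f"P{i}" for i in range(1, 6)], name="protein_id"),
        columns=tiny_design.sample_ids,
    )
    return ol.AbundanceMatrix(data=data, scale="log2")


@pytest.fixture
def tiny_catalog() -> ol.AnnotationCatalog:
    return ol.AnnotationCatalog(
        sets={
            "mito": frozenset({"P1", "P2", "P3"}),
            "lyso": frozenset({"P3", "P4"}),
        },
        groups={"all_organelles": ("mito", "lyso")},
        disease_class={"Control": "Control", "KO_A": "Sphingolipidoses"},
    )


def fc_from_vectors(vectors: dict, proteins=None) -> pd.DataFrame:
    """Build a fold-change table from {(genotype, cell_type): log2fc list}."""
    frames = []
    for (genotype, cell_type), values in vectors.items():
        ids = proteins or [f"P{i}" for i in range(1, len(values) + 1)]
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": ids,
                    "genotype": genotype,
                    "cell_type": cell_type,
                    "fraction": "whole_cell",
                    "log2fc": values,
                    "p": np.nan,
                    "q": np.nan,
                    "n_test": 3,
                    "n_ref": 3,
                    "neglog10p": np.nan,
                    "neglog10q": np.nan,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
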