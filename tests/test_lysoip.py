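"""LysoIP enrichment, co-enrichment thresholds, and organelle shift tests."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import olscape as ol
from olscape._stats import ranksum_test
from olscape.model import ValidationError
from oracles_util import wilcoxon_exact_oracle


def _lysoip_cfg(**kw):
    defaults = dict(
        n_proteins=400,
        genotypes=("Control", "ASAH1_KO"),
        cell_types=("HeLa",),
        annotations=(("lysosome", 80, None), ("ER", 100, None)),
        noise_sd=0.0, missing_rate=0.0, seed=9,
        groups={}, disease_classes={},
    )
    defaults.update(kw)
    return ol.SimConfig(**defaults)


class TestEnrichment:
    def test_noiseless_planted_recovery(self):
        m, d, cat, _ = ol.simulate_lysoip(
            _lysoip_cfg(), lyso_enrichment=3.0
        )
        e = ol.enrichment_vs_untagged(m, d, "Control")
        e = e.set_index("protein_id")
        lyso = sorted(cat.members("lysosome"))
        others = sorted(set(e.index) - set(lyso))
        assert np.allclose(e.loc[lyso, "enrich_log2fc"], 3.0, atol=1e-12)
        assert np.allclose(e.loc[others, "enrich_log2fc"], 0.0, atol=1e-12)

    def test_null_ip_and_additivity(self):
        m, d, cat, _ = ol.simulate_lysoip(
            _lysoip_cfg(), lyso_enrichment=0.0
        )
        e0 = ol.enrichment_vs_untagged(m, d, "Control")
        assert np.allclose(e0["enrich_log2fc"], 0.0, atol=1e-12)
        # adding +1 to every tagged replicate raises enrichment by exactly 1
        tagged = d.select(genotype="Control", tag_status="tagged")
        bumped = ol.AbundanceMatrix(data=m.data.copy(), scale="log2")
        bumped.data[tagged] += 1.0
        e1 = ol.enrichment_vs_untagged(bumped, d, "Control")
        assert np.allclose(
            e1["enrich_log2fc"] - e0["enrich_log2fc"], 1.0, atol=1e-12
        )

    def test_untagged_background_required(self):
        m, d, _, _ = ol.simulate_lysoip(_lysoip_cfg())
        no_untagged = ol.make_design(
            [s for s in d.samples if s.tag_status != "untagged"]
        )
        kept = no_untagged.sample_ids
        m2 = ol.AbundanceMatrix(data=m.data[kept], scale="log2")
        with pytest.raises(ValidationError, match="untagged"):
            ol.enrichment_vs_untagged(m2, no_untagged, "Control")


class TestCoEnrichment:
    def _table(self, values):
        return pd.DataFrame(
            {
                "protein_id": list(values),
                "group": "Control",
                "enrich_log2fc": list(values.values()),
            }
        )

    def test_hand_threshold_and_flags(self):
        e = self._table({"L1": 2.0, "L2": 4.0, "A": 3.5, "B": 2.5})
        catalog = ol.AnnotationCatalog(
            sets={"lysosome": frozenset({"L1", "L2"}),
                  "other": frozenset({"A", "B"})}
        )
        res = ol.coenrichment_flags(e, catalog)
        assert res.threshold == pytest.approx(3.0)
        assert bool(res.flags["A"]) and not bool(res.flags["B"])
        assert res.counts["other"] == 1

    def test_boundary_inclusive_when_all_equal(self):
        e = self._table({"L1": 1.5, "L2": 1.5, "L3": 1.5})
        catalog = ol.AnnotationCatalog(
            sets={"lysosome": frozenset({"L1", "L2", "L3"})}
        )
        res = ol.coenrichment_flags(e, catalog)
        assert res.threshold == 1.5
        assert res.counts["lysosome"] == 3  # >= keeps the boundary

    def test_flags_match_exhaustive_recomputation(self):
        cfg = _lysoip_cfg(n_proteins=1000, noise_sd=0.25, missing_rate=0.03,
                          annotations=(("lysosome", 150, None),
                                       ("ER", 200, None),
                                       ("endosome", 120, None)))
        m, d, cat, _ = ol.simulate_lysoip(cfg, lyso_enrichment=3.0)
        e = ol.enrichment_vs_untagged(m, d, "Control")
        res = ol.coenrichment_flags(e, cat)
        # brute force, independent of the implementation's pandas path
        values = dict(zip(e["protein_id"], e["enrich_log2fc"]))
        lyso_vals = [
            v for p, v in values.items()
            if p in cat.members("lysosome") and not np.isnan(v)
        ]
        t = sum(lyso_vals) / len(lyso_vals)
        assert abs(res.threshold - t) < 1e-12
        for p, v in values.items():
            if not np.isnan(v):
                assert bool(res.flags[p]) == (v >= t)
        for label in cat.labels:
            want = sum(
                1 for p in cat.members(label)
                if p in values and not np.isnan(values[p]) and values[p] >= t
            )
            assert res.counts[label] == want

    def test_monotone_in_enrichment(self):
        e = self._table({"L1": 0.0, "L2": 2.0, "A": 0.9})
        catalog = ol.AnnotationCatalog(
            sets={"lysosome": frozenset({"L1", "L2"}),
                  "other": frozenset({"A"})}
        )
        before = ol.coenrichment_flags(e, catalog).counts["other"]
        e2 = e.copy()
        e2.loc[e2["protein_id"] == "A", "enrich_log2fc"] = 1.5
        after = ol.coenrichment_flags(e2, catalog).counts["other"]
        assert after >= before

    def test_no_quantified_lysosome_rejected(self):
        e = self._table({"A": 1.0})
        catalog = ol.AnnotationCatalog(
            sets={"lysosome": frozenset({"L_unseen"}),
                  "other": frozenset({"A"})}
        )
        with pytest.raises(ValidationError):
            ol.coenrichment_flags(e, catalog)


class TestRankSum:
    def test_separated_triplets_exact_p(self):
        _, p = ranksum_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 arrangements

    def test_all_tied_gives_p_one(self):
        _, p = ranksum_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_exact_matches_enumeration_oracle_all_small_sizes(self):
        rng = np.random.default_rng(13)
        for nx in range(2, 6):
            for ny in range(2, 6):
                if nx + ny > 10:
                    continue
                for _ in range(3):
                    x = rng.integers(0, 6, size=nx).astype(float)
                    y = rng.integers(0, 6, size=ny).astype(float)
                    _, p = ranksum_test(x, y, exact_max_n=12)
                    want = wilcoxon_exact_oracle(list(x), list(y))
                    assert abs(Fraction(p).limit_denominator(10**9) - want) \
                        < Fraction(1, 10**9)

    def test_shift_monotone_one_sided_evidence(self):
        x = [1.0, 2.0, 3.0]
        y = [2.5, 3.5, 4.5]
        _, p_base = ranksum_test(x, y)
        _, p_shift = ranksum_test(x, [v + 2 for v in y])
        assert p_shift <= p_base + 1e-12


class TestShiftTest:
    def test_planted_er_shift_flagged(self):
        cfg = _lysoip_cfg(n_proteins=1000, noise_sd=0.25,
                          annotations=(("lysosome", 150, None),
                                       ("ER", 200, None)))
        m, d, cat, _ = ol.simulate_lysoip(
            cfg, lyso_enrichment=3.0, ko_organelle_shifts=(("ER", 1.0),)
        )
        ec = ol.enrichment_vs_untagged(m, d, "Control")
        ek = ol.enrichment_vs_untagged(m, d, "ASAH1_KO")
        res = ol.organelle_shift_test(ec, ek, cat)
        assert res.loc["ER", "q"] < 0.05

    def test_small_annotation_skipped(self):
        e = pd.DataFrame(
            {"protein_id": ["A", "B"], "group": "g",
             "enrich_log2fc": [1.0, 2.0]}
        )
        catalog = ol.AnnotationCatalog(sets={"tiny": frozenset({"A", "B"})})
        res = ol.organelle_shift_test(e, e, catalog, min_members=3)
        assert res.empty


def test_per_organelle_significance_set_idempotence():
    fc = pd.DataFrame(
        {
            "protein_id": [f"P{i}" for i in range(8)],
            "enrich_log2fc": [1.0, -1.0, 0.5, -0.5, 2.0, -2.0, 0.1, -0.1],
            "q": [0.01, 0.01, 0.2, 0.01, 0.04, 0.04, 0.01, 0.5],
        }
    )
    members = frozenset({"P0", "P1", "P4", "P5"})
    single = ol.AnnotationCatalog(sets={"ER": members})
    doubled = ol.AnnotationCatalog(sets={"ER": frozenset(members | members)})
    a = ol.per_organelle_significance(fc, single, q_max=0.05,
                                      min_abs_log2fc=0.5)
    b = ol.per_organelle_significance(fc, doubled, q_max=0.05,
                                      min_abs_log2fc=0.5)
    # brute force: up {P0, P4}, down {P1, P5}
    assert a.loc["ER", "up"] == 2 and a.loc["ER", "down"] == 2
    pd.testing.assert_frame_equal(a, b)
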