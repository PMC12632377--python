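"""Correlation landscape: annotation correlations, composite map, links,
impact ranking, disease-class summaries, hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest

import olscape as ol
from olscape.landscape import Condition
from olscape.model import ValidationError
from conftest import fc_from_vectors
from oracles_util import pairwise_r_oracle, pearson_oracle


def _catalog(n, label="mito"):
    return ol.AnnotationCatalog(
        sets={label: frozenset({f"P{i}" for i in range(1, n + 1)})}
    )


class TestAnnotationCorrelation:
    def test_self_and_anticorrelation(self):
        x = [1.0, 2.0, 3.0, 4.0, 2.5, 0.5, 3.5, 1.5, 2.2, 0.9]
        fc = fc_from_vectors(
            {("KO_A", "iN"): x, ("KO_B", "iN"): [-v for v in x]}
        )
        acm = ol.annotation_correlation(fc, _catalog(10), "mito",
                                        min_proteins=5)
        r = acm.r.to_numpy()
        assert r[0, 0] == 1.0 and r[1, 1] == 1.0
        assert r[0, 1] == pytest.approx(-1.0)

    def test_textbook_pearson_value(self):
        fc = fc_from_vectors(
            {("KO_A", "iN"): [1, 2, 3, 4], ("KO_B", "iN"): [2, 1, 4, 3]}
        )
        acm = ol.annotation_correlation(fc, _catalog(4), "mito",
                                        min_proteins=2)
        assert acm.r.iloc[0, 1] == pytest.approx(0.6)

    def test_matches_brute_force_oracle_with_missingness(self):
        rng = np.random.default_rng(31)
        k = 4
        vals = rng.normal(0, 1, size=(8, k))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        fc = fc_from_vectors(
            {(f"KO_{j}", "iN"): vals[:, j] for j in range(k)}
        )
        acm = ol.annotation_correlation(fc, _catalog(8), "mito",
                                        min_proteins=2)
        wide = ol.pivot_log2fc(fc).loc[
            [f"P{i}" for i in range(1, 9)]
        ].to_numpy()
        for i in range(k):
            for j in range(i + 1, k):
                got = acm.r.iloc[i, j]
                mask = ~np.isnan(wide[:, i]) & ~np.isnan(wide[:, j])
                if mask.sum() >= 2 and not np.isnan(got):
                    assert got == pytest.approx(
                        pairwise_r_oracle(wide, i, j), abs=1e-12
                    )

    def test_min_proteins_gate(self):
        fc = fc_from_vectors(
            {("KO_A", "iN"): [1.0, 2.0], ("KO_B", "iN"): [2.0, 1.0]}
        )
        acm = ol.annotation_correlation(fc, _catalog(2), "mito",
                                        min_proteins=10)
        assert acm.empty and acm.r.isna().all().all()


class TestOrganelleCorrelationAndComposite:
    def test_mean_of_pairwise_oracle(self):
        rng = np.random.default_rng(41)
        vals = rng.normal(0, 1, size=(12, 3))
        fc = fc_from_vectors(
            {(f"KO_{j}", "iN"): vals[:, j] for j in range(3)}
        )
        cond = Condition("KO_0", "iN")
        peers = [Condition("KO_1", "iN"), Condition("KO_2", "iN")]
        got = ol.organelle_correlation(fc, _catalog(12), "mito", cond, peers,
                                       min_proteins=2)
        want = np.mean(
            [pearson_oracle(vals[:, 0], vals[:, 1]),
             pearson_oracle(vals[:, 0], vals[:, 2])]
        )
        assert got == pytest.approx(want, abs=1e-12)
        # invariant to peer ordering
        assert got == pytest.approx(
            ol.organelle_correlation(fc, _catalog(12), "mito", cond,
                                     peers[::-1], min_proteins=2)
        )

    def test_identical_conditions_give_unit_composite(self):
        x = list(np.random.default_rng(2).normal(0, 1, 12))
        fc = fc_from_vectors({("KO_A", "iN"): x, ("KO_B", "iN"): x})
        catalog = ol.AnnotationCatalog(
            sets={
                "mito": frozenset({f"P{i}" for i in range(1, 7)}),
                "lyso": frozenset({f"P{i}" for i in range(7, 13)}),
            }
        )
        cm = ol.composite_map(fc, catalog, min_proteins=2)
        assert np.allclose(cm.values.to_numpy(), 1.0)
        assert (cm.values.to_numpy() <= 1).all()

    def test_composite_matches_brute_force_and_order_invariance(self):
        rng = np.random.default_rng(43)
        vals = rng.normal(0, 1, size=(14, 3))
        fc = fc_from_vectors(
            {(f"KO_{j}", "iN"): vals[:, j] for j in range(3)}
        )
        catalog = ol.AnnotationCatalog(
            sets={
                "a1": frozenset({f"P{i}" for i in range(1, 8)}),
                "a2": frozenset({f"P{i}" for i in range(6, 15)}),
            }
        )
        cm = ol.composite_map(fc, catalog, min_proteins=2)
        wide = ol.pivot_log2fc(fc)
        for label in ("a1", "a2"):
            members = sorted(catalog.members(label) & set(wide.index))
            sub = wide.loc[members].to_numpy()
            for i in range(3):
                peers = [j for j in range(3) if j != i]
                want = np.mean([pairwise_r_oracle(sub, i, j) for j in peers])
                got = cm.values.loc[Condition(f"KO_{i}", "iN"), label]
                assert got == pytest.approx(want, abs=1e-12)
        # permuting condition and annotation order leaves entries unchanged
        conds = [Condition(f"KO_{j}", "iN") for j in (2, 0, 1)]
        cm2 = ol.composite_map(fc, catalog, conditions=conds,
                               annotations=["a2", "a1"], min_proteins=2)
        for cond in conds:
            for label in ("a1", "a2"):
                assert cm2.values.loc[cond, label] == pytest.approx(
                    cm.values.loc[cond, label]
                )

    def test_cross_cell_type_peers_never_mix(self):
        rng = np.random.default_rng(44)
        fc = fc_from_vectors(
            {
                ("KO_A", "iN"): rng.normal(0, 1, 10),
                ("KO_B", "iN"): rng.normal(0, 1, 10),
                ("KO_A", "iDA"): rng.normal(5, 1, 10),
                ("KO_B", "iDA"): rng.normal(5, 1, 10),
            }
        )
        catalog = ol.AnnotationCatalog(
            sets={
                "mito": frozenset({f"P{i}" for i in range(1, 11)}),
                "lyso": frozenset({f"P{i}" for i in range(1, 6)}),
            }
        )
        cm = ol.composite_map(fc, catalog, min_proteins=2)
        wide = ol.pivot_log2fc(fc)
        cols = list(wide.columns)
        ia = cols.index(Condition("KO_A", "iN"))
        ib = cols.index(Condition("KO_B", "iN"))
        want = pearson_oracle(wide.iloc[:, ia], wide.iloc[:, ib])
        assert cm.values.loc[Condition("KO_A", "iN"), "mito"] == pytest.approx(
            want
        )


class TestClassVariance:
    def _composite(self, entries):
        conds = list(entries)
        values = pd.DataFrame(
            {"mito": [entries[c] for c in conds]},
            index=pd.Index(conds, dtype=object, tupleize_cols=False),
        )
        return ol.CompositeMap(values=values)

    def test_two_member_class_stats(self):
        cm = self._composite(
            {Condition("KO_A", "iN"): 0.2, Condition("KO_B", "iN"): 0.4,
             Condition("KO_C", "iN"): -0.1}
        )
        cs = ol.class_variance(
            cm, {"KO_A": "Sph", "KO_B": "Sph", "KO_C": "NCL"}
        )
        sph = cs[cs["disease_class"] == "Sph"].iloc[0]
        assert sph["mean"] == pytest.approx(0.3)
        assert sph["sd"] == pytest.approx(np.std([0.2, 0.4], ddof=1))
        ncl = cs[cs["disease_class"] == "NCL"].iloc[0]
        assert ncl["sd"] == 0.0 and ncl["n"] == 1

    def test_weighted_class_means_recombine_to_grand_mean(self):
        rng = np.random.default_rng(51)
        entries = {
            Condition(f"KO_{i}", "iN"): float(rng.normal()) for i in range(9)
        }
        classes = {f"KO_{i}": f"C{i % 3}" for i in range(9)}
        cs = ol.class_variance(self._composite(entries), classes)
        grand = np.average(cs["mean"], weights=cs["n"])
        assert grand == pytest.approx(np.mean(list(entries.values())),
                                      abs=1e-12)

    def test_missing_class_rejected(self):
        cm = self._composite({Condition("KO_A", "iN"): 0.2,
                              Condition("KO_B", "iN"): 0.1})
        with pytest.raises(ValidationError, match="KO_B"):
            ol.class_variance(cm, {"KO_A": "Sph"})


class TestFilterLinks:
    def _acm(self, r_matrix, labels=("KO_A", "KO_B", "KO_C")):
        conds = [Condition(g, "iN") for g in labels]
        idx = pd.Index(conds, dtype=object, tupleize_cols=False)
        return ol.AnnotationCorrelationMatrix(
            annotation="mito",
            conditions=conds,
            r=pd.DataFrame(np.asarray(r_matrix, float), index=idx,
                           columns=idx),
            n_pairs=pd.DataFrame(99, index=idx, columns=idx),
        )

    def test_display_thresholds_on_toy_matrix(self):
        acm = self._acm(
            [[1.0, -0.3, 0.5], [-0.3, 1.0, 0.8], [0.5, 0.8, 1.0]]
        )
        links = ol.filter_links(acm)
        assert sorted(links["r"]) == [-0.3, 0.8]

    def test_all_zero_matrix_and_no_self_links(self):
        acm = self._acm(np.eye(3))
        assert ol.filter_links(acm).empty  # diagonal never emitted

    def test_origin_filter(self):
        acm = self._acm(
            [[1.0, 0.9, 0.0], [0.9, 1.0, 0.95], [0.0, 0.95, 1.0]]
        )
        links = ol.filter_links(acm, origin=[Condition("KO_A", "iN")])
        assert len(links) == 1
        assert links["condition_a"].iloc[0] == Condition("KO_A", "iN")

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            ol.filter_links(self._acm(np.eye(3)), neg_max=0.8, pos_min=0.2)


class TestImpactScore:
    def test_dominant_condition_ranks_first(self):
        cfg = ol.SimConfig(
            n_proteins=600,
            genotypes=("Control", "KO_A", "KO_B", "KO_C"),
            cell_types=("iN",),
            annotations=(("a1", 100, None), ("a2", 100, None)),
            effects=(("KO_A", "iN", "a1", 1.0), ("KO_A", "iN", "a2", -1.0)),
            noise_sd=0.0, missing_rate=0.0, seed=3,
            groups={"g": ("a1", "a2")}, disease_classes={},
        )
        m, d, cat, _ = ol.simulate_landscape(cfg)
        fc = ol.compute_all_contrasts(m, d)
        ranking = ol.impact_score(fc, cat, "g", "iN")
        assert ranking.impact.iloc[0]["genotype"] == "KO_A"
        assert ranking.impact.iloc[0]["rank"] == 1

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(61)
        vals = rng.normal(0, 1, size=(30, 3))
        fc = fc_from_vectors(
            {(f"KO_{j}", "iN"): vals[:, j] for j in range(3)}
        )
        catalog = ol.AnnotationCatalog(
            sets={"mito": frozenset({f"P{i}" for i in range(1, 31)})},
            groups={"g": ("mito",)},
        )
        base = ol.impact_score(fc, catalog, "g", "iN")
        flipped_fc = fc.copy()
        flip = flipped_fc["genotype"] == "KO_1"
        flipped_fc.loc[flip, "log2fc"] *= -1
        flipped = ol.impact_score(flipped_fc, catalog, "g", "iN")
        pd.testing.assert_frame_equal(base.impact, flipped.impact)

    def test_degenerate_equality_breaks_ties_by_label(self):
        x = list(np.abs(np.random.default_rng(6).normal(0, 1, 20)))
        fc = fc_from_vectors(
            {("KO_B", "iN"): x, ("KO_A", "iN"): x, ("KO_C", "iN"): x}
        )
        catalog = ol.AnnotationCatalog(
            sets={"mito": frozenset({f"P{i}" for i in range(1, 21)})},
            groups={"g": ("mito",)},
        )
        ranking = ol.impact_score(fc, catalog, "g", "iN")
        assert (ranking.impact["impact"] == 0).all()
        assert ranking.impact["genotype"].tolist() == ["KO_A", "KO_B", "KO_C"]


class TestHCluster:
    def test_two_rows_single_merge(self):
        rng = np.random.default_rng(71)
        a = rng.normal(0, 1, 10)
        b = a + rng.normal(0, 0.5, 10)
        prof = pd.DataFrame([a, b], index=["x", "y"])
        res = ol.hcluster_correlations(prof)
        assert len(res.heights) == 1
        assert res.heights[0] == pytest.approx(1 - pearson_oracle(a, b))

    def test_three_rows_match_hand_agglomeration_average_linkage(self):
        rng = np.random.default_rng(72)
        base = rng.normal(0, 1, 20)
        rows = {
            "a": base + rng.normal(0, 0.1, 20),
            "b": base + rng.normal(0, 0.1, 20),
            "c": rng.normal(0, 1, 20),
        }
        prof = pd.DataFrame(rows.values(), index=list(rows))
        res = ol.hcluster_correlations(prof, linkage="average")
        d = {
            (i, j): 1 - pearson_oracle(rows[i], rows[j])
            for i in rows for j in rows if i < j
        }
        first = min(d, key=d.get)
        assert set(first) == {"a", "b"}
        assert res.heights[0] == pytest.approx(d[("a", "b")])
        # average linkage: second merge height is the mean distance to c
        expected = np.mean([d[("a", "c")], d[("b", "c")]])
        assert res.heights[1] == pytest.approx(expected)

    def test_relabeling_preserves_height_multiset(self):
        rng = np.random.default_rng(73)
        prof = pd.DataFrame(rng.normal(0, 1, size=(5, 15)),
                            index=list("abcde"))
        res1 = ol.hcluster_correlations(prof)
        perm = [3, 1, 4, 0, 2]
        res2 = ol.hcluster_correlations(prof.iloc[perm])
        assert np.allclose(sorted(res1.heights), sorted(res2.heights))

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(74)
        prof = pd.DataFrame(rng.normal(0, 1, size=(4, 12)),
                            index=["w", "x", "y", "z"])
        nwk = ol.hcluster_correlations(prof).to_newick()
        assert nwk.endswith(";")
        for leaf in ("w", "x", "y", "z"):
            assert leaf in nwk
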