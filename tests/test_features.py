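"""Per-category feature values, symmetry, and the missing->zero rule."""

import math

import numpy as np
import pandas as pd
import pytest

import funlink as fl
from funlink.features import (
    FeatureComputer,
    coexpression_features,
    colocalization_features,
    domain_features,
    interolog_feature,
    phylo_features,
    shared_annotation_features,
)
from funlink.io import OrthologData
from funlink.ontology import AnnotationCorpus


def expr_frame(rows: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene"
    return df


class TestCoexpression:
    def test_identical_vectors_give_unit_correlation(self):
        expr = expr_frame({"a": [1, 2, 3], "b": [1, 2, 3], "c": [5, 1, 2]})
        vals, missing = coexpression_features(expr, ("a", "b"))
        assert not missing
        assert vals[0] == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        expr = expr_frame({"a": [1, 2, 3], "b": [3, 2, 1], "c": [2, 0, 1]})
        vals, _ = coexpression_features(expr, ("a", "b"))
        assert vals[0] == pytest.approx(-1.0)

    def test_absent_gene_is_masked_zero(self):
        expr = expr_frame({"a": [1, 2, 3], "b": [3, 2, 1]})
        vals, missing = coexpression_features(expr, ("a", "zz"))
        assert missing and np.all(vals == 0.0)

    def test_zero_variance_is_masked(self):
        expr = expr_frame({"a": [1, 1, 1], "b": [3, 2, 1], "c": [0, 1, 0]})
        _, missing = coexpression_features(expr, ("a", "b"))
        assert missing

    def test_mutual_rank_is_best_for_top_partners(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(10)
        expr = expr_frame(
            {
                "a": base + 0.01 * rng.standard_normal(10),
                "b": base + 0.01 * rng.standard_normal(10),
                "c": rng.standard_normal(10),
                "d": rng.standard_normal(10),
            }
        )
        vals, _ = coexpression_features(expr, ("a", "b"))
        assert vals[1] == pytest.approx(1.0)  # rank 1 both ways


class TestSharedAnnotation:
    def test_jaccard_per_aspect(self, small_dag):
        c = AnnotationCorpus()
        leaves = small_dag.leaves("BP")
        # propagated sets {leaf + ancestors}: same leaf -> jaccard 1
        c.add("a", leaves[0], "BP")
        c.add("b", leaves[0], "BP")
        vals, missing = shared_annotation_features(c, small_dag, ("a", "b"))
        assert not missing
        assert vals[0] == pytest.approx(1.0)
        assert vals[1] == 0.0 and vals[2] == 0.0  # unannotated aspects

    def test_set_arithmetic_example(self, small_dag):
        # direct sets {t1,t2,t3} vs {t2,t3,t4} with a flat hierarchy give 2/4
        root = small_dag.roots()["BP"]
        kids = sorted(small_dag.children(root))
        g1 = sorted(small_dag.children(kids[0]))  # two leaves under kid0
        g2 = sorted(small_dag.children(kids[1]))
        c = AnnotationCorpus()
        for t in [kids[0], g1[0], g1[1]]:
            c.add("a", t, "BP")
        for t in [g1[0], g1[1], kids[1]]:
            c.add("b", t, "BP")
        vals, _ = shared_annotation_features(c, small_dag, ("a", "b"))
        # closures: a -> {kid0, g1a, g1b, root}; b -> {g1a, g1b, kid0, kid1, root}
        assert vals[0] == pytest.approx(4 / 5)

    def test_unannotated_gene_masked(self, small_dag):
        c = AnnotationCorpus()
        c.add("a", small_dag.leaves("BP")[0], "BP")
        vals, missing = shared_annotation_features(c, small_dag, ("a", "nobody"))
        assert missing and np.all(vals == 0.0)


class TestColocalization:
    def test_shared_singleton_with_frequency(self):
        loc = {
            "g1": {"nucleus", "cytosol"},
            "g2": {"cytosol"},
            "g3": {"er"},
            "g4": {"golgi"},
        }
        vals, missing = colocalization_features(loc, ("g1", "g2"))
        assert not missing
        # f(cytosol) = 2/4 -> specificity -log(0.5)
        assert vals == pytest.approx([1.0, 0.5, 1.0, -math.log(0.5)])

    def test_disjoint_compartments(self):
        loc = {"g1": {"nucleus"}, "g2": {"er"}}
        vals, missing = colocalization_features(loc, ("g1", "g2"))
        assert not missing and np.all(vals == 0.0)

    def test_no_compartments_masked(self):
        loc = {"g1": {"nucleus"}}
        vals, missing = colocalization_features(loc, ("g1", "g2"))
        assert missing and np.all(vals == 0.0)


class TestDomains:
    def test_no_scored_pair_gives_zeros_unmasked(self):
        vals, missing = domain_features(
            {"a": {"D1"}, "b": {"D2"}}, {("D3", "D4"): 1.0}, ("a", "b")
        )
        assert not missing and np.all(vals == 0.0)

    def test_two_scored_pairs_aggregates(self):
        domains = {"a": {"D1", "D2"}, "b": {"D3", "D4"}}
        ddi = {("D1", "D3"): 0.3, ("D2", "D4"): 0.7}
        vals, _ = domain_features(domains, ddi, ("a", "b"))
        count, fraction, mx, mean, total = vals
        assert (count, fraction, mx, mean, total) == pytest.approx(
            (2, 0.5, 0.7, 0.5, 1.0)
        )

    def test_singleton_aggregates(self):
        vals, _ = domain_features(
            {"a": {"D1"}, "b": {"D2"}}, {("D1", "D2"): 0.4}, ("a", "b")
        )
        assert vals == pytest.approx([1, 1.0, 0.4, 0.4, 0.4])

    def test_domainless_gene_masked(self):
        vals, missing = domain_features({"a": {"D1"}}, {}, ("a", "b"))
        assert missing and np.all(vals == 0.0)


class TestPhylo:
    def prof(self, rows):
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "gene"
        return df

    def test_identical_balanced_profiles(self):
        p = self.prof({"a": [1, 0, 1, 0], "b": [1, 0, 1, 0]})
        vals, missing = phylo_features(p, ("a", "b"))
        assert not missing
        assert vals[0] == pytest.approx(1.0)
        assert vals[1] == pytest.approx(1.0)

    def test_complementary_profiles(self):
        p = self.prof({"a": [1, 0, 1, 0], "b": [0, 1, 0, 1]})
        vals, _ = phylo_features(p, ("a", "b"))
        assert vals[0] == pytest.approx(-1.0)
        assert vals[1] == 0.0
        assert vals[2] == pytest.approx(math.log(2))  # deterministic 2x2 MI

    def test_constant_profile_masked(self):
        p = self.prof({"a": [1, 1, 1, 1], "b": [0, 1, 0, 1]})
        vals, missing = phylo_features(p, ("a", "b"))
        assert missing and np.all(vals == 0.0)

    def test_independent_profiles_low_mi(self):
        rng = np.random.default_rng(42)
        mis = []
        for _ in range(200):
            a = rng.integers(0, 2, 24)
            b = rng.integers(0, 2, 24)
            if a.min() == a.max() or b.min() == b.max():
                continue
            p = self.prof({"a": a, "b": b})
            mis.append(phylo_features(p, ("a", "b"))[0][2])
        assert np.mean(mis) < 0.05  # nats


class TestInterolog:
    def make(self):
        d = OrthologData()
        for sp in ("R0", "R1", "R2"):
            d.add_ortholog(sp, "a", f"{sp}|a")
            d.add_ortholog(sp, "b", f"{sp}|b")
        d.add_interaction("R0", "R0|a", "R0|b")
        d.add_interaction("R1", "R1|a", "R1|b")
        return d

    def test_counts_species(self):
        vals, missing = interolog_feature(self.make(), ("a", "b"))
        assert not missing and vals[0] == 2.0

    def test_no_shared_species(self):
        d = OrthologData()
        d.add_ortholog("R0", "a", "R0|a")
        d.add_ortholog("R1", "b", "R1|b")
        vals, missing = interolog_feature(d, ("a", "b"))
        assert not missing and vals[0] == 0.0

    def test_paralog_fanout_counts_species_once(self):
        d = OrthologData()
        d.add_ortholog("R0", "a", "R0|a1")
        d.add_ortholog("R0", "a", "R0|a2")
        d.add_ortholog("R0", "b", "R0|b1")
        d.add_ortholog("R0", "b", "R0|b2")
        d.add_interaction("R0", "R0|a1", "R0|b1")
        d.add_interaction("R0", "R0|a2", "R0|b2")
        vals, _ = interolog_feature(d, ("a", "b"))
        assert vals[0] == 1.0

    def test_orthologless_gene_masked(self):
        d = OrthologData()
        d.add_ortholog("R0", "a", "R0|a")
        vals, missing = interolog_feature(d, ("a", "b"))
        assert missing and np.all(vals == 0.0)


class TestBuildFeatureMatrix:
    def test_symmetry_in_pair_order(self, default_fixture):
        comp, truth = default_fixture
        fc = FeatureComputer(comp)
        a, b = sorted(truth.positives)[0]
        va, ma = fc.pair_features((a, b))
        vb, mb = fc.pair_features((b, a))
        assert np.array_equal(va, vb) and np.array_equal(ma, mb)

    def test_unknown_gene_raises_with_name(self, default_fixture):
        comp, _ = default_fixture
        with pytest.raises(KeyError, match="NOPE"):
            fl.build_feature_matrix(comp, [("G0000", "NOPE")])

    def test_masked_categories_are_exactly_zero(self, default_fixture):
        comp, truth = default_fixture
        fm = fl.build_feature_matrix(comp, truth.background_pairs(200, seed=5))
        cats = np.array(fm.feature_categories)
        for j, cat in enumerate(fm.category_names):
            cols = np.flatnonzero(cats == cat)
            rows = np.flatnonzero(fm.missing_mask[:, j])
            assert np.all(fm.values[np.ix_(rows, cols)] == 0.0)

    def test_planted_pairs_have_more_signal(self, default_fixture):
        comp, truth = default_fixture
        pos = sorted(truth.all_positives)[:100]
        neg = truth.background_pairs(100, seed=7)
        fm_pos = fl.build_feature_matrix(comp, pos)
        fm_neg = fl.build_feature_matrix(comp, neg)
        nz_pos = np.median((fm_pos.values != 0).sum(axis=1))
        nz_neg = np.median((fm_neg.values != 0).sum(axis=1))
        assert nz_pos > nz_neg

    def test_determinism(self, default_fixture):
        comp, truth = default_fixture
        pairs = sorted(truth.positives)[:20]
        m1 = fl.build_feature_matrix(comp, pairs)
        m2 = fl.build_feature_matrix(comp, pairs)
        assert np.array_equal(m1.values, m2.values)
        assert np.array_equal(m1.missing_mask, m2.missing_mask)

    def test_tsv_round_trip(self, default_fixture, tmp_path):
        comp, truth = default_fixture
        fm = fl.build_feature_matrix(comp, sorted(truth.positives)[:10])
        fm.write_tsv(tmp_path / "f.tsv")
        back = fl.FeatureMatrix.read_tsv(tmp_path / "f.tsv")
        assert back.pairs == fm.pairs
        assert np.allclose(back.values, fm.values)
        assert np.array_equal(back.missing_mask, fm.missing_mask)
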