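"""Neighbor-based function prediction evaluation harness."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

import funlink as fl
from funlink.funcpred import DEFAULT_CUTOFFS, TimeSplitCorpus
from funlink.network import Interactome
from funlink.ontology import AnnotationCorpus, OntologyDag, Term


class TestNeighborGeneSet:
    def star(self):
        return Interactome.from_edges([("hub", f"leaf{i}") for i in range(5)])

    def test_star_center_sees_all_leaves(self):
        net = self.star()
        assert fl.neighbor_gene_set(net, "hub") == {f"leaf{i}" for i in range(5)}

    def test_leaf_sees_center(self):
        assert fl.neighbor_gene_set(self.star(), "leaf0") == {"hub"}

    def test_triangle(self):
        net = Interactome.from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        assert fl.neighbor_gene_set(net, "a") == {"b", "c"}

    def test_isolated_gene_empty(self):
        net = self.star()
        net.add_node("alone")
        assert fl.neighbor_gene_set(net, "alone") == set()


class TestEnrichTerms:
    def flat_dag(self, n_terms=5):
        terms = [Term("ROOT", "root", "BP")] + [
            Term(f"T{i}", f"t{i}", "BP") for i in range(n_terms)
        ]
        return OntologyDag(terms, {f"T{i}": ["ROOT"] for i in range(n_terms)})

    def test_closed_form_minimum_p(self):
        dag = self.flat_dag()
        corpus = AnnotationCorpus()
        genes = [f"G{i}" for i in range(100)]
        for g in genes:
            corpus.add(g, "ROOT", "BP")
        for g in genes[:10]:
            corpus.add(g, "T0", "BP")
        hits = set(genes[:10])
        result = dict(fl.enrich_terms(hits, corpus, dag, aspect="BP"))
        assert result["T0"] == pytest.approx(1.0 / math.comb(100, 10), rel=1e-9)
        assert result["T0"] == pytest.approx(
            float(hypergeom.sf(9, 100, 10, 10)), rel=1e-9
        )

    def test_universal_term_has_p_one(self):
        dag = self.flat_dag()
        corpus = AnnotationCorpus()
        for i in range(20):
            corpus.add(f"G{i}", "ROOT", "BP")
        result = dict(fl.enrich_terms({"G0", "G1"}, corpus, dag, aspect="BP"))
        assert result["ROOT"] == pytest.approx(1.0)

    def test_empty_set_gives_empty_list(self):
        dag = self.flat_dag()
        assert fl.enrich_terms(set(), AnnotationCorpus(), dag) == []

    def test_deterministic_ordering(self):
        dag = self.flat_dag()
        corpus = AnnotationCorpus()
        for i in range(30):
            corpus.add(f"G{i}", "ROOT", "BP")
            corpus.add(f"G{i}", f"T{i % 3}", "BP")
        out = fl.enrich_terms({"G0", "G1", "G2"}, corpus, dag, aspect="BP")
        assert out == sorted(out, key=lambda tp: (tp[1], tp[0]))


class TestDescendantMatch:
    def test_exact_and_descendant_and_sibling(self, small_dag):
        root = small_dag.roots()["BP"]
        kids = sorted(small_dag.children(root))
        leaves0 = sorted(small_dag.children(kids[0]))
        assert fl.descendant_match(kids[0], {kids[0]}, small_dag)
        assert fl.descendant_match(leaves0[0], {kids[0]}, small_dag)
        assert not fl.descendant_match(kids[1], {kids[0]}, small_dag)

    def test_unknown_term_errors(self, small_dag):
        with pytest.raises(KeyError):
            fl.descendant_match("NOPE", set(), small_dag)

    def test_agrees_with_ancestor_walk_oracle_on_random_dags(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            n = 50
            terms = [Term("N0", "root", "BP")] + [
                Term(f"N{i}", f"n{i}", "BP") for i in range(1, n)
            ]
            is_a = {
                f"N{i}": [
                    f"N{j}"
                    for j in rng.choice(i, size=min(i, 1 + rng.integers(0, 2)), replace=False)
                ]
                for i in range(1, n)
            }
            dag = OntologyDag(terms, is_a)

            def walk_up(t):  # brute-force ancestor walk
                seen = set()
                stack = [t]
                while stack:
                    cur = stack.pop()
                    for p in is_a.get(cur, []):
                        if p not in seen:
                            seen.add(p)
                            stack.append(p)
                return seen

            truth_terms = {f"N{i}" for i in rng.choice(n, size=5, replace=False)}
            for i in range(n):
                t = f"N{i}"
                expected = t in truth_terms or bool(walk_up(t) & truth_terms)
                assert fl.descendant_match(t, truth_terms, dag) == expected


def toy_split():
    """Two target genes on a 3-level ontology with known new terms."""
    terms = [
        Term("R", "root", "BP"),
        Term("A", "a", "BP"),
        Term("B", "b", "BP"),
        Term("A1", "a1", "BP"),
        Term("A2", "a2", "BP"),
        Term("B1", "b1", "BP"),
    ]
    dag = OntologyDag(terms, {"A": ["R"], "B": ["R"], "A1": ["A"], "A2": ["A"], "B1": ["B"]})
    corpus = AnnotationCorpus()
    # module genes share term A1; others carry B1
    for g in ("t1", "n1", "n2", "n3"):
        corpus.add(g, "A1", "BP")
    for g in ("t2", "m1", "m2", "m3"):
        corpus.add(g, "B1", "BP")
    for g in ("x1", "x2", "x3", "x4"):
        corpus.add(g, "A2", "BP")
    new = {("t1", "A1"), ("t2", "B1")}
    return dag, TimeSplitCorpus(corpus=corpus, new=new, aspect="BP")


class TestPrSweep:
    def test_oracle_network_recovers_new_annotations(self):
        dag, split = toy_split()
        net = Interactome.from_edges(
            [("t1", "n1"), ("t1", "n2"), ("t1", "n3"),
             ("t2", "m1"), ("t2", "m2"), ("t2", "m3")]
        )
        res = fl.pr_sweep(net, split, dag, cutoffs=(0.5, 0.05))
        strict = res.table.iloc[-1]
        assert res.n_new == 2
        # hand arithmetic at cutoff 0.05 (hypergeometric, M=12, n=3):
        # t1: A1 has 3/4 hits -> p = 4/220 ~ 0.018 (predicted), A (8
        # members, 3 hits) -> 0.25, R -> 1.0; t2: B1 and B (4 members
        # each, 3 hits) -> 0.018 both.  N = 3, X = {A1, B1} = 2, both
        # new terms recovered.
        assert strict["recall"] == 1.0
        assert strict["precision"] == pytest.approx(2 / 3)

    def test_counts_match_hand_enumeration(self):
        dag, split = toy_split()
        # t1's neighbors are the A1 module; t2 is wired to unrelated genes
        net = Interactome.from_edges(
            [("t1", "n1"), ("t1", "n2"), ("t1", "n3"),
             ("t2", "x1"), ("t2", "x2"), ("t2", "x3"), ("t2", "x4")]
        )
        res = fl.pr_sweep(net, split, dag, cutoffs=(1.0,))
        row = res.table.iloc[0]
        # at cutoff 1.0 every enriched term with >=1 hit is reported;
        # hand enumeration over propagated annotations:
        # t1 neighbors {n1,n2,n3}: terms {A1, A, R} -> N += 3, all match
        # t1's known {A1} or descendants? A1 yes, A no, R no -> X += 1
        # t2 neighbors {x1..x4}: terms {A2, A, R} -> N += 3
        # t2 known {B1}: none matches -> X += 0
        # Y: t1's new A1 predicted -> 1; t2's new B1 not predicted -> 0
        assert (row["N"], row["X"], row["Y"]) == (6, 1, 1)
        assert row["precision"] == pytest.approx(1 / 6)
        assert row["recall"] == pytest.approx(0.5)

    def test_monotone_counts_as_cutoff_tightens(self, dense_fixture):
        comp, truth = dense_fixture
        net = fl.truth_network(truth)
        split = fl.generate_time_split(comp, new_fraction=0.3, seed=5)
        res = fl.pr_sweep(net, split, comp.ontology, cutoffs=DEFAULT_CUTOFFS)
        n = res.table["N"].to_numpy()
        y = res.table["Y"].to_numpy()
        assert np.all(np.diff(n) <= 0)
        assert np.all(np.diff(y) <= 0)

    def test_fixed_recall_denominator(self, dense_fixture):
        comp, _ = dense_fixture
        split = fl.generate_time_split(comp, new_fraction=0.3, seed=5)
        net = fl.truth_network(dense_fixture[1])
        res = fl.pr_sweep(net, split, comp.ontology)
        assert np.allclose(res.table["recall"], res.table["Y"] / split.n_new)

    def test_unsorted_cutoffs_rejected(self, dense_fixture):
        comp, truth = dense_fixture
        net = fl.truth_network(truth)
        split = fl.generate_time_split(comp, new_fraction=0.3, seed=5)
        with pytest.raises(ValueError):
            fl.pr_sweep(net, split, comp.ontology, cutoffs=(0.01, 0.5))

    def test_no_evaluable_target_errors(self):
        dag, split = toy_split()
        net = Interactome()
        net.add_nodes(["t1", "t2"])
        with pytest.raises(ValueError, match="nothing to evaluate"):
            fl.pr_sweep(net, split, dag)


class TestCompareInteractomes:
    def test_identical_networks_identical_aupr(self, dense_fixture):
        comp, truth = dense_fixture
        net = fl.truth_network(truth)
        split = fl.generate_time_split(comp, new_fraction=0.3, seed=5)
        cmpres = fl.compare_interactomes({"a": net, "b": net}, split, comp.ontology)
        auprs = dict(zip(cmpres.ranking["interactome"], cmpres.ranking["aupr"]))
        assert auprs["a"] == auprs["b"]

    def test_true_network_beats_rewired(self, dense_fixture):
        comp, truth = dense_fixture
        net = fl.truth_network(truth)
        rewired = fl.rewire_network(net, seed=3)
        split = fl.generate_time_split(comp, new_fraction=0.3, seed=5)
        cmpres = fl.compare_interactomes(
            {"true": net, "rewired": rewired}, split, comp.ontology
        )
        assert cmpres.ranking.iloc[0]["interactome"] == "true"
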