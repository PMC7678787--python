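"""Gene set linkage analysis: density, rewiring null, Q1/Q2, reports."""

import warnings

import numpy as np
import pytest

import funlink as fl
from funlink.gsla import RewireWarning, rewire_network
from funlink.network import Interactome


def grid_network():
    return Interactome.from_edges(
        [("a", "c"), ("b", "d"), ("a", "b")], nodes=["a", "b", "c", "d"]
    )


class TestIntersetDensity:
    def test_complete_bipartite(self):
        net = Interactome.from_edges(
            [(a, b) for a in ("a1", "a2") for b in ("b1", "b2", "b3")]
        )
        assert fl.interset_density(net, {"a1", "a2"}, {"b1", "b2", "b3"}) == 1.0

    def test_no_cross_edges(self):
        net = Interactome.from_edges([("a1", "a2"), ("b1", "b2")])
        assert fl.interset_density(net, {"a1", "a2"}, {"b1", "b2"}) == 0.0

    def test_hand_enumeration_with_intra_edge(self):
        # edges a-c and b-d cross; a-b does not: 2 ordered occurrences
        # over |A||B| = 4 ordered cross pairs
        assert fl.interset_density(grid_network(), {"a", "b"}, {"c", "d"}) == 0.5

    def test_symmetric(self):
        net = grid_network()
        assert fl.interset_density(net, {"a", "b"}, {"c", "d"}) == fl.interset_density(
            net, {"c", "d"}, {"a", "b"}
        )

    def test_overlapping_sets_denominator(self):
        # A = {a, b}, B = {b, c}; edges a-b, b-c; ordered cross hits:
        # (a,b),(b,c) -> 2 over 2*2 - 1 = 3
        net = Interactome.from_edges([("a", "b"), ("b", "c")])
        assert fl.interset_density(net, {"a", "b"}, {"b", "c"}) == pytest.approx(2 / 3)

    def test_relabeling_invariance(self, dense_fixture):
        _, truth = dense_fixture
        net = fl.truth_network(truth)
        mapping = {g: f"X{g}" for g in net.nodes}
        relabeled = Interactome.from_edges(
            ((mapping[a], mapping[b]) for (a, b), _, _ in net.edges()),
            nodes=mapping.values(),
        )
        a, b = set(truth.modules[0]), set(truth.modules[1])
        assert fl.interset_density(net, a, b) == fl.interset_density(
            relabeled, {mapping[g] for g in a}, {mapping[g] for g in b}
        )

    def test_degenerate_identical_singletons_error(self):
        net = Interactome.from_edges([("a", "b")])
        with pytest.raises(ValueError):
            fl.interset_density(net, {"a"}, {"a"})

    def test_genes_outside_network_count_degree_zero(self):
        net = Interactome.from_edges([("a", "b")])
        assert fl.interset_density(net, {"a"}, {"b", "ghost"}) == 0.5


class TestRewireNetwork:
    def test_degree_sequence_preserved(self, dense_fixture):
        _, truth = dense_fixture
        net = fl.truth_network(truth)
        rw = rewire_network(net, seed=1)
        assert rw.degree_sequence() == net.degree_sequence()

    def test_deterministic_and_varying(self, dense_fixture):
        _, truth = dense_fixture
        net = fl.truth_network(truth)
        assert rewire_network(net, seed=1) == rewire_network(net, seed=1)
        assert rewire_network(net, seed=1) != rewire_network(net, seed=2)

    def test_path_cannot_be_rewired(self):
        net = Interactome.from_edges([("a", "b"), ("b", "c")])
        with pytest.warns(RewireWarning):
            rw = rewire_network(net, seed=0)
        assert rw.edge_pairs() == net.edge_pairs()

    def test_single_edge_warns(self):
        net = Interactome.from_edges([("a", "b")])
        with pytest.warns(RewireWarning):
            rewire_network(net, seed=0)

    def test_no_self_loops_or_multi_edges(self, dense_fixture):
        _, truth = dense_fixture
        net = fl.truth_network(truth)
        rw = rewire_network(net, seed=3)
        assert all(a != b for (a, b), _, _ in rw.edges())
        assert rw.n_edges == net.n_edges


class TestQ1:
    def test_boundary_is_strict(self):
        net = Interactome.from_edges([("a", "c")], nodes=list("abcd") + ["e" + str(i) for i in range(96)])
        # one cross edge over exactly 100 ordered cross pairs: density 0.01
        scg = {"a", "b", "x1", "x2", "x3", "x4", "x5", "x6", "x7", "x8"}
        proc = {"c", "d", "y1", "y2", "y3", "y4", "y5", "y6", "y7", "y8"}
        res = fl.q1_test(net, scg, proc, density_cutoff=0.01)
        assert res.density == pytest.approx(0.01)
        assert not res.passed

    def test_empty_network_fails(self):
        net = Interactome()
        net.add_nodes(["a", "b", "c", "d"])
        res = fl.q1_test(net, {"a", "b"}, {"c", "d"})
        assert res.density == 0.0 and not res.passed

    def test_planted_module_passes_with_random_set_p(self, dense_fixture):
        _, truth = dense_fixture
        net = fl.truth_network(truth)
        scg = set(truth.modules[0][:8])
        proc = set(truth.modules[0][8:])
        res = fl.q1_test(net, scg, proc, n_rand=99, seed=5)
        assert res.passed and res.density > 0.2
        assert res.p == pytest.approx(1 / 100)


class TestQ2:
    def test_estimator_floor(self, dense_fixture):
        _, truth = dense_fixture
        net = fl.truth_network(truth)
        p = fl.q2_test(
            net, set(truth.modules[0]), set(truth.modules[0][:8]), n_perm=1999, seed=2
        )
        assert p == pytest.approx(1 / 2000)

    def test_unrewirable_network_returns_one(self):
        net = Interactome.from_edges([("a", "b")], nodes=["c", "d"])
        with pytest.warns(RewireWarning):
            p = fl.q2_test(net, {"a", "c"}, {"b", "d"}, n_perm=99, seed=0)
        assert p == 1.0

    def test_p_at_least_add_one_floor(self, dense_fixture):
        _, truth = dense_fixture
        net = fl.truth_network(truth)
        rng = np.random.default_rng(7)
        genes = net.nodes
        scg = set(rng.choice(genes, 20, replace=False))
        proc = set(rng.choice(genes, 20, replace=False))
        p = fl.q2_test(net, scg, proc, n_perm=199, seed=3)
        assert p >= 1 / 200


@pytest.fixture(scope="module")
def gsla_setup(dense_fixture):
    comp, truth = dense_fixture
    net = fl.truth_network(truth)
    lib = fl.ProcessLibrary.from_annotations(
        comp.annotations, comp.ontology, genes=net.nodes,
        aspect="BP", min_size=5, max_size=60,
    )
    return comp, truth, net, lib


class TestProcessLibrary:
    def test_size_bounds_respected(self, gsla_setup):
        comp, truth, net, lib = gsla_setup
        sizes = [len(lib.genes_of(p)) for p in lib]
        assert sizes and all(5 <= s <= 60 for s in sizes)

    def test_members_within_namespace(self, gsla_setup):
        comp, truth, net, lib = gsla_setup
        nodes = set(net.nodes)
        for p in lib:
            assert lib.genes_of(p) <= nodes


class TestGslaRun:
    def test_planted_link_reported(self, gsla_setup):
        comp, truth, net, lib = gsla_setup
        term = truth.module_terms[0]["BP"]
        scg = fl.generate_scg(truth, set(truth.modules[0]), n=12,
                              contamination=0.2, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = fl.gsla_run(net, scg, lib, n_perm=1999, seed=7)
        assert term in set(res.reported["process_id"])
        row = res.reported.set_index("process_id").loc[term]
        assert row["density"] > 0.01 and row["q2_p"] < 0.001

    def test_reported_rows_satisfy_both_cutoffs(self, gsla_setup):
        comp, truth, net, lib = gsla_setup
        scg = fl.generate_scg(truth, set(truth.modules[1]), n=12, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = fl.gsla_run(net, scg, lib, n_perm=1999, seed=9)
        assert (res.reported["density"] > 0.01).all()
        assert (res.reported["q2_p"] < 0.001).all()
        assert list(res.reported["q2_p"]) == sorted(res.reported["q2_p"])

    def test_isolated_scg_reports_nothing(self, gsla_setup):
        comp, truth, net, lib = gsla_setup
        isolated = [g for g in net.nodes if net.degree(g) == 0][:10]
        assert isolated, "fixture should contain degree-0 genes"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = fl.gsla_run(net, isolated, lib, n_perm=199, seed=1)
        assert res.reported.empty

    def test_byte_identical_report(self, gsla_setup):
        comp, truth, net, lib = gsla_setup
        scg = fl.generate_scg(truth, set(truth.modules[2]), n=12, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            r1 = fl.gsla_run(net, scg, lib, n_perm=499, seed=4)
            r2 = fl.gsla_run(net, scg, lib, n_perm=499, seed=4)
        assert r1.to_report_text() == r2.to_report_text()

    def test_report_layout(self, gsla_setup, tmp_path):
        comp, truth, net, lib = gsla_setup
        scg = fl.generate_scg(truth, set(truth.modules[0]), n=12, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = fl.gsla_run(net, scg, lib, n_perm=1999, seed=4)
        res.write_report(tmp_path / "report.tsv")
        lines = (tmp_path / "report.tsv").read_text().splitlines()
        header = [ln for ln in lines if ln.startswith("#")]
        assert len(header) >= 10
        assert any(ln.startswith("process_id\t") for ln in lines)

    def test_connecting_edges_are_real_cross_edges(self, gsla_setup):
        comp, truth, net, lib = gsla_setup
        scg = fl.generate_scg(truth, set(truth.modules[0]), n=12,
                              contamination=0.2, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = fl.gsla_run(net, scg, lib, n_perm=1999, seed=4)
        for pid, edges in res.connecting_edges.items():
            proc = set(lib.genes_of(pid))
            for a, b in edges:
                assert a in set(scg) and b in proc
                assert net.has_edge(a, b)

    def test_all_unmapped_scg_errors(self, gsla_setup):
        comp, truth, net, lib = gsla_setup
        with pytest.raises(ValueError):
            fl.gsla_run(net, ["ZZZ1", "ZZZ2"], lib, n_perm=99, seed=0)

    def test_size_guidance_warning(self, gsla_setup):
        comp, truth, net, lib = gsla_setup
        scg = fl.generate_scg(truth, set(truth.modules[0]), n=12, seed=3)
        with pytest.warns(UserWarning, match="recommended"):
            fl.gsla_run(net, scg, lib, n_perm=99, seed=0)
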