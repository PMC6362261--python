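"""Map-equation codelengths, the search, PageRank, and hierarchy summaries."""

import math

import networkx as nx
import numpy as np
import pytest

import seednet as sn
from seednet import community as cm
from seednet.reference import reference_hierarchy


def unit_graph(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for e in edges:
        if len(e) == 3:
            g.add_edge(e[0], e[1], weight=float(e[2]))
        else:
            g.add_edge(e[0], e[1], weight=1.0)
    return g


def cycle(n):
    return unit_graph([(f"n{i}", f"n{(i + 1) % n}") for i in range(n)])


def set_partitions(items):
    """All partitions of a list (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def exhaustive_best_codelength(g):
    flow = cm.visit_rates(g)
    best = math.inf
    for part in set_partitions(sorted(g.nodes)):
        assign = {v: i for i, block in enumerate(part) for v in block}
        best = min(best, cm.codelength(flow, assign))
    return best


class TestVisitRates:
    def test_cycle_uniform(self):
        flow = cm.visit_rates(cycle(4))
        np.testing.assert_allclose(flow.p, 0.25)
        assert flow.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_star_strength_proportional(self):
        g = unit_graph([("c", "a"), ("c", "b"), ("c", "d")])
        flow = cm.visit_rates(g)
        rates = dict(zip(flow.nodes, flow.p))
        assert rates["c"] == pytest.approx(0.5)
        for leaf in "abd":
            assert rates[leaf] == pytest.approx(1 / 6)

    def test_weighted_path(self):
        g = unit_graph([("A", "B", 1.0), ("B", "C", 3.0)])
        flow = cm.visit_rates(g)
        rates = dict(zip(flow.nodes, flow.p))
        assert rates["A"] == pytest.approx(1 / 8)
        assert rates["B"] == pytest.approx(4 / 8)
        assert rates["C"] == pytest.approx(3 / 8)

    def test_zero_weight_rejected(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        with pytest.raises(ValueError, match="zero total"):
            cm.visit_rates(g)


class TestCodelength:
    def test_cycle_single_module_is_node_entropy(self):
        flow = cm.visit_rates(cycle(4))
        assert cm.codelength(flow, {v: 0 for v in flow.nodes}) == pytest.approx(2.0)

    def test_cycle_singletons(self):
        # q_i = 0.25 each, H(Q) = 2; p_circ = 0.5 with internal entropy 1
        flow = cm.visit_rates(cycle(4))
        part = {v: i for i, v in enumerate(flow.nodes)}
        assert cm.codelength(flow, part) == pytest.approx(4.0)

    def test_clique_pair_partition_beats_single_module(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g})
        nx.set_edge_attributes(g, 1.0, "weight")
        flow = cm.visit_rates(g)
        split = {v: (0 if int(v[1:]) < 4 else 1) for v in flow.nodes}
        single = {v: 0 for v in flow.nodes}
        assert cm.codelength(flow, split) < cm.codelength(flow, single)

    def test_missing_node_rejected(self):
        flow = cm.visit_rates(cycle(4))
        with pytest.raises(KeyError, match="missing"):
            cm.codelength(flow, {"n0": 0})

    def test_minimized_at_planted_partition(self):
        g, truth = sn.generate_planted_graph(4, 8, 0.9, 0.02, seed=1)
        flow = cm.visit_rates(g)
        planted = cm.codelength(flow, truth)
        rng = np.random.default_rng(0)
        labels = np.array([truth[v] for v in flow.nodes])
        for _ in range(1000):
            perm = rng.permutation(labels)
            shuffled = dict(zip(flow.nodes, perm))
            assert planted <= cm.codelength(flow, shuffled) + 1e-12


class TestHierarchicalCodelength:
    def test_depth_one_reduces_to_node_entropy(self):
        g = cycle(5)
        flow = cm.visit_rates(g)
        tree = cm.ModuleTree(cm.ModuleNode(children=[cm.ModuleNode(genes=list(flow.nodes))]))
        hp = -(flow.p * np.log2(flow.p)).sum()
        assert cm.hierarchical_codelength(flow, tree) == pytest.approx(hp)

    def test_depth_two_reduces_to_flat_codelength(self):
        g, _ = sn.generate_planted_graph(3, 6, 0.9, 0.05, seed=2)
        flow = cm.visit_rates(g)
        nodes = sorted(g.nodes)
        blocks = [nodes[:6], nodes[6:12], nodes[12:]]
        tree = cm.ModuleTree(
            cm.ModuleNode(children=[cm.ModuleNode(genes=b) for b in blocks])
        )
        part = {v: i for i, b in enumerate(blocks) for v in b}
        assert cm.hierarchical_codelength(flow, tree) == pytest.approx(
            cm.codelength(flow, part), abs=1e-12
        )

    def test_nested_cliques_favor_three_levels(self):
        # two super-groups, each two 8-cliques bridged by an edge
        g = nx.Graph()
        for c in range(4):
            members = [f"c{c}_{i}" for i in range(8)]
            g.add_edges_from(
                (members[i], members[j]) for i in range(8) for j in range(i + 1, 8)
            )
        for i in range(4):  # sibling cliques share several bridges
            g.add_edge(f"c0_{i}", f"c1_{i}")
            g.add_edge(f"c2_{i}", f"c3_{i}")
        g.add_edge("c0_7", "c2_7")  # one weak link between super-groups
        nx.set_edge_attributes(g, 1.0, "weight")
        flow = cm.visit_rates(g)
        cliques = [[f"c{c}_{i}" for i in range(8)] for c in range(4)]
        three = cm.ModuleTree(
            cm.ModuleNode(
                children=[
                    cm.ModuleNode(children=[cm.ModuleNode(genes=cliques[0]), cm.ModuleNode(genes=cliques[1])]),
                    cm.ModuleNode(children=[cm.ModuleNode(genes=cliques[2]), cm.ModuleNode(genes=cliques[3])]),
                ]
            )
        )
        flat_cliques = {v: v.split("_")[0] for v in g}
        flat_pairs = {v: int(v[1]) // 2 for v in g}
        best_two = min(
            cm.codelength(flow, flat_cliques),
            cm.codelength(flow, flat_pairs),
            cm.codelength(flow, {v: 0 for v in g}),
        )
        assert cm.hierarchical_codelength(flow, three) < best_two

    def test_mismatched_tree_rejected(self):
        flow = cm.visit_rates(cycle(4))
        tree = cm.ModuleTree(cm.ModuleNode(children=[cm.ModuleNode(genes=["n0"])]))
        with pytest.raises(ValueError, match="coincide"):
            cm.hierarchical_codelength(flow, tree)


class TestDetectModules:
    def test_two_triangles_found_exactly(self):
        g = unit_graph(
            [("A", "B"), ("B", "C"), ("C", "A"), ("X", "Y"), ("Y", "Z"), ("Z", "X")]
        )
        tree = sn.detect_modules(g, n_trials=10, rng_seed=0)
        mods = {frozenset(c.member_genes()) for c in tree.root.children}
        assert mods == {frozenset("ABC"), frozenset("XYZ")}
        flow = cm.visit_rates(g)
        assert cm.codelength(flow, tree.top_assignment()) == pytest.approx(
            exhaustive_best_codelength(g)
        )

    def test_single_clique_single_module(self):
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, {i: f"k{i}" for i in g})
        nx.set_edge_attributes(g, 1.0, "weight")
        tree = sn.detect_modules(g, n_trials=10, rng_seed=1)
        assert len(tree.root.children) == 1
        assert tree.depth == 1

    @pytest.mark.parametrize(
        "name,graph",
        [
            ("path7", lambda: nx.path_graph(7)),
            ("cycle8", lambda: nx.cycle_graph(8)),
            ("barbell", lambda: nx.barbell_graph(3, 1)),
            ("star6", lambda: nx.star_graph(6)),
            ("bipartite", lambda: nx.complete_bipartite_graph(2, 3)),
            ("random8", lambda: nx.gnp_random_graph(8, 0.5, seed=3)),
        ],
    )
    def test_attains_exhaustive_optimum_on_small_graphs(self, name, graph):
        g = graph()
        if not nx.is_connected(g):
            pytest.skip("fixture must be connected")
        g = nx.relabel_nodes(g, {v: f"v{v}" for v in g})
        nx.set_edge_attributes(g, 1.0, "weight")
        tree = sn.detect_modules(g, n_trials=50, rng_seed=5)
        flow = cm.visit_rates(g)
        found = cm.codelength(flow, tree.top_assignment())
        assert found == pytest.approx(exhaustive_best_codelength(g), abs=1e-9)

    def test_planted_partition_recovery(self):
        from sklearn.metrics import normalized_mutual_info_score

        g, truth = sn.generate_planted_graph(4, 16, 0.9, 0.02, seed=0)
        tree = sn.detect_modules(g, n_trials=10, rng_seed=3)
        assign = tree.top_assignment()
        nodes = sorted(truth)
        nmi = normalized_mutual_info_score(
            [truth[v] for v in nodes], [assign[v] for v in nodes]
        )
        assert nmi >= 0.95

    def test_never_worse_than_flat_baseline(self):
        for seed in (0, 1):
            g = nx.gnp_random_graph(20, 0.2, seed=seed)
            g = nx.relabel_nodes(g, {v: f"v{v:02d}" for v in g})
            g.remove_nodes_from([v for v in g if g.degree(v) == 0])
            nx.set_edge_attributes(g, 1.0, "weight")
            tree = sn.detect_modules(g, n_trials=5, rng_seed=seed)
            flow = cm.visit_rates(g)
            flat = cm.ModuleTree(
                cm.ModuleNode(children=[cm.ModuleNode(genes=list(flow.nodes))])
            )
            assert tree.codelength_bits <= cm.hierarchical_codelength(flow, flat) + 1e-10

    def test_reported_codelength_self_consistent(self):
        g, _ = sn.generate_planted_graph(3, 10, 0.8, 0.05, seed=4)
        tree = sn.detect_modules(g, n_trials=5, rng_seed=9)
        flow = cm.visit_rates(g)
        assert tree.codelength_bits == pytest.approx(
            cm.hierarchical_codelength(flow, tree), abs=1e-12
        )

    def test_deterministic_for_fixed_seed(self):
        g, _ = sn.generate_planted_graph(4, 10, 0.8, 0.05, seed=6)
        a = sn.detect_modules(g, n_trials=5, rng_seed=2).leaf_paths()
        b = sn.detect_modules(g, n_trials=5, rng_seed=2).leaf_paths()
        assert a == b

    def test_single_node_trivial_tree(self):
        g = nx.Graph()
        g.add_node("solo")
        tree = sn.detect_modules(g)
        assert tree.genes() == ["solo"]

    def test_incremental_deltas_match_full_recomputation(self):
        # the search's running objective must agree with recomputing the
        # two-level objective from scratch on the final partition
        from seednet.community import _SubProblem

        for seed in (0, 1, 2):
            g = nx.gnp_random_graph(15, 0.3, seed=seed)
            g.remove_nodes_from([v for v in g if g.degree(v) == 0])
            g = nx.convert_node_labels_to_integers(g)
            nx.set_edge_attributes(g, 1.0, "weight")
            mapping = {v: f"v{v:02d}" for v in g}
            flow = cm.visit_rates(nx.relabel_nodes(g, mapping))
            n = len(flow.nodes)
            sub = _SubProblem(flow.neighbors, np.zeros(n), flow.p, 0.0, flow.two_w)
            rng = np.random.default_rng(seed)
            assign, g_inc = sub.optimize(rng)
            assert g_inc == pytest.approx(sub.objective(assign), abs=1e-9)


class TestPageRank:
    def test_regular_graph_uniform(self):
        pr = sn.pagerank(cycle(6))
        np.testing.assert_allclose(pr.to_numpy(), 1 / 6, atol=1e-9)

    def test_scores_sum_to_one(self):
        g, _ = sn.generate_planted_graph(3, 8, 0.8, 0.1, seed=7)
        assert sn.pagerank(g).sum() == pytest.approx(1.0, abs=1e-10)

    def test_star_closed_form(self):
        # K_{1,4}: c = 0.03 + 3.4*l, l = 0.03 + 0.2125*c, c + 4l = 1
        g = unit_graph([("c", f"l{i}") for i in range(4)])
        pr = sn.pagerank(g, d=0.85)
        c = 0.132 / 0.2775
        assert pr["c"] == pytest.approx(c, abs=1e-8)
        assert pr["l0"] == pytest.approx((1 - c) / 4, abs=1e-8)

    def test_matches_networkx(self):
        g, _ = sn.generate_planted_graph(3, 10, 0.7, 0.1, seed=8)
        ref = nx.pagerank(g, alpha=0.85, weight="weight", tol=1e-12)
        pr = sn.pagerank(g)
        for v in g:
            assert pr[v] == pytest.approx(ref[v], abs=1e-8)


class TestLabeling:
    def test_top_gene_labels_module(self):
        g = unit_graph([("HUB", x) for x in ("a", "b", "c")] + [("a", "b")])
        tree = sn.detect_modules(g, n_trials=5, rng_seed=0)
        sn.label_modules(tree, sn.pagerank(g))
        assert tree.root.children[0].label == "HUB"

    def test_tie_broken_lexicographically(self):
        import pandas as pd

        tree = cm.ModuleTree(
            cm.ModuleNode(children=[cm.ModuleNode(genes=["beta", "alpha"])])
        )
        pr = pd.Series({"alpha": 0.5, "beta": 0.5})
        sn.label_modules(tree, pr)
        assert tree.root.children[0].label == "alpha"

    def test_labels_belong_to_their_module(self):
        g, _ = sn.generate_planted_graph(4, 12, 0.9, 0.02, seed=9)
        tree = sn.detect_modules(g, n_trials=10, rng_seed=1)
        sn.label_modules(tree, sn.pagerank(g))
        for child in tree.root.children:
            assert child.label in child.member_genes()


class TestHierarchySummary:
    def test_reference_hierarchy_counts(self):
        tree = reference_hierarchy()
        summary = sn.hierarchy_summary(tree)
        assert summary["modules_per_level"][1] == 4
        assert summary["modules_per_level"][2] == 28
        assert summary["total_genes"] == 787

    def test_reference_module_sizes(self):
        summary = sn.hierarchy_summary(reference_hierarchy())
        top = summary["module_sizes"][1]
        assert top == {"CCR5": 376, "SPARC": 230, "ZFPM1": 173, "ACSL4": 8}
        sub = summary["module_sizes"][2]
        assert sub["CD2"] == 87 and sub["LDB2"] == 41 and sub["ZNF683"] == 1

    def test_single_module_tree(self):
        tree = cm.ModuleTree(
            cm.ModuleNode(children=[cm.ModuleNode(genes=list("abcde"))])
        )
        summary = sn.hierarchy_summary(tree)
        assert summary["modules_per_level"] == {1: 1}
        assert list(summary["module_sizes"][1].values()) == [5]
        assert summary["total_genes"] == 5
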