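"""Co-expression network, cohesiveness modules, hypergeometric enrichment."""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from metadriver import (
    CoexpressionModuleDetector,
    build_coexpression_network,
    detect_modules,
    enrichment_p,
    select_signatures,
)
from metadriver.modules import _cohesiveness, _overlap_score


def hypergeom_oracle(k, universe, annotated, drawn):
    """Exact upper tail P(X ≥ k) by summing point masses in rational arithmetic."""
    total = Fraction(0)
    for x in range(k, min(annotated, drawn) + 1):
        total += Fraction(
            comb(annotated, x) * comb(universe - annotated, drawn - x),
            comb(universe, drawn),
        )
    return float(total)


class TestCoexpressionNetwork:
    def test_collinear_pair_linked_noise_isolated(self, correlated_expression):
        net = build_coexpression_network(correlated_expression)
        assert net.has_edge("g1", "g2")
        assert net.degree("g3") == 0
        assert net.edges["g1", "g2"]["r"] == pytest.approx(1.0)

    def test_rmin_one_links_only_exact_collinearity(self, correlated_expression):
        net = build_coexpression_network(correlated_expression, r_min=1.0)
        assert set(map(frozenset, net.edges)) == {frozenset({"g1", "g2"})}

    def test_mutually_collinear_genes_form_clique(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 2, 20)
        expr = pd.DataFrame(
            {f"g{k}": (k + 1.0) * base for k in range(5)}
        ).T.set_axis([f"s{i}" for i in range(20)], axis=1)
        net = build_coexpression_network(expr)
        assert net.number_of_edges() == 10  # K5

    def test_zero_variance_gene_excluded(self, correlated_expression):
        expr = correlated_expression.copy()
        expr.loc["flat"] = 7.0
        net = build_coexpression_network(expr)
        assert "flat" not in net
        assert net.graph["n_dropped_genes"] == 1

    def test_too_few_samples_errors(self, correlated_expression):
        with pytest.raises(ValueError):
            build_coexpression_network(correlated_expression.iloc[:, :2])


def clique_graph(*cliques, weight=1.0):
    g = nx.Graph()
    for nodes in cliques:
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                g.add_edge(a, b, weight=weight)
    return g


class TestDetectModules:
    def test_two_disjoint_cliques_found(self):
        g = clique_graph(["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"])
        mods = detect_modules(g)
        assert sorted(sorted(m.genes) for m in mods) == [
            ["a1", "a2", "a3", "a4"],
            ["b1", "b2", "b3", "b4"],
        ]

    def test_exhaustive_cohesiveness_agrees_on_small_clique_pair(self):
        """Each returned module maximizes cohesiveness over connected supersets/subsets."""
        g = clique_graph(["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"])
        mods = detect_modules(g)
        import itertools

        best = 0.0
        nodes = sorted(g.nodes)
        for size in range(1, len(nodes) + 1):
            for sub in itertools.combinations(nodes, size):
                sub = set(sub)
                sg = g.subgraph(sub)
                if size > 1 and not nx.is_connected(sg):
                    continue
                best = max(best, _cohesiveness(g, sub, penalty=2.0))
        assert max(m.cohesiveness for m in mods) == pytest.approx(best)

    def test_single_triangle(self):
        g = clique_graph(["x", "y", "z"])
        (mod,) = detect_modules(g)
        assert mod.genes == frozenset({"x", "y", "z"})
        assert mod.density == 1.0

    def test_high_overlap_candidates_merge(self):
        shared = [f"s{i}" for i in range(9)]
        g = clique_graph(shared + ["pa"], shared + ["pb"])
        mods = detect_modules(g)
        # overlap score 81/100 ≥ 0.8 forces a single merged module
        assert len(mods) == 1
        assert {"pa", "pb"} <= set(mods[0].genes)

    def test_overlap_score_arithmetic(self):
        a = frozenset("abcde")
        b = frozenset("abcdX")
        assert _overlap_score(a, b) == pytest.approx(16 / 25)

    def test_empty_network_gives_no_modules(self):
        assert detect_modules(nx.Graph()) == []

    def test_returned_modules_meet_density_floor(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(25, 0.25, seed=3)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        for e in g.edges:
            g.edges[e]["weight"] = float(rng.uniform(0.5, 1.0))
        for mod in detect_modules(g):
            assert mod.density >= 0.5
            assert len(mod) >= 3

    def test_relabeling_equivariance(self):
        g = clique_graph(["a1", "a2", "a3", "a4"], ["b1", "b2", "b3"])
        mapping = {n: f"z_{n}" for n in g.nodes}
        mods_a = detect_modules(g)
        mods_b = detect_modules(nx.relabel_nodes(g, mapping))
        relabeled = sorted(
            sorted(mapping[x] for x in m.genes) for m in mods_a
        )
        assert sorted(sorted(m.genes) for m in mods_b) == relabeled


class TestEnrichment:
    def test_full_overlap_worked_example(self):
        universe = {f"u{i}" for i in range(50)}
        module = {f"u{i}" for i in range(5)}
        assert enrichment_p(module, module, universe) == pytest.approx(
            1 / 2_118_760, rel=1e-12
        )

    def test_zero_overlap_is_one(self):
        universe = {f"u{i}" for i in range(20)}
        module = {f"u{i}" for i in range(5)}
        annotated = {f"u{i}" for i in range(10, 15)}
        assert enrichment_p(module, annotated, universe) == pytest.approx(1.0)

    def test_module_equals_universe_is_one(self):
        universe = {f"u{i}" for i in range(10)}
        annotated = {f"u{i}" for i in range(4)}
        assert enrichment_p(universe, annotated, universe) == pytest.approx(1.0)

    def test_matches_point_mass_oracle(self):
        rng = np.random.default_rng(0)
        universe = [f"u{i}" for i in range(40)]
        for _ in range(25):
            n_ann = int(rng.integers(1, 20))
            n_mod = int(rng.integers(1, 15))
            annotated = set(rng.choice(universe, n_ann, replace=False))
            module = set(rng.choice(universe, n_mod, replace=False))
            k = len(annotated & module)
            expected = hypergeom_oracle(k, 40, n_ann, n_mod)
            assert enrichment_p(module, annotated, set(universe)) == pytest.approx(
                expected, abs=1e-12
            )

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            enrichment_p(set(), set(), set())


def module_like(genes):
    from metadriver.modules import GeneModule

    return GeneModule(frozenset(genes), cohesiveness=0.5, density=1.0)


class TestSelectSignatures:
    @pytest.fixture
    def universe(self):
        return {f"u{i}" for i in range(200)}

    def deg_frame(self, universe, deg_genes):
        idx = sorted(universe)
        return pd.DataFrame(
            {"deg": [g in deg_genes for g in idx]}, index=idx
        )

    def test_planted_module_selected_with_its_tf(self, universe):
        module_genes = {f"u{i}" for i in range(10)}
        degs = self.deg_frame(universe, module_genes)
        tfmap = {"TF1": frozenset(module_genes | {"u100", "u101"})}
        sig = select_signatures([module_like(module_genes)], degs, tfmap, universe)
        assert len(sig.modules) == 1
        assert "TF1" in sig.tfs

    def test_module_disjoint_from_degs_excluded(self, universe):
        degs = self.deg_frame(universe, {f"u{i}" for i in range(100, 110)})
        tfmap = {"TF1": frozenset({f"u{i}" for i in range(10)})}
        sig = select_signatures(
            [module_like({f"u{i}" for i in range(10)})], degs, tfmap, universe
        )
        assert sig.modules == []

    def test_deg_enriched_but_no_tf_excluded(self, universe):
        module_genes = {f"u{i}" for i in range(10)}
        degs = self.deg_frame(universe, module_genes)
        tfmap = {"TF1": frozenset({f"u{i}" for i in range(150, 162)})}
        sig = select_signatures([module_like(module_genes)], degs, tfmap, universe)
        assert sig.modules == []
        assert sig.tfs == set()


class TestDetectorEstimator:
    def test_fit_on_planted_expression(self, default_cohort, default_scenario):
        hrm = default_cohort.labels.group("HRM")
        X = default_cohort.expression[hrm].T  # samples × genes
        det = CoexpressionModuleDetector().fit(X)
        found = [set(m.genes) for m in det.modules_]
        for t in range(default_scenario.n_modules):
            planted = set(default_scenario.module_genes(t))
            # planted co-expression block recovered inside some module
            assert any(planted <= f for f in found)
        assert (det.labels_ >= -1).all()
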