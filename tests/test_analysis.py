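"""Pair/triplet censuses, subnetworks, knockout graphs, replicate aggregation."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tscevo import (
    Gene,
    Genome,
    activation_counts,
    all_canonical_triplets,
    all_raw_triplets,
    build_effective_graph,
    canonicalize_triplet,
    census_pairs,
    census_triplets,
    environment_sweep,
    evaluate,
    geometric_mean_best_fitness,
    graph_stats,
    isolated_gene_expression,
    knockout_switches,
    minimal_subnetwork_size,
    random_genome,
    random_genome_baseline,
    solve_expression,
)
from tscevo.analysis import PAIR_ORIENTATIONS, _pair_orientation

from conftest import make_pair


@pytest.fixture(autouse=True)
def _quiet(params):
    from tscevo import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


def spread_genome(n=6, spacing=20_000, sigma_basal=-0.066):
    """Genes so far apart that no pair interacts (all distances >> d_max)."""
    genes = [
        Gene(k, ["A", "B", "AB"][k % 3], k * spacing, 1000, "+" if k % 2 else "-")
        for k in range(n)
    ]
    return Genome(genes, n * spacing, sigma_basal)


class TestActivationCounts:
    def test_isolated_ab_gene_active_in_both_environments(self, params):
        g = Genome([Gene(0, "AB", 0, 1000, "+")], 67_500, params.sigma_basal)
        counts = activation_counts(g, params)
        assert counts["A"]["AB"] == 1 and counts["B"]["AB"] == 1

    def test_counts_bounded_by_genes_per_type(self, genome60, params):
        counts = activation_counts(genome60, params)
        for env in ("A", "B"):
            for t in ("A", "B", "AB"):
                assert 0 <= counts[env][t] <= 20


class TestEnvironmentSweep:
    def test_baselines_and_consistency(self, genome60, params):
        grid = [-0.01, 0.0, 0.01]
        df = environment_sweep(genome60, params, grid, n_random_baseline=2,
                               rng=np.random.default_rng(0))
        iso = df[df.series == "isolated"].sort_values("delta_sigma_env")
        assert (np.diff(iso.mean_expression) <= 0).all()
        at_zero = iso[iso.delta_sigma_env == 0.0].mean_expression.iloc[0]
        assert at_zero == pytest.approx(0.9798, abs=1e-4)
        # per-type values at the two selective shifts equal a direct evaluation
        rep = evaluate(genome60, params)
        for delta, env in ((0.01, "A"), (-0.01, "B")):
            for t in ("A", "B", "AB"):
                got = df[(df.series == t) & (df.delta_sigma_env == delta)].mean_expression.iloc[0]
                assert got == pytest.approx(rep.mean_expression[env][t], abs=1e-12)


class TestPairCensus:
    def test_taxonomy_is_nine_kinds_by_four_orientations(self, genome60, params):
        counts = census_pairs(genome60, params)["counts"]
        assert len(counts) == 36
        assert set(counts.orientation) == set(PAIR_ORIENTATIONS)
        assert len(counts.groupby(["focal_type", "target_type"])) == 9

    def test_total_oriented_pairs_is_2n(self, genome60, params):
        counts = census_pairs(genome60, params)["counts"]
        assert counts["count"].sum() == 2 * genome60.n_genes

    def test_upstream_downstream_duality(self, genome60, params):
        counts = census_pairs(genome60, params)["counts"].set_index(
            ["focal_type", "target_type", "orientation"]
        )["count"]
        for x in ("A", "B", "AB"):
            for y in ("A", "B", "AB"):
                assert counts[(x, y, "focal_upstream")] == counts[(y, x, "focal_downstream")]
                assert counts[(x, y, "convergent")] == counts[(y, x, "convergent")]

    @pytest.mark.parametrize(
        "left, right, expected_left_focal, expected_right_focal",
        [
            ("+", "-", "convergent", "convergent"),
            ("-", "+", "divergent", "divergent"),
            ("+", "+", "focal_upstream", "focal_downstream"),
            ("-", "-", "focal_downstream", "focal_upstream"),
        ],
    )
    def test_orientation_classification(self, left, right, expected_left_focal,
                                        expected_right_focal):
        assert _pair_orientation(left, right, True) == expected_left_focal
        assert _pair_orientation(left, right, False) == expected_right_focal

    def test_two_gene_toy_counts_match_manual_enumeration(self, params):
        """Brute-force oracle over the four orientation configurations of an
        A-B pair: each yields two oriented records in the expected class."""
        for left, right in (("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")):
            g = make_pair(left, right)
            counts = census_pairs(g, params)["counts"]
            nz = counts[counts["count"] > 0]
            assert nz["count"].sum() == 4  # 2 genes x 2 roles, both adjacencies
            got = {
                (r["focal_type"], r["target_type"], r["orientation"]): r["count"]
                for _, r in nz.iterrows()
            }
            if left == "+" and right == "-":
                assert got[("A", "B", "convergent")] >= 1
                assert got[("B", "A", "convergent")] >= 1

    def test_convergent_pair_contributes_positive_supercoiling(self, params):
        contrib = census_pairs(make_pair("+", "-"), params)["contributions"]
        ab = contrib[(contrib.focal_type == "A") & (contrib.target_type == "B")]
        assert (ab.positive > 0).all()
        assert (ab.negative == 0).all()

    def test_divergent_pair_contributes_negative_supercoiling(self, params):
        contrib = census_pairs(make_pair("-", "+"), params)["contributions"]
        ab = contrib[(contrib.focal_type == "A") & (contrib.target_type == "B")]
        assert (ab.negative < 0).all()
        assert (ab.positive == 0).all()


class TestTripletCensus:
    def test_raw_and_canonical_class_counts(self):
        raw = all_raw_triplets()
        canon = all_canonical_triplets()
        assert len(raw) == 216
        assert len(canon) == 108

    def test_each_canonical_class_covers_exactly_two_raw_classes(self):
        cover = {}
        for trip in all_raw_triplets():
            c = canonicalize_triplet([u[0] for u in trip], [u[1] for u in trip])
            cover.setdefault(c, set()).add(trip)
        assert all(len(v) == 2 for v in cover.values())

    def test_worked_symmetry_example(self):
        # A>, B<, AB<  reads as  AB>, B>, A<  from the other strand
        assert canonicalize_triplet(("A", "B", "AB"), ("+", "-", "-")) == (
            ("AB", "+"), ("B", "+"), ("A", "-"),
        )

    def test_canonical_central_gene_is_forward(self):
        for trip in all_canonical_triplets():
            assert trip[1][1] == "+"

    def test_frequencies_sum_to_one(self, genome60):
        df = census_triplets(genome60)
        assert df["count"].sum() == genome60.n_genes
        assert df.frequency.sum() == pytest.approx(1.0)

    def test_requires_three_genes(self, params):
        with pytest.raises(ValueError):
            census_triplets(make_pair("+", "+"))


class TestMinimalSubnetwork:
    def test_isolated_behaving_gene_needs_only_itself(self, params):
        g = spread_genome()
        for gene in g.genes:
            for env in ("A", "B"):
                assert minimal_subnetwork_size(g, params, gene.id, env) == 1

    def test_k1_equals_isolated_closed_form(self, params):
        from tscevo.analysis import _subnetwork_state

        g = spread_genome()
        expr = _subnetwork_state(g, params, 0, 1, params.environment_A)
        assert expr[0] == pytest.approx(
            isolated_gene_expression(params, params.delta_sigma_A), abs=1e-10
        )

    def test_returned_k_is_minimal(self, genome60, params):
        """Exhaustive-scan oracle: the returned k reproduces the full-genome
        state and (for k > 1) the next smaller odd size does not."""
        from tscevo.analysis import _subnetwork_state

        env = params.environment_A
        full = solve_expression(genome60, params, env)
        e_half = params.e_half
        checked = 0
        for gene in genome60.genes[:8]:
            k = minimal_subnetwork_size(genome60, params, gene.id, env, full_state=full)
            center = int(np.nonzero(genome60.gene_ids == gene.id)[0][0])
            target = full.expression[center] > e_half
            if k < genome60.n_genes:
                expr = _subnetwork_state(genome60, params, center, k, env)
                assert (expr[k // 2] > e_half) == target
            if k > 2:
                smaller = min(k - 2, genome60.n_genes - 1 if k == genome60.n_genes else k - 2)
                expr = _subnetwork_state(genome60, params, center, smaller, env)
                assert (expr[smaller // 2] > e_half) != target
                checked += 1
        assert checked >= 1

    def test_unknown_gene_rejected(self, genome60, params):
        with pytest.raises(KeyError):
            minimal_subnetwork_size(genome60, params, 999, "A")


class TestKnockouts:
    def test_non_interacting_genome_has_empty_switch_sets(self, params):
        g = spread_genome()
        for gene in g.genes:
            switches = knockout_switches(g, params, gene.id)
            assert switches["A"] == {} and switches["B"] == {}

    def test_knocked_gene_never_in_own_switch_set(self, genome60, params):
        for gene in genome60.genes[:6]:
            switches = knockout_switches(genome60, params, gene.id)
            assert gene.id not in switches["A"]
            assert gene.id not in switches["B"]

    def test_effective_graph_nodes_and_edge_definition(self, genome60, params):
        G = build_effective_graph(genome60, params)
        assert G.number_of_nodes() == genome60.n_genes
        assert not any(u == v for u, v in G.edges)
        for gene in genome60.genes[:5]:
            switches = knockout_switches(genome60, params, gene.id)
            switched = set(switches["A"]) | set(switches["B"])
            assert set(G.successors(gene.id)) == switched

    def test_non_interacting_genome_gives_edgeless_graph(self, params):
        g = spread_genome()
        G = build_effective_graph(g, params)
        stats = graph_stats(G)
        assert G.number_of_edges() == 0
        assert stats["wcc_sizes"] == [1] * g.n_genes
        assert all(v == 0 for v in stats["mean_out_degree"].values())

    def test_graph_determinism(self, genome60, params):
        g1 = build_effective_graph(genome60, params)
        g2 = build_effective_graph(genome60, params)
        assert sorted(g1.edges(data="label")) == sorted(g2.edges(data="label"))


class TestGraphStats:
    def graph_of(self, edges, n=6):
        G = nx.DiGraph()
        for k in range(n):
            G.add_node(k, gene_type=["A", "B", "AB"][k % 3])
        G.add_edges_from(edges)
        return G

    def test_complete_graph_single_wcc(self):
        n = 6
        G = self.graph_of([(i, j) for i in range(n) for j in range(n) if i != j], n)
        assert graph_stats(G)["wcc_sizes"] == [n]

    def test_handshake_identity(self):
        G = self.graph_of([(0, 1), (1, 2), (3, 1), (4, 5)])
        stats = graph_stats(G)
        out_total = sum(2 * v for v in stats["mean_out_degree"].values())  # 2 nodes/type
        in_total = sum(2 * v for v in stats["mean_in_degree"].values())
        assert out_total == in_total == stats["n_edges"]


class TestBaselineAndAggregation:
    def test_random_baseline_deterministic_and_sized(self, params):
        runs = [
            random_genome_baseline(params, 3, np.random.default_rng(5), lambda g: g.signature())
            for _ in range(2)
        ]
        assert runs[0] == runs[1]
        assert len(runs[0]) == 3

    def test_geometric_mean_identities(self):
        gens = np.arange(5)
        a = pd.DataFrame({"generation": gens, "best_fitness": np.full(5, 0.5)})
        b = pd.DataFrame({"generation": gens, "best_fitness": np.full(5, 0.125)})
        out = geometric_mean_best_fitness([a, b])
        assert out.geometric_mean.iloc[0] == pytest.approx(np.sqrt(0.5 * 0.125))
        single = geometric_mean_best_fitness([a, a, a])
        assert (single.geometric_mean == 0.5).all()
        # geometric mean never exceeds the arithmetic mean
        assert (out.geometric_mean <= (a.best_fitness + b.best_fitness) / 2 + 1e-15).all()

    def test_zero_fitness_rejected(self):
        a = pd.DataFrame({"generation": [0], "best_fitness": [0.0]})
        with pytest.raises(ValueError):
            geometric_mean_best_fitness([a])
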