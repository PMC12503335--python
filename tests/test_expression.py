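"""Interaction matrix, promoter thermodynamics, and the fixed-point solver."""

import numpy as np
import pytest

from tscevo import (
    ConvergenceWarning,
    Gene,
    Genome,
    SimulationParams,
    activation_threshold,
    build_interaction_matrix,
    eta,
    expression_from_opening,
    isolated_gene_expression,
    local_supercoiling,
    mirror_genome,
    opening_energy,
    random_genome,
    rotate_genome,
    solve_expression,
)
from tscevo.params import Environment

from conftest import isolated_oracle, make_pair


def eta_oracle(side: str, same_strand: bool) -> int:
    """Hand-enumerated twin-domain sign table: an upstream co-oriented gene
    pushes positive supercoils toward the focal promoter (+1); flipping the
    side or the strand flips the sign."""
    if side == "upstream":
        return 1 if same_strand else -1
    return -1 if same_strand else 1


class TestEta:
    @pytest.mark.parametrize("left", "+-")
    @pytest.mark.parametrize("right", "+-")
    @pytest.mark.parametrize("focal_is_left", [True, False])
    def test_exhaustive_eight_configurations(self, left, right, focal_is_left):
        from tscevo.genome import signed_offset

        g = make_pair(left, right)
        focal, other = (g.genes[0], g.genes[1]) if focal_is_left else (g.genes[1], g.genes[0])
        _, side = signed_offset(focal, other, g.total_length)
        expected = eta_oracle(side, focal.orientation == other.orientation)
        assert eta(focal, other, g) == expected

    def test_convergent_pair_mutual_positive(self):
        g = make_pair("+", "-")
        assert eta(g.genes[0], g.genes[1], g) == 1
        assert eta(g.genes[1], g.genes[0], g) == 1

    def test_divergent_pair_mutual_negative(self):
        g = make_pair("-", "+")
        assert eta(g.genes[0], g.genes[1], g) == -1
        assert eta(g.genes[1], g.genes[0], g) == -1

    def test_tandem_pair_asymmetric(self):
        g = make_pair("+", "+")
        left, right = g.genes
        assert eta(right, left, g) == 1  # upstream gene inhibits the downstream one
        assert eta(left, right, g) == -1


class TestInteractionMatrix:
    def test_adjacent_tandem_entry_value(self, params):
        g = make_pair("+", "+")
        M = build_interaction_matrix(g, params)
        # d(promoter of right gene, middle of left gene) = 1125 - 500 = 625
        assert M[1, 0] == pytest.approx(0.03 * (1 - 625 / 5000), abs=1e-15)

    def test_entries_vanish_beyond_dmax(self, params):
        g = make_pair("+", "+", spacing=6000, L=100_000)
        M = build_interaction_matrix(g, params)
        assert M[1, 0] == 0.0 and M[0, 1] == 0.0

    def test_zero_diagonal_and_bound(self, genome60, params):
        M = build_interaction_matrix(genome60, params)
        assert np.all(np.diag(M) == 0.0)
        assert np.max(np.abs(M)) <= params.c

    def test_single_gene_zero_matrix(self, params):
        g = Genome([Gene(0, "A", 0, 1000, "+")], 67_500, params.sigma_basal)
        assert build_interaction_matrix(g, params).shape == (1, 1)
        assert build_interaction_matrix(g, params)[0, 0] == 0.0


class TestPromoterThermodynamics:
    def test_sigmoid_midpoint(self, params):
        assert opening_energy(params.sigma_half, params) == pytest.approx(0.5)

    def test_opening_at_basal(self, params):
        # (sigma - sigma_half)/epsilon = -4.8 at basal supercoiling
        assert opening_energy(-0.066, params) == pytest.approx(1 / (1 + np.exp(-4.8)), rel=1e-12)

    def test_strictly_decreasing_and_saturating(self, params):
        grid = np.linspace(-0.2, 0.2, 101)
        U = opening_energy(grid, params)
        assert (np.diff(U) < 0).all()
        assert opening_energy(1e6, params) == 0.0
        assert opening_energy(-1e6, params) == 1.0

    def test_expression_range(self, params):
        assert expression_from_opening(1.0, params) == 1.0
        assert expression_from_opening(0.0, params) == pytest.approx(np.exp(-2.5), rel=1e-12)

    def test_activation_threshold(self, params):
        assert activation_threshold(params) == pytest.approx((np.exp(-2.5) + 1) / 2, rel=1e-12)
        big_m = SimulationParams(m=200.0)
        assert activation_threshold(big_m) == pytest.approx(0.5, abs=1e-12)

    def test_local_supercoiling_linearity(self, params, rng):
        M = rng.normal(scale=0.01, size=(4, 4))
        np.fill_diagonal(M, 0.0)
        e = rng.uniform(0.1, 1.0, 4)
        env = Environment(0.0)
        base = local_supercoiling(M, e, params, env)
        e2 = e.copy()
        e2[1] *= 2
        delta = local_supercoiling(M, e2, params, env) - base
        assert delta == pytest.approx(M[:, 1] * e[1], rel=1e-12)


class TestSolveExpression:
    @pytest.mark.parametrize("delta", [-0.01, 0.0, 0.01])
    def test_single_gene_matches_closed_form(self, params, delta):
        g = Genome([Gene(0, "AB", 0, 1000, "+")], 67_500, params.sigma_basal)
        state = solve_expression(g, params, delta)
        assert state.converged
        assert state.expression[0] == pytest.approx(isolated_oracle(params, delta), abs=1e-12)
        assert isolated_gene_expression(params, delta) == pytest.approx(
            isolated_oracle(params, delta), abs=1e-14
        )

    def test_divergent_above_isolated_above_convergent(self, params):
        iso = isolated_gene_expression(params, 0.0)
        div = solve_expression(make_pair("-", "+"), params, 0.0).expression
        con = solve_expression(make_pair("+", "-"), params, 0.0).expression
        assert (div > iso).all()
        assert (con < iso).all()

    def test_all_knockouts_zero_everything(self, genome60, params):
        ids = [g.id for g in genome60.genes]
        state = solve_expression(genome60, params, params.environment_A, knockouts=ids)
        assert np.all(state.expression == 0.0)
        assert state.sigma_local == pytest.approx(
            params.sigma_basal + params.delta_sigma_A, abs=1e-15
        )

    def test_unknown_knockout_id_rejected(self, genome60, params):
        with pytest.raises(KeyError):
            solve_expression(genome60, params, 0.0, knockouts=[999])

    def test_self_consistency_residual(self, params, rng):
        for _ in range(5):
            g = random_genome(20, 1000, 125, params.sigma_basal, rng)
            M = build_interaction_matrix(g, params)
            for env in params.environments():
                state = solve_expression(g, params, env)
                assert state.converged
                sigma = params.sigma_basal + env.delta_sigma_env + M @ state.expression
                U = 1 / (1 + np.exp((sigma - params.sigma_half) / params.epsilon))
                e_back = np.exp(params.m * (U - 1))
                assert np.max(np.abs(e_back - state.expression)) <= params.solver_tol

    def test_bounds_on_expression(self, genome60, params):
        state = solve_expression(genome60, params, params.environment_B)
        assert (state.expression >= params.e_min - 1e-12).all()
        assert (state.expression <= 1.0 + 1e-12).all()

    def test_rotation_invariance(self, params, rng):
        g = random_genome(10, 1000, 125, params.sigma_basal, rng)
        base = solve_expression(g, params, params.environment_A).expression
        for offset in (1, 1125, 12_345):
            rot = rotate_genome(g, offset)
            got = solve_expression(rot, params, params.environment_A)
            by_id = dict(zip(got.gene_ids, got.expression))
            assert np.max(np.abs([by_id[i] - e for i, e in zip(g.gene_ids, base)])) < 1e-12

    def test_mirror_invariance(self, params, rng):
        g = random_genome(10, 1000, 125, params.sigma_basal, rng)
        base = solve_expression(g, params, params.environment_B)
        mir = solve_expression(mirror_genome(g), params, params.environment_B)
        a = dict(zip(base.gene_ids, base.expression))
        b = dict(zip(mir.gene_ids, mir.expression))
        assert np.max(np.abs([a[i] - b[i] for i in a])) < 1e-12

    def test_isolated_response_non_increasing_in_shift(self, params):
        grid = np.linspace(-0.03, 0.03, 31)
        vals = [isolated_gene_expression(params, d) for d in grid]
        assert (np.diff(vals) <= 1e-15).all()

    def test_trajectory_recording(self, params):
        g = make_pair("-", "+")
        state = solve_expression(g, params, 0.0, record_trajectory=True)
        assert state.trajectory is not None
        assert np.all(state.trajectory[0] == params.e_half)
        assert state.converged

    def test_nonconvergence_surfaces_warning(self, genome60):
        p = SimulationParams(solver_max_iter=0)
        with pytest.warns(ConvergenceWarning):
            state = solve_expression(genome60, p, 0.0)
        assert not state.converged


class TestFixedPointUniqueness:
    def test_small_systems_reach_one_fixed_point_from_many_starts(self, params, rng):
        """For n <= 5 genes, heavily damped iteration from 100 random initial
        vectors lands on a self-consistent fixed point; starts that agree with
        the e_half solution dominate, and any disagreeing basin is reported
        in the assertion message rather than hidden."""
        g = random_genome(1, 1000, 125, params.sigma_basal, rng)  # 3 genes
        M = build_interaction_matrix(g, params)
        ref = solve_expression(g, params, 0.0).expression
        mismatches = []
        for k in range(100):
            e = rng.uniform(params.e_min, 1.0, g.n_genes)
            for _ in range(20_000):
                sigma = params.sigma_basal + M @ e
                U = 1 / (1 + np.exp((sigma - params.sigma_half) / params.epsilon))
                e_new = e + 0.2 * (np.exp(params.m * (U - 1)) - e)
                if np.max(np.abs(e_new - e)) < 1e-12:
                    break
                e = e_new
            if np.max(np.abs(e - ref)) > 1e-6:
                mismatches.append((k, e.copy()))
        assert not mismatches, f"alternative fixed points found: {mismatches[:3]}"
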