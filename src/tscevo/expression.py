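"""Equilibrium gene expression under the transcription-supercoiling coupling.

The transcription of a gene perturbs the local supercoiling level at the
promoters of its neighbors (twin-domain model: positive supercoils build up
downstream of the transcribing polymerase, negative supercoils upstream), and
the local supercoiling level in turn sets each promoter's opening free energy
and hence its transcription rate. Expression levels of an individual in an
environment are defined as the fixed point of this mutual feedback:

    sigma_i = sigma_basal + delta_sigma_env + sum_j (d sigma_i / d e_j) e_j
    U_i     = 1 / (1 + exp((sigma_i - sigma_half) / epsilon))
    e_i     = exp(m (U_i - 1))

solved by synchronous substitution from the uniform initial state e = e_half.
Knocked-out genes are pinned to a transcription rate of exactly 0 (they
generate no supercoiling), below the physical floor exp(-m).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from ._kernels import interaction_matrix_kernel, solve_ladder_kernel
from .genome import Gene, Genome, signed_offset, TIE
from .params import Environment, SimulationParams


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when the fixed-point iteration fails to converge."""


@dataclass
class ExpressionState:
    """Equilibrium state of a genome in one environment.

    Vectors are indexed in genome (begin-sorted) order; ``gene_ids`` maps
    positions back to stable gene identities. ``trajectory`` (optional) holds
    the expression vector at every iteration, first row = initial state.
    """

    expression: np.ndarray
    sigma_local: np.ndarray
    opening: np.ndarray
    converged: bool
    iterations: int
    gene_ids: np.ndarray
    knockouts: frozenset
    damping: float = 1.0
    trajectory: Optional[np.ndarray] = None

    def expression_of(self, gene_id: int) -> float:
        idx = int(np.nonzero(self.gene_ids == gene_id)[0][0])
        return float(self.expression[idx])


# -- elementary pieces -------------------------------------------------------


def eta(gene_i: Gene, gene_j: Gene, genome: Genome) -> int:
    """Sign of the supercoiling generated by gene_j's transcription at gene_i's
    promoter: +1 (positive supercoiling, inhibitory at default parameters) when
    gene_j is upstream of gene_i on the same strand or downstream on the
    opposite strand; -1 in the two other configurations; 0 on an exact
    antipodal tie."""
    distance, side = signed_offset(gene_i, gene_j, genome.total_length)
    if side == TIE:
        return 0
    same_strand = gene_i.orientation == gene_j.orientation
    upstream = side == "upstream"
    return 1 if upstream == same_strand else -1


def build_interaction_matrix(genome: Genome, params: SimulationParams) -> np.ndarray:
    """n x n matrix of coefficients d(sigma_i)/d(e_j); zero diagonal, entries
    vanish beyond ``d_max`` and are bounded by ``c`` in magnitude."""
    return interaction_matrix_kernel(
        genome.promoters,
        genome.middles,
        genome.orientations,
        float(genome.total_length),
        params.c,
        params.d_max,
    )


def local_supercoiling(
    M: np.ndarray,
    expression: np.ndarray,
    params: SimulationParams,
    env: Environment,
) -> np.ndarray:
    """Local supercoiling at each promoter: constant background plus the
    transcription-generated contribution M @ e."""
    background = params.sigma_basal + env.delta_sigma_env
    return background + M @ expression


def opening_energy(sigma, params: SimulationParams):
    """Promoter opening free energy U(sigma) = 1 / (1 + exp((sigma - sigma_half)/epsilon)).

    Strictly decreasing in sigma; arguments beyond +/-700 saturate to 0/1 to
    guard against overflow. Accepts scalars or arrays.
    """
    x = (np.asarray(sigma, dtype=float) - params.sigma_half) / params.epsilon
    out = np.where(x > 700.0, 0.0, np.where(x < -700.0, 1.0, 1.0 / (1.0 + np.exp(np.clip(x, -700.0, 700.0)))))
    return float(out) if out.ndim == 0 else out


def expression_from_opening(U, params: SimulationParams):
    """Transcription rate e = exp(m (U - 1)), in [exp(-m), 1]. Scalar or array."""
    out = np.exp(params.m * (np.asarray(U, dtype=float) - 1.0))
    return float(out) if out.ndim == 0 else out


def activation_threshold(params: SimulationParams) -> float:
    """Midpoint (exp(-m) + 1)/2; a gene is *activated* iff e > this value."""
    return params.e_half


def isolated_gene_expression(params: SimulationParams, delta_sigma_env: float) -> float:
    """Closed-form equilibrium expression of a neighbor-less gene (zero
    interaction matrix), the analytic baseline for sweeps and subnetworks."""
    sigma = params.sigma_basal + delta_sigma_env
    x = min(max((sigma - params.sigma_half) / params.epsilon, -700.0), 700.0)
    U = 1.0 / (1.0 + math.exp(x))
    return math.exp(params.m * (U - 1.0))


# -- fixed-point solver ------------------------------------------------------


def solve_from_matrix(
    M: np.ndarray,
    params: SimulationParams,
    env: Environment,
    gene_ids: np.ndarray,
    knockouts: Iterable[int] = (),
    record_trajectory: bool = False,
) -> ExpressionState:
    """Fixed-point solve given a prebuilt interaction matrix (genome order).

    The first attempt uses plain synchronous substitution at the configured
    ``solver_damping`` (default 1.0, i.e. undamped). When the synchronous map
    locks into a stable oscillation instead of converging — which happens for
    genomes with strong near-threshold couplings — the solve is restarted
    deterministically with progressively smaller damping factors. A point
    accepted at any damping is a genuine fixed point of the undamped system,
    and the reported state always satisfies |F(e) - e| < solver_tol.
    """
    n = M.shape[0]
    knockouts = frozenset(knockouts)
    ko_mask = np.isin(gene_ids, np.fromiter(knockouts, dtype=np.int64, count=len(knockouts)))
    background = params.sigma_basal + env.delta_sigma_env
    e_init = np.full(n, params.e_half)

    ladder = damping_ladder(params)

    trajectory = None
    if record_trajectory:
        total_iterations = 0
        for damping in ladder:
            max_iter = int(round(_BUDGET_FACTOR * params.solver_max_iter / damping))
            expression, sigma_out, U_out, iterations, converged, trajectory = _solve_python(
                M, background, params, e_init, ko_mask, damping, max_iter
            )
            total_iterations += int(iterations)
            if converged:
                break
    else:
        expression, sigma_out, U_out, total_iterations, converged, damping = solve_ladder_kernel(
            np.ascontiguousarray(M, dtype=np.float64),
            background,
            params.sigma_half,
            params.epsilon,
            params.m,
            params.e_half,
            ko_mask,
            params.solver_tol,
            params.solver_max_iter,
            np.asarray(ladder),
            _BUDGET_FACTOR,
        )

    if not converged:
        warnings.warn(
            f"fixed-point iteration did not converge within {params.solver_max_iter} "
            f"iterations at any damping (env shift {env.delta_sigma_env:+g})",
            ConvergenceWarning,
            stacklevel=2,
        )
    return ExpressionState(
        expression=np.asarray(expression),
        sigma_local=np.asarray(sigma_out),
        opening=np.asarray(U_out),
        converged=bool(converged),
        iterations=total_iterations,
        gene_ids=np.asarray(gene_ids),
        knockouts=knockouts,
        damping=damping,
        trajectory=trajectory,
    )


_DAMPING_LADDER = (0.5, 0.25, 0.1, 0.05, 0.02, 0.01, 0.005)
_BUDGET_FACTOR = 5


def damping_ladder(params: SimulationParams) -> list[float]:
    """Sequence of damping factors attempted in order: the configured default
    first, then progressively heavier damping for oscillation-prone systems."""
    ladder = [params.solver_damping]
    for d in _DAMPING_LADDER:
        if d < ladder[-1]:
            ladder.append(d)
    return ladder


def _solve_python(M, background, params, e_init, ko_mask, damping, max_iter):
    """Pure-numpy mirror of the compiled kernel, recording the trajectory."""
    e = e_init.copy()
    e[ko_mask] = 0.0
    traj = [e.copy()]
    e_prev = None
    converged = False
    iterations = 0
    best_residual = np.inf
    stale = 0
    while iterations < max_iter:
        iterations += 1
        sigma = background + M @ e
        U = opening_energy(sigma, params)
        raw = expression_from_opening(U, params)
        raw[ko_mask] = 0.0
        residual = np.max(np.abs(raw - e))
        if residual < params.solver_tol:
            converged = True
            break
        e_new = raw if damping == 1.0 else e + damping * (raw - e)
        if (
            e_prev is not None
            and np.max(np.abs(e_new - e_prev)) < params.solver_tol
            and np.max(np.abs(e_new - e)) > 1000.0 * params.solver_tol
        ):
            break  # genuine period-2 cycle
        if residual < 0.999 * best_residual:
            best_residual = residual
            stale = 0
        else:
            stale += 1
            if stale > 200:
                break  # stagnated oscillation
        e_prev = e
        e = e_new
        traj.append(e.copy())
    sigma_out = background + M @ e
    U_out = opening_energy(sigma_out, params)
    return e, sigma_out, U_out, iterations, converged, np.array(traj)


def solve_expression(
    genome: Genome,
    params: SimulationParams,
    env: Environment | float,
    knockouts: Iterable[int] = (),
    record_trajectory: bool = False,
) -> ExpressionState:
    """Equilibrium expression of every gene of ``genome`` in ``env``.

    ``env`` may be an :class:`Environment` or a bare ``delta_sigma_env``
    float. ``knockouts`` is a set of gene ids whose transcription rate is
    pinned to exactly 0 throughout the computation.
    """
    if not isinstance(env, Environment):
        env = Environment(float(env))
    gene_ids = genome.gene_ids
    unknown = frozenset(knockouts) - set(gene_ids.tolist())
    if unknown:
        raise KeyError(f"knockout ids not in genome: {sorted(unknown)}")
    M = build_interaction_matrix(genome, params)
    return solve_from_matrix(
        M, params, env, gene_ids, knockouts=knockouts, record_trajectory=record_trajectory
    )


def activated(state: ExpressionState, params: SimulationParams) -> np.ndarray:
    """Boolean activation vector: expression strictly above e_half."""
    return state.expression > params.e_half
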