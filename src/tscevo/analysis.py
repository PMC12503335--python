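"""Post-hoc analyses of evolved genomes.

Covers activation statistics per environment, continuous environment sweeps,
the oriented pair census with per-pair supercoiling contributions, the
canonical triplet census, minimal contiguous-subnetwork sizes, and the
knockout-derived effective interaction graph with its connectivity statistics.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression import (
    activated,
    build_interaction_matrix,
    isolated_gene_expression,
    solve_from_matrix,
    solve_expression,
)
from .genome import FORWARD, GENE_TYPES, REVERSE, Genome, random_genome
from .params import Environment, SimulationParams

ENV_NAMES = ("A", "B")
PAIR_ORIENTATIONS = ("convergent", "divergent", "focal_upstream", "focal_downstream")


# -- activation statistics ---------------------------------------------------


def activation_counts(genome: Genome, params: SimulationParams) -> dict:
    """Number of activated genes (e > e_half) per type, in each environment."""
    counts: dict = {}
    types = genome.type_codes
    for env in params.environments():
        state = solve_expression(genome, params, env)
        act = activated(state, params)
        counts[env.name] = {
            t: int(act[types == code].sum()) for code, t in enumerate(GENE_TYPES)
        }
    return counts


def environment_sweep(
    genomes: Genome | Sequence[Genome],
    params: SimulationParams,
    grid: Optional[Iterable[float]] = None,
    n_random_baseline: int = 30,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Mean expression per gene type as a function of a continuously varying
    environmental supercoiling shift, with two baselines: the closed-form
    isolated (neighbor-less) gene and the average over freshly drawn random
    genomes.

    Returns a tidy frame with columns ``delta_sigma_env``, ``series`` (gene
    type, ``"isolated"`` or ``"random"``), ``mean_expression`` and
    ``converged`` (fraction of solves that converged at that grid point).
    """
    if isinstance(genomes, Genome):
        genomes = [genomes]
    if grid is None:
        grid = np.arange(-0.02, 0.0201, 0.001)
    grid = [float(d) for d in grid]
    if rng is None:
        rng = np.random.default_rng(0)
    randoms = [
        random_genome(
            params.n_genes_per_type,
            params.gene_length,
            params.intergene,
            params.sigma_basal,
            rng,
        )
        for _ in range(n_random_baseline)
    ]

    rows = []
    mats = [(g, build_interaction_matrix(g, params)) for g in genomes]
    rmats = [(g, build_interaction_matrix(g, params)) for g in randoms]
    for delta in grid:
        env = Environment(delta)
        by_type = {t: [] for t in GENE_TYPES}
        ok = []
        for g, M in mats:
            state = solve_from_matrix(M, params, env, g.gene_ids)
            ok.append(state.converged)
            for code, t in enumerate(GENE_TYPES):
                by_type[t].append(float(state.expression[g.type_codes == code].mean()))
        for t in GENE_TYPES:
            rows.append(
                {
                    "delta_sigma_env": delta,
                    "series": t,
                    "mean_expression": float(np.mean(by_type[t])),
                    "converged": float(np.mean(ok)),
                }
            )
        rows.append(
            {
                "delta_sigma_env": delta,
                "series": "isolated",
                "mean_expression": isolated_gene_expression(params, delta),
                "converged": 1.0,
            }
        )
        rand_means, rand_ok = [], []
        for g, M in rmats:
            state = solve_from_matrix(M, params, env, g.gene_ids)
            rand_ok.append(state.converged)
            rand_means.append(float(state.expression.mean()))
        rows.append(
            {
                "delta_sigma_env": delta,
                "series": "random",
                "mean_expression": float(np.mean(rand_means)) if rand_means else np.nan,
                "converged": float(np.mean(rand_ok)) if rand_ok else 1.0,
            }
        )
    return pd.DataFrame(rows)


# -- oriented pair census ----------------------------------------------------


def _pair_orientation(left_orient: str, right_orient: str, focal_is_left: bool) -> str:
    """Relative orientation of an adjacent (focal, target) pair, reading the
    arc with the two genes side by side: head-to-head genes are convergent,
    tail-to-tail divergent; for co-oriented genes the focal is upstream when
    the reading direction runs from focal to target."""
    if (left_orient, right_orient) == (FORWARD, REVERSE):
        return "convergent"
    if (left_orient, right_orient) == (REVERSE, FORWARD):
        return "divergent"
    if left_orient == FORWARD:  # both forward: reading direction left -> right
        return "focal_upstream" if focal_is_left else "focal_downstream"
    return "focal_downstream" if focal_is_left else "focal_upstream"


def census_pairs(genome: Genome, params: SimulationParams) -> dict:
    """Census of oriented pairs of adjacent genes and their supercoiling coupling.

    Every adjacent pair on the circle is counted twice, once per choice of
    focal gene, giving 2n oriented pairs. Returns a dict with

    - ``counts``: frame (focal_type, target_type, orientation, count) over the
      full 9 x 4 taxonomy (zeros included);
    - ``contributions``: frame (focal_type, target_type, environment,
      positive, negative): the transcription-generated supercoiling of focal
      genes measured at the promoter of adjacent target genes at equilibrium,
      M[target, focal] * e_focal, summed over pairs and split by sign.
    """
    if genome.n_genes < 2:
        raise ValueError("pair census needs at least two genes")
    M = build_interaction_matrix(genome, params)
    ids = genome.gene_ids
    states = {
        env.name: solve_from_matrix(M, params, env, ids) for env in params.environments()
    }

    counts = Counter()
    contrib: dict = Counter()
    n = genome.n_genes
    for k in range(n):
        left, right = genome.genes[k], genome.genes[(k + 1) % n]
        li, ri = k, (k + 1) % n
        for focal_idx, target_idx, focal_is_left in ((li, ri, True), (ri, li, False)):
            focal, target = genome.genes[focal_idx], genome.genes[target_idx]
            orient = _pair_orientation(left.orientation, right.orientation, focal_is_left)
            counts[(focal.gene_type, target.gene_type, orient)] += 1
            coef = M[target_idx, focal_idx]
            for env_name, state in states.items():
                val = coef * float(state.expression[focal_idx])
                key = (focal.gene_type, target.gene_type, env_name)
                if val >= 0:
                    contrib[key + ("positive",)] += val
                else:
                    contrib[key + ("negative",)] += val

    count_rows = [
        {"focal_type": f, "target_type": t, "orientation": o, "count": counts[(f, t, o)]}
        for f in GENE_TYPES
        for t in GENE_TYPES
        for o in PAIR_ORIENTATIONS
    ]
    contrib_rows = [
        {
            "focal_type": f,
            "target_type": t,
            "environment": e,
            "positive": float(contrib[(f, t, e, "positive")]),
            "negative": float(contrib[(f, t, e, "negative")]),
        }
        for f in GENE_TYPES
        for t in GENE_TYPES
        for e in ENV_NAMES
    ]
    return {"counts": pd.DataFrame(count_rows), "contributions": pd.DataFrame(contrib_rows)}


# -- triplet census ----------------------------------------------------------

Triplet = tuple[tuple[str, str], tuple[str, str], tuple[str, str]]


def canonicalize_triplet(types: Sequence[str], orientations: Sequence[str]) -> Triplet:
    """Map a (types, orientations) triple to its canonical class.

    A triplet read in the opposite direction (reversed order, all orientations
    flipped) describes the same physical arrangement; the canonical
    representative is the one whose central gene is in forward (leading)
    orientation, quotienting the 216 raw classes into 108.
    """
    trip = tuple(zip(types, orientations))
    if trip[1][1] == REVERSE:
        flip = {FORWARD: REVERSE, REVERSE: FORWARD}
        trip = tuple((t, flip[o]) for t, o in reversed(trip))
    return trip  # type: ignore[return-value]


def all_raw_triplets() -> list[Triplet]:
    """The 216 raw (type, orientation) triples."""
    units = [(t, o) for t in GENE_TYPES for o in (FORWARD, REVERSE)]
    return [tuple(c) for c in itertools.product(units, repeat=3)]


def all_canonical_triplets() -> list[Triplet]:
    """The 108 canonical triplet classes, in a stable order."""
    seen: dict = {}
    for trip in all_raw_triplets():
        canon = canonicalize_triplet([u[0] for u in trip], [u[1] for u in trip])
        seen.setdefault(canon, None)
    return list(seen)


def census_triplets(genome: Genome) -> pd.DataFrame:
    """Relative frequency of every canonical triplet class among the n
    consecutive gene triples of the circular genome (frequencies sum to 1)."""
    n = genome.n_genes
    if n < 3:
        raise ValueError("triplet census needs at least three genes")
    counts: Counter = Counter()
    for k in range(n):
        window = [genome.genes[(k + t) % n] for t in range(3)]
        canon = canonicalize_triplet(
            [g.gene_type for g in window], [g.orientation for g in window]
        )
        counts[canon] += 1
    rows = []
    for canon in all_canonical_triplets():
        (t1, o1), (t2, o2), (t3, o3) = canon
        rows.append(
            {
                "types": f"{t1},{t2},{t3}",
                "orientations": f"{o1}{o2}{o3}",
                "count": counts[canon],
                "frequency": counts[canon] / n,
            }
        )
    return pd.DataFrame(rows)


# -- minimal contiguous subnetworks ------------------------------------------


def _linear_interaction_matrix(
    positions: np.ndarray,
    lengths: np.ndarray,
    orients: np.ndarray,
    params: SimulationParams,
) -> np.ndarray:
    """Interaction matrix of genes laid out on a line (no circular wrap),
    with coordinates already unrolled to preserve the original arc distances."""
    promoters = np.where(orients > 0, positions, positions + lengths)
    mids = positions + lengths / 2.0
    delta = mids[None, :] - promoters[:, None]  # signed, along the line
    dist = np.abs(delta)
    downstream = (delta > 0) == (orients[:, None] > 0)
    same = (orients[:, None] > 0) == (orients[None, :] > 0)
    eta = np.where(~downstream == same, 1.0, -1.0)
    M = eta * params.c * np.maximum(1.0 - dist / params.d_max, 0.0)
    np.fill_diagonal(M, 0.0)
    return M


def _subnetwork_state(
    genome: Genome, params: SimulationParams, center: int, k: int, env: Environment
) -> np.ndarray:
    """Equilibrium expression of the k consecutive genes centered on index
    ``center``, evaluated as a linear arrangement with original arc spacing."""
    n = genome.n_genes
    h = k // 2
    idx = [(center - h + t) % n for t in range(k)]
    begins = genome.begins
    L = genome.total_length
    pos = np.empty(k)
    pos[0] = 0.0
    for t in range(1, k):
        pos[t] = pos[t - 1] + (begins[idx[t]] - begins[idx[t - 1]]) % L
    lengths = genome.lengths[idx]
    orients = genome.orientations[idx]
    M = _linear_interaction_matrix(pos, lengths, orients, params)
    state = solve_from_matrix(M, params, env, genome.gene_ids[idx])
    return state.expression


def minimal_subnetwork_size(
    genome: Genome,
    params: SimulationParams,
    gene_id: int,
    env: Environment | str,
    full_state=None,
) -> int:
    """Smallest odd number k of contiguous genes centered on ``gene_id`` whose
    isolated (linear) evaluation reproduces the gene's full-genome activation
    state in ``env``; returns n (the full circular genome) if no odd k < n does."""
    if isinstance(env, str):
        env = {"A": params.environment_A, "B": params.environment_B}[env]
    if full_state is None:
        full_state = solve_expression(genome, params, env)
    n = genome.n_genes
    hits = np.nonzero(genome.gene_ids == gene_id)[0]
    if len(hits) == 0:
        raise KeyError(f"no gene with id {gene_id}")
    center = int(hits[0])
    e_half = params.e_half
    target = full_state.expression[center] > e_half
    for k in range(1, n, 2):
        expr = _subnetwork_state(genome, params, center, k, env)
        if (expr[k // 2] > e_half) == target:
            return k
    return n


# -- knockouts and the effective interaction graph ---------------------------


def knockout_switches(
    genome: Genome,
    params: SimulationParams,
    gene_id: int,
    base_states: Optional[dict] = None,
    M: Optional[np.ndarray] = None,
) -> dict:
    """Genes whose activation state is switched by knocking out ``gene_id``.

    Returns ``{env name: {switched gene id: "activation" | "inhibition"}}``;
    an on -> off switch is evidence that the knocked-out gene activated the
    target, off -> on that it inhibited it. The knocked-out gene itself is
    never reported.
    """
    if M is None:
        M = build_interaction_matrix(genome, params)
    ids = genome.gene_ids
    if base_states is None:
        base_states = {
            env.name: solve_from_matrix(M, params, env, ids)
            for env in params.environments()
        }
    e_half = params.e_half
    out: dict = {}
    for env in params.environments():
        base = base_states[env.name].expression > e_half
        ko = solve_from_matrix(M, params, env, ids, knockouts=(gene_id,))
        after = ko.expression > e_half
        switches = {}
        for i, gid in enumerate(ids):
            if gid == gene_id:
                continue
            if base[i] and not after[i]:
                switches[int(gid)] = "activation"
            elif after[i] and not base[i]:
                switches[int(gid)] = "inhibition"
        out[env.name] = switches
    return out


def build_effective_graph(genome: Genome, params: SimulationParams) -> nx.DiGraph:
    """Directed graph of effective gene-gene influences revealed by knockouts.

    Every gene is knocked out in turn; an edge g -> h is added when the
    knockout of g switches h's activation state in at least one environment.
    A pair switched in both environments keeps a single edge; its ``label`` is
    ``"activation"``, ``"inhibition"``, or ``"mixed"`` when the environments
    disagree.
    """
    M = build_interaction_matrix(genome, params)
    ids = genome.gene_ids
    base_states = {
        env.name: solve_from_matrix(M, params, env, ids) for env in params.environments()
    }
    G = nx.DiGraph()
    for g in genome.genes:
        G.add_node(g.id, gene_type=g.gene_type)
    for g in genome.genes:
        switches = knockout_switches(genome, params, g.id, base_states=base_states, M=M)
        labels: dict = {}
        for env_name in ENV_NAMES:
            for target, direction in switches[env_name].items():
                labels.setdefault(target, set()).add(direction)
        for target, directions in labels.items():
            label = directions.pop() if len(directions) == 1 else "mixed"
            G.add_edge(g.id, target, label=label)
    return G


def graph_stats(G: nx.DiGraph) -> dict:
    """WCC size distribution and mean in/out degree by gene type.

    Connectivity ignores edge directions and labels; degrees are averaged by
    the type of the knocked-out gene (out-degree) and of the switched gene
    (in-degree).
    """
    wcc_sizes = sorted((len(c) for c in nx.weakly_connected_components(G)), reverse=True)
    out_deg: dict = {t: [] for t in GENE_TYPES}
    in_deg: dict = {t: [] for t in GENE_TYPES}
    for node, data in G.nodes(data=True):
        t = data["gene_type"]
        out_deg[t].append(G.out_degree(node))
        in_deg[t].append(G.in_degree(node))
    return {
        "wcc_sizes": wcc_sizes,
        "n_edges": G.number_of_edges(),
        "mean_out_degree": {
            t: float(np.mean(v)) if v else float("nan") for t, v in out_deg.items()
        },
        "mean_in_degree": {
            t: float(np.mean(v)) if v else float("nan") for t, v in in_deg.items()
        },
    }


def random_genome_baseline(
    params: SimulationParams,
    n_genomes: int,
    rng: np.random.Generator,
    analysis: Callable[[Genome], object],
) -> list:
    """Apply ``analysis`` to freshly drawn random genomes (same genome
    parameters as evolution founders), for comparison with evolved genomes."""
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    results = []
    for _ in range(n_genomes):
        g = random_genome(
            params.n_genes_per_type,
            params.gene_length,
            params.intergene,
            params.sigma_basal,
            rng,
        )
        results.append(analysis(g))
    return results


# -- replicate aggregation ----------------------------------------------------


def geometric_mean_best_fitness(runlogs: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-generation geometric mean of the best fitness across replicates,
    with first/last decile traces. Replicates are aligned on the generations
    they all share."""
    frames = []
    for i, log in enumerate(runlogs):
        df = log.to_frame() if hasattr(log, "to_frame") else log
        frames.append(df[["generation", "best_fitness"]].set_index("generation"))
    wide = pd.concat(frames, axis=1, join="inner")
    values = wide.to_numpy()
    if (values <= 0).any():
        raise ValueError("fitness must be strictly positive")
    logs = np.log(values)
    return pd.DataFrame(
        {
            "generation": wide.index,
            "geometric_mean": np.exp(logs.mean(axis=1)),
            "decile_first": np.quantile(values, 0.1, axis=1),
            "decile_last": np.quantile(values, 0.9, axis=1),
        }
    ).reset_index(drop=True)
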