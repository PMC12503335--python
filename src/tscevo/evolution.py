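"""Evolutionary loop: fitness in two environments, selection, inversions.

Individuals reproduce in non-overlapping generations. Each generation the
fitness f = exp(-k * g) of every genome is computed from its equilibrium
expression in the two environments (g is the summed squared gap between the
per-type mean expression and its target), N parents are drawn proportionally
to fitness with replacement, and each offspring receives K ~ Poisson(lam)
random inversions. All randomness of a replicate flows from one seeded
generator in a fixed draw order (selection, then per-offspring mutations),
so a (seed, params) pair fully determines the run.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._kernels import matrix_batch_kernel, solve_batch_kernel
from .expression import _BUDGET_FACTOR, build_interaction_matrix, damping_ladder, solve_from_matrix
from .genome import GENE_TYPES, Genome, mutate, random_genome
from .params import SimulationParams

ENV_NAMES = ("A", "B")


@dataclass(frozen=True)
class FitnessReport:
    """Per-type mean expression in each environment, gap g, and fitness exp(-k g)."""

    mean_expression: dict  # env name -> {gene type -> mean expression}
    activated_counts: dict  # env name -> {gene type -> count of e > e_half}
    gap: float
    fitness: float
    converged: bool


@dataclass
class Population:
    individuals: list
    generation: int = 0

    @property
    def size(self) -> int:
        return len(self.individuals)


@dataclass
class RunLog:
    """One record per generation: best individual's fitness, gap, activation counts."""

    records: list = field(default_factory=list)

    def append(self, generation: int, report: FitnessReport) -> None:
        row = {
            "generation": generation,
            "best_fitness": report.fitness,
            "best_gap": report.gap,
        }
        for env in ENV_NAMES:
            for t in GENE_TYPES:
                row[f"activated_{t}_env{env}"] = report.activated_counts[env][t]
        self.records.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def expression_targets(params: SimulationParams) -> dict:
    """Target per-type mean expression in each environment: A and AB genes at
    the maximum (1) in environment A, B genes at the minimum exp(-m); the
    symmetric pattern in environment B."""
    lo, hi = params.e_min, 1.0
    return {
        "A": {"A": hi, "B": lo, "AB": hi},
        "B": {"A": lo, "B": hi, "AB": hi},
    }


def evaluate(genome: Genome, params: SimulationParams) -> FitnessReport:
    """Solve the expression system in both environments and score the genome."""
    M = build_interaction_matrix(genome, params)
    states = [
        solve_from_matrix(M, params, env, genome.gene_ids)
        for env in params.environments()
    ]
    expressions = np.stack([s.expression for s in states])
    ok = np.array([s.converged for s in states])
    return _reports_from_expressions(genome, expressions, ok, params)


def _reports_from_expressions(genome: Genome, expressions: np.ndarray, ok: np.ndarray,
                              params: SimulationParams) -> FitnessReport:
    """Assemble a FitnessReport from the (n_env, n) expression block of one genome."""
    onehot = genome.type_onehot
    n_per_type = onehot.sum(axis=0)
    targets = expression_targets(params)
    # (n_env, 3): per-type mean expression and activation count, columns A,B,AB
    means = (expressions @ onehot) / n_per_type
    counts = (expressions > params.e_half) @ onehot
    mean_expression: dict = {}
    activated_counts: dict = {}
    gap = 0.0
    for v, env in enumerate(params.environments()):
        mean_expression[env.name] = {t: float(means[v, c]) for c, t in enumerate(GENE_TYPES)}
        activated_counts[env.name] = {t: int(counts[v, c]) for c, t in enumerate(GENE_TYPES)}
        for c, t in enumerate(GENE_TYPES):
            gap += (means[v, c] - targets[env.name][t]) ** 2
    fitness = float(np.exp(-params.k_selection * gap))
    return FitnessReport(mean_expression, activated_counts, float(gap), fitness, bool(ok.all()))


def evaluate_batch(genomes: list, params: SimulationParams) -> list:
    """Evaluate many genomes at once through the batched compiled solver.

    Produces the same numbers as :func:`evaluate` genome by genome, but
    amortizes dispatch overhead across the population; used by the
    generational loop.
    """
    if not genomes:
        return []
    promoters = np.stack([g.promoters for g in genomes])
    mids = np.stack([g.middles for g in genomes])
    orients = np.stack([g.orientations for g in genomes])
    L = float(genomes[0].total_length)
    Ms = matrix_batch_kernel(promoters, mids, orients, L, params.c, params.d_max)
    backgrounds = np.array(
        [params.sigma_basal + env.delta_sigma_env for env in params.environments()]
    )
    expressions, ok = solve_batch_kernel(
        Ms,
        backgrounds,
        params.sigma_half,
        params.epsilon,
        params.m,
        params.e_half,
        params.solver_tol,
        params.solver_max_iter,
        np.asarray(damping_ladder(params)),
        _BUDGET_FACTOR,
    )
    n_bad = int((~ok).sum())
    if n_bad:
        import warnings

        from .expression import ConvergenceWarning

        warnings.warn(
            f"{n_bad} of {ok.size} population solves did not converge",
            ConvergenceWarning,
            stacklevel=2,
        )
    return [
        _reports_from_expressions(g, expressions[i], ok[i], params)
        for i, g in enumerate(genomes)
    ]


def select_reproducers(fitnesses: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw N parent indices proportionally to fitness, with replacement."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    total = fitnesses.sum()
    if total <= 0:
        raise ValueError("all fitnesses are zero; cannot select reproducers")
    n = len(fitnesses)
    return rng.choice(n, size=n, replace=True, p=fitnesses / total)


class _FitnessCache:
    """Content-addressed fitness memo; clones (and unmutated offspring) are
    only ever evaluated once. Cleared wholesale when it outgrows its cap."""

    def __init__(self, maxsize: int = 4096):
        self.maxsize = maxsize
        self._data: dict = {}

    def get(self, genome: Genome, params: SimulationParams) -> FitnessReport:
        key = genome.signature()
        report = self._data.get(key)
        if report is None:
            report = evaluate(genome, params)
            if len(self._data) >= self.maxsize:
                self._data.clear()
            self._data[key] = report
        return report

    def get_all(self, genomes: list, params: SimulationParams) -> list:
        """Batched lookup: unseen genomes are evaluated together."""
        keys = [g.signature() for g in genomes]
        unique: dict = {}
        for key, g in zip(keys, genomes):
            unique.setdefault(key, g)
        fresh = {k: g for k, g in unique.items() if k not in self._data}
        if fresh:
            if len(self._data) + len(fresh) >= self.maxsize:
                self._data.clear()
                fresh = unique  # keep every key needed by this call
            reports = evaluate_batch(list(fresh.values()), params)
            for key, report in zip(fresh, reports):
                self._data[key] = report
        return [self._data[key] for key in keys]


def step_generation(
    pop: Population,
    params: SimulationParams,
    rng: np.random.Generator,
    log: Optional[RunLog] = None,
    cache: Optional[_FitnessCache] = None,
) -> Population:
    """Advance one non-overlapping generation; logs the evaluated parents' best."""
    if cache is None:
        cache = _FitnessCache()
    reports = cache.get_all(pop.individuals, params)
    fitnesses = np.array([r.fitness for r in reports])
    if log is not None:
        log.append(pop.generation, reports[int(np.argmax(fitnesses))])
    parents = select_reproducers(fitnesses, rng)
    offspring = [mutate(pop.individuals[int(i)], params.lam, rng) for i in parents]
    return Population(offspring, pop.generation + 1)


def run_replicate(
    seed: int,
    params: SimulationParams,
    n_generations: int,
    out_dir: Optional[str] = None,
    checkpoint_every: int = 1000,
) -> tuple[RunLog, Population]:
    """Evolve one replicate from N clones of a fresh random genome.

    Returns the per-generation log (including the final generation's parents)
    and the final population. If ``out_dir`` is given, writes ``runlog.csv``,
    ``params.json``, periodic ``best_gen<t>.json`` snapshots and a final
    ``best_final.json`` (all writes are atomic: write-then-rename).
    """
    from .io import save_genome  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    founder = random_genome(
        params.n_genes_per_type,
        params.gene_length,
        params.intergene,
        params.sigma_basal,
        rng,
    )
    pop = Population([founder] * params.pop_size, generation=0)
    log = RunLog()
    cache = _FitnessCache()

    def best_of(p: Population) -> Genome:
        reports = cache.get_all(p.individuals, params)
        return p.individuals[int(np.argmax([r.fitness for r in reports]))]

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        _atomic_write(
            os.path.join(out_dir, "params.json"),
            json.dumps({"seed": seed, "n_generations": n_generations, **_params_dict(params)}, indent=2),
        )

    for _ in range(n_generations):
        gen = pop.generation
        if out_dir is not None and checkpoint_every and gen % checkpoint_every == 0:
            save_genome(best_of(pop), os.path.join(out_dir, f"best_gen{gen}.json"))
            save_checkpoint(pop, rng, os.path.join(out_dir, "checkpoint.json"))
        pop = step_generation(pop, params, rng, log=log, cache=cache)

    # log the final population's parents as well
    reports = cache.get_all(pop.individuals, params)
    best_idx = int(np.argmax([r.fitness for r in reports]))
    log.append(pop.generation, reports[best_idx])

    if out_dir is not None:
        save_genome(pop.individuals[best_idx], os.path.join(out_dir, "best_final.json"))
        _atomic_write(os.path.join(out_dir, "runlog.csv"), log.to_frame().to_csv(index=False))
    return log, pop


def save_checkpoint(pop: Population, rng: np.random.Generator, path: str) -> None:
    """Write the full replicate state (generation, genomes, RNG state) as JSON;
    resuming from it reproduces the uninterrupted run bit-exactly."""
    from .io import genome_to_dict

    data = {
        "generation": pop.generation,
        "rng_state": rng.bit_generator.state,
        "individuals": [genome_to_dict(g) for g in pop.individuals],
    }
    _atomic_write(path, json.dumps(data))


def load_checkpoint(path: str) -> tuple[Population, np.random.Generator]:
    from .io import genome_from_dict

    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    pop = Population(
        [genome_from_dict(d) for d in data["individuals"]],
        generation=data["generation"],
    )
    rng = np.random.default_rng()
    rng.bit_generator.state = data["rng_state"]
    return pop, rng


def resume_replicate(
    checkpoint_path: str,
    params: SimulationParams,
    n_generations: int,
    out_dir: Optional[str] = None,
    checkpoint_every: int = 1000,
) -> tuple[RunLog, Population]:
    """Continue a replicate from a checkpoint up to ``n_generations`` total;
    the log covers the resumed generations only."""
    pop, rng = load_checkpoint(checkpoint_path)
    log = RunLog()
    cache = _FitnessCache()
    while pop.generation < n_generations:
        if (
            out_dir is not None
            and checkpoint_every
            and pop.generation % checkpoint_every == 0
        ):
            save_checkpoint(pop, rng, os.path.join(out_dir, "checkpoint.json"))
        pop = step_generation(pop, params, rng, log=log, cache=cache)
    reports = cache.get_all(pop.individuals, params)
    best_idx = int(np.argmax([r.fitness for r in reports]))
    log.append(pop.generation, reports[best_idx])
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        from .io import save_genome

        save_genome(pop.individuals[best_idx], os.path.join(out_dir, "best_final.json"))
        _atomic_write(os.path.join(out_dir, "runlog.csv"), log.to_frame().to_csv(index=False))
    return log, pop


def _params_dict(params: SimulationParams) -> dict:
    from dataclasses import asdict

    return asdict(params)


def _atomic_write(path: str, text: str) -> None:
    tmp = path + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(text)
    os.replace(tmp, path)
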