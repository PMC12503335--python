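"""Serialization and configuration plumbing.

Genome files use a small JSON schema that round-trips bit-exactly; run
configurations are read from TOML or JSON (unknown keys rejected, missing
keys defaulted) and always echoed back to disk as fully resolved JSON so a
run can be replayed without the original file.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .expression import ExpressionState, activated
from .genome import Gene, Genome
from .params import PARAM_FIELDS, SimulationParams

GENOME_SCHEMA_VERSION = 1


# -- genome files ------------------------------------------------------------


def genome_to_dict(genome: Genome) -> dict:
    return {
        "schema_version": GENOME_SCHEMA_VERSION,
        "total_length": genome.total_length,
        "sigma_basal": genome.sigma_basal,
        "genes": [
            {
                "id": g.id,
                "type": g.gene_type,
                "begin": g.begin,
                "length": g.length,
                "orientation": g.orientation,
                "basal_expression": g.basal_expression,
            }
            for g in genome.genes
        ],
    }


def genome_from_dict(data: dict) -> Genome:
    if "schema_version" not in data:
        raise ValueError("genome file lacks a schema_version field")
    if data["schema_version"] != GENOME_SCHEMA_VERSION:
        raise ValueError(f"unsupported genome schema version {data['schema_version']!r}")
    genes = [
        Gene(
            id=g["id"],
            gene_type=g["type"],
            begin=g["begin"],
            length=g["length"],
            orientation=g["orientation"],
            basal_expression=g.get("basal_expression", 1.0),
        )
        for g in data["genes"]
    ]
    # Genome.__init__ revalidates non-overlap and coordinate ranges
    return Genome(genes, data["total_length"], data["sigma_basal"])


def save_genome(genome: Genome, path: str) -> None:
    _atomic_write(path, json.dumps(genome_to_dict(genome), indent=2))


def load_genome(path: str) -> Genome:
    with open(path, encoding="utf-8") as fh:
        return genome_from_dict(json.load(fh))


def export_gff3(genome: Genome, path: str, seqid: str = "chromosome") -> None:
    """Write one ``gene`` feature per gene (1-based inclusive coordinates)."""
    lines = ["##gff-version 3", f"##sequence-region {seqid} 1 {genome.total_length}"]
    for g in genome.genes:
        attrs = f"ID=gene{g.id};gene_type={g.gene_type}"
        lines.append(
            "\t".join(
                [
                    seqid,
                    "tscevo",
                    "gene",
                    str(g.begin + 1),
                    str(g.begin + g.length),
                    ".",
                    g.orientation,
                    ".",
                    attrs,
                ]
            )
        )
    _atomic_write(path, "\n".join(lines) + "\n")


# -- expression state CSV -----------------------------------------------------


def expression_state_to_frame(
    genome: Genome, state: ExpressionState, params: SimulationParams
) -> pd.DataFrame:
    act = activated(state, params)
    return pd.DataFrame(
        {
            "gene_id": [g.id for g in genome.genes],
            "type": [g.gene_type for g in genome.genes],
            "orientation": [g.orientation for g in genome.genes],
            "begin": [g.begin for g in genome.genes],
            "expression": state.expression,
            "sigma_local": state.sigma_local,
            "activated": act,
        }
    )


def trajectory_to_frame(state: ExpressionState) -> pd.DataFrame:
    """Long-format per-iteration record of the fixed-point computation."""
    if state.trajectory is None:
        raise ValueError("state was solved without record_trajectory=True")
    n_iter, n = state.trajectory.shape
    return pd.DataFrame(
        {
            "iteration": np.repeat(np.arange(n_iter), n),
            "gene_id": np.tile(state.gene_ids, n_iter),
            "expression": state.trajectory.ravel(),
        }
    )


# -- effective interaction graph export ---------------------------------------


def export_graph_csv(G, path: str) -> None:
    """Edge list as CSV: source, target, label."""
    rows = [
        {"source": u, "target": v, "label": d.get("label", "")}
        for u, v, d in G.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "label"]).to_csv(path, index=False)


def export_graph_graphml(G, path: str) -> None:
    import networkx as nx

    nx.write_graphml(G, path)


# -- run configuration --------------------------------------------------------


@dataclass
class RunConfig:
    """A resolved experiment configuration: model parameters plus run plumbing."""

    params: SimulationParams = field(default_factory=SimulationParams)
    n_generations: int = 1000
    n_replicates: int = 1
    seed: int = 0
    checkpoint_every: int = 1000
    output_dir: str = "runs"

    def seeds(self) -> list[int]:
        return [self.seed + i for i in range(self.n_replicates)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.params)
        d.update(
            n_generations=self.n_generations,
            n_replicates=self.n_replicates,
            seed=self.seed,
            checkpoint_every=self.checkpoint_every,
            output_dir=self.output_dir,
        )
        return d


_RUN_KEYS = ("n_generations", "n_replicates", "seed", "checkpoint_every", "output_dir")


def config_from_dict(data: dict) -> RunConfig:
    unknown = set(data) - set(PARAM_FIELDS) - set(_RUN_KEYS)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    param_kwargs = {k: data[k] for k in PARAM_FIELDS if k in data}
    run_kwargs = {k: data[k] for k in _RUN_KEYS if k in data}
    # SimulationParams.__post_init__ validates ranges (epsilon > 0, ...)
    return RunConfig(params=SimulationParams(**param_kwargs), **run_kwargs)


def load_config(path: Optional[str]) -> RunConfig:
    """Load a TOML or JSON configuration; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    with open(path, "rb") as fh:
        raw = fh.read()
    if path.endswith(".json"):
        data = json.loads(raw.decode("utf-8"))
    else:
        import tomllib

        try:
            data = tomllib.loads(raw.decode("utf-8"))
        except tomllib.TOMLDecodeError:
            # accept JSON content regardless of extension
            data = json.loads(raw.decode("utf-8"))
    if not isinstance(data, dict):
        raise ValueError("configuration must be a table/object of key-value pairs")
    return config_from_dict(data)


def save_config(config: RunConfig, path: str) -> None:
    """Echo the fully resolved configuration as JSON."""
    _atomic_write(path, json.dumps(config.to_dict(), indent=2))


def _atomic_write(path: str, text: str) -> None:
    directory = os.path.dirname(path)
    if directory:
        os.makedirs(directory, exist_ok=True)
    tmp = path + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(text)
    os.replace(tmp, path)
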