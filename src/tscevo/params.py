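"""Model parameters and environments.

All supercoiling quantities are dimensionless densities (relative over/under-
winding of the double helix); genomic coordinates and distances are in base
pairs. Defaults describe an *E. coli*-like chromosome: a basal supercoiling of
-0.066, promoters that open sigmoidally around sigma_half = -0.042, and a
transcription-generated supercoiling signal that decays linearly over
d_max = 5 kb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields


@dataclass(frozen=True)
class Environment:
    """An environment, defined by the shift it imposes on background supercoiling.

    Positive ``delta_sigma_env`` relaxes DNA (inhibiting transcription at
    default parameters); negative values increase negative supercoiling
    (activating transcription).
    """

    delta_sigma_env: float
    name: str = ""


@dataclass(frozen=True)
class SimulationParams:
    """Every constant of the coupled transcription-supercoiling model.

    Attributes
    ----------
    gene_length : int
        Length ``l`` of every gene, in bp.
    intergene : int
        Initial intergenic distance ``d0`` between consecutive genes, in bp.
    n_genes_per_type : int
        Number of genes of each of the three types (A, B, AB) per genome.
    c : float
        Torsional drag coefficient: magnitude of the supercoiling variation
        generated at zero distance by a gene transcribed at maximal rate.
    d_max : float
        Maximum distance (bp) over which transcription-generated supercoiling
        propagates; the effect decays linearly and vanishes at ``d_max``.
    sigma_basal : float
        Basal supercoiling density of the chromosome.
    sigma_half : float
        Supercoiling level at which promoter opening free energy is at half
        its maximum.
    epsilon : float
        Width of the sigmoidal promoter response; smaller values give a
        sharper transition.
    m : float
        Inverse effective thermal energy; expression spans [exp(-m), 1].
    k_selection : float
        Intensity of selection: fitness = exp(-k * gap).
    lam : float
        Poisson rate of genomic inversions per reproduction event.
    pop_size : int
        Number of individuals N in the (non-overlapping) population.
    delta_sigma_A, delta_sigma_B : float
        Supercoiling shifts of the two selective environments (A relaxes DNA,
        B adds negative supercoiling).
    solver_tol : float
        Max-norm convergence threshold of the fixed-point iteration.
    solver_max_iter : int
        Iteration cap of the fixed-point solver.
    solver_damping : float
        Damping factor of the iteration (1.0 = plain substitution).
    """

    gene_length: int = 1000
    intergene: int = 125
    n_genes_per_type: int = 20
    c: float = 0.03
    d_max: float = 5000.0
    sigma_basal: float = -0.066
    sigma_half: float = -0.042
    epsilon: float = 0.005
    m: float = 2.5
    k_selection: float = 50.0
    lam: float = 2.0
    pop_size: int = 100
    delta_sigma_A: float = 0.01
    delta_sigma_B: float = -0.01
    solver_tol: float = 1e-10
    solver_max_iter: int = 1000
    solver_damping: float = 1.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.m <= 0:
            raise ValueError("m must be > 0")
        if self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0 < self.solver_damping <= 1:
            raise ValueError("solver_damping must be in (0, 1]")

    @property
    def e_min(self) -> float:
        """Minimum expression level exp(-m), reached when the promoter is closed."""
        return math.exp(-self.m)

    @property
    def e_half(self) -> float:
        """Activation threshold: midpoint (exp(-m) + 1) / 2 between the extremes."""
        return 0.5 * (math.exp(-self.m) + 1.0)

    @property
    def environment_A(self) -> Environment:
        return Environment(self.delta_sigma_A, "A")

    @property
    def environment_B(self) -> Environment:
        return Environment(self.delta_sigma_B, "B")

    def environments(self) -> tuple[Environment, Environment]:
        return (self.environment_A, self.environment_B)

    def replace(self, **kwargs) -> "SimulationParams":
        from dataclasses import replace

        return replace(self, **kwargs)


PARAM_FIELDS = tuple(f.name for f in fields(SimulationParams))
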