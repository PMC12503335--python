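"""Circular genome model: typed, oriented genes and the inversion operator.

Coordinates are 0-based, half-open, modulo the genome length ``L``: a gene
occupies ``[begin, begin + length)`` on the circle. The only structural
mutation is the genomic inversion, whose endpoints always fall in intergenic
sequence so that genes are never broken apart; an inversion reverses the
orientation of every gene inside the segment while conserving their relative
spacing, gene counts, and the total amount of intergenic material.

Internally a genome is a set of parallel numpy arrays in begin-sorted order
(positions, lengths, orientations, types, ids); :class:`Gene` objects are
materialized lazily for the object-level API.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable

import numpy as np

from ._kernels import mutate_arrays_kernel

GENE_TYPES = ("A", "B", "AB")
_TYPE_CODE = {t: i for i, t in enumerate(GENE_TYPES)}

FORWARD = "+"
REVERSE = "-"

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
TIE = "tie"


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene on a circular chromosome.

    ``id`` is a stable identity assigned clockwise at genome creation and
    carried along through inversions. ``basal_expression`` is stored as part
    of the genotype but plays no role in the interaction model (all genes
    share the same promoter response).
    """

    id: int
    gene_type: str
    begin: int
    length: int
    orientation: str
    basal_expression: float = 1.0

    def __post_init__(self) -> None:
        if self.gene_type not in GENE_TYPES:
            raise ValueError(f"unknown gene type {self.gene_type!r}")
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if self.length <= 0:
            raise ValueError("gene length must be > 0")

    @property
    def end(self) -> int:
        """One-past-the-end coordinate (not reduced modulo L)."""
        return self.begin + self.length


@dataclass(frozen=True)
class InversionEvent:
    """Two intergenic breakpoints; the non-wrapping arc between them is inverted."""

    start_bp: int
    end_bp: int


class Genome:
    """Ordered, non-overlapping genes on a circle plus a basal supercoiling level."""

    def __init__(self, genes: Iterable[Gene], total_length: int, sigma_basal: float):
        genes = tuple(sorted(genes, key=lambda g: g.begin))
        if not genes:
            raise ValueError("a genome needs at least one gene")
        self.total_length = int(total_length)
        self.sigma_basal = float(sigma_basal)
        self._ids = np.array([g.id for g in genes], dtype=np.int64)
        self._types = np.array([_TYPE_CODE[g.gene_type] for g in genes], dtype=np.int64)
        self._begins = np.array([g.begin for g in genes], dtype=np.int64)
        self._lengths = np.array([g.length for g in genes], dtype=np.int64)
        self._orients = np.array(
            [1 if g.orientation == FORWARD else -1 for g in genes], dtype=np.int64
        )
        self._basal = np.array([g.basal_expression for g in genes], dtype=np.float64)
        self.__dict__["genes"] = genes
        self._validate()

    @classmethod
    def _from_arrays(cls, ids, types, begins, lengths, orients, basal,
                     total_length: int, sigma_basal: float) -> "Genome":
        """Internal fast path: caller guarantees begin-sorted, non-overlapping
        arrays; Gene objects are materialized only on demand."""
        obj = object.__new__(cls)
        obj.total_length = total_length
        obj.sigma_basal = sigma_basal
        obj._ids = ids
        obj._types = types
        obj._begins = begins
        obj._lengths = lengths
        obj._orients = orients
        obj._basal = basal
        return obj

    # -- integrity ---------------------------------------------------------

    def _validate(self) -> None:
        L = self.total_length
        if int(self._lengths.sum()) > L:
            raise ValueError("genes longer than the genome")
        if ((self._begins < 0) | (self._begins >= L)).any():
            raise ValueError("gene begins outside [0, L)")
        # non-overlap on the circle: each gene must end before the next begins
        nxt = np.roll(self._begins, -1)
        gaps = (nxt - self._begins) % L
        if len(self._begins) > 1 and (gaps < self._lengths).any():
            k = int(np.argmax(gaps < self._lengths))
            raise ValueError(f"gene {self._ids[k]} overlaps its successor")
        if len(self._begins) == 1 and self._lengths[0] > L:
            raise ValueError("gene longer than the genome")

    # -- derived views -----------------------------------------------------

    @cached_property
    def genes(self) -> tuple:
        """Gene objects in begin-sorted (clockwise) order."""
        return tuple(
            Gene(
                id=int(self._ids[k]),
                gene_type=GENE_TYPES[self._types[k]],
                begin=int(self._begins[k]),
                length=int(self._lengths[k]),
                orientation=FORWARD if self._orients[k] > 0 else REVERSE,
                basal_expression=float(self._basal[k]),
            )
            for k in range(len(self._ids))
        )

    @property
    def n_genes(self) -> int:
        return len(self._ids)

    @property
    def gene_ids(self) -> np.ndarray:
        """Stable gene identities, in genome (begin-sorted) order."""
        return self._ids

    @property
    def begins(self) -> np.ndarray:
        return self._begins.astype(np.float64)

    @property
    def lengths(self) -> np.ndarray:
        return self._lengths.astype(np.float64)

    @property
    def orientations(self) -> np.ndarray:
        """+1 for forward, -1 for reverse, in genome (begin-sorted) order."""
        return self._orients

    @property
    def type_codes(self) -> np.ndarray:
        """0 = A, 1 = B, 2 = AB, in genome order."""
        return self._types

    @cached_property
    def type_onehot(self) -> np.ndarray:
        """n x 3 indicator matrix of gene types (columns A, B, AB)."""
        onehot = np.zeros((len(self._types), 3))
        onehot[np.arange(len(self._types)), self._types] = 1.0
        return onehot

    @cached_property
    def promoters(self) -> np.ndarray:
        """Promoter position of each gene (bp, modulo L), in genome order."""
        return np.where(
            self._orients > 0,
            self._begins,
            (self._begins + self._lengths) % self.total_length,
        ).astype(np.float64)

    @cached_property
    def middles(self) -> np.ndarray:
        """Middle of each gene (bp, may be half-integer), in genome order."""
        return (self._begins + self._lengths / 2.0) % self.total_length

    @property
    def intergenic_total(self) -> int:
        return self.total_length - int(self._lengths.sum())

    def intergenic_segments(self) -> list[tuple[int, int]]:
        """(start, length) of every intergenic stretch, clockwise; may wrap 0."""
        L = self.total_length
        n = self.n_genes
        begins = self._begins
        lengths = self._lengths
        segs = []
        for k in range(n):
            start = int((begins[k] + lengths[k]) % L)
            seg_len = int((begins[(k + 1) % n] - start) % L) if n > 1 else L - int(lengths[0])
            if seg_len > 0:
                segs.append((start, seg_len))
        return segs

    @cached_property
    def _intergenic_arrays(self) -> tuple[list[int], list[int]]:
        """(segment starts, cumulative segment lengths) for breakpoint sampling."""
        segs = self.intergenic_segments()
        starts = [s for s, _ in segs]
        cum = []
        total = 0
        for _, seg_len in segs:
            total += seg_len
            cum.append(total)
        return starts, cum

    def gene_by_id(self, gene_id: int) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(f"no gene with id {gene_id}")

    @cached_property
    def _signature(self) -> tuple:
        return (
            self._begins.tobytes(),
            self._lengths.tobytes(),
            self._types.tobytes(),
            self._orients.tobytes(),
        )

    def signature(self) -> tuple:
        """Hashable content key (positions, lengths, types, orientations)."""
        return self._signature

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Genome)
            and self.total_length == other.total_length
            and self.sigma_basal == other.sigma_basal
            and self.signature() == other.signature()
            and np.array_equal(self._ids, other._ids)
            and np.array_equal(self._basal, other._basal)
        )

    def __hash__(self) -> int:
        return hash((self.total_length, self.sigma_basal, self.signature()))

    def __repr__(self) -> str:
        return f"Genome(n_genes={self.n_genes}, L={self.total_length}, sigma_basal={self.sigma_basal})"


# -- coordinate arithmetic -------------------------------------------------


def promoter_position(gene: Gene, total_length: int) -> float:
    """Promoter coordinate: ``begin`` for forward genes, ``begin + length`` for
    reverse genes (the half-open right edge), reduced modulo L."""
    if gene.orientation == FORWARD:
        return float(gene.begin % total_length)
    return float((gene.begin + gene.length) % total_length)


def gene_middle(gene: Gene, total_length: int) -> float:
    """Middle of the gene body, the average position of transcribing polymerases."""
    return (gene.begin + gene.length / 2.0) % total_length


def signed_offset(gene_i: Gene, gene_j: Gene, total_length: int) -> tuple[float, str]:
    """Shortest circular distance from gene_i's promoter to gene_j's middle,
    and on which side of gene_i's reading frame gene_j lies.

    Returns ``(distance, side)`` with side one of ``"upstream"``,
    ``"downstream"`` or ``"tie"`` (exact antipodal distance L/2, in which case
    interaction coefficients are defined to vanish).
    """
    if gene_i is gene_j or (gene_i.id == gene_j.id and gene_i == gene_j):
        raise ValueError("signed_offset requires two distinct genes")
    L = total_length
    p = promoter_position(gene_i, L)
    mid = gene_middle(gene_j, L)
    delta = (mid - p) % L
    if delta * 2 == L:
        return (L / 2.0, TIE)
    if delta * 2 < L:
        distance = delta
        clockwise = True
    else:
        distance = L - delta
        clockwise = False
    forward_i = gene_i.orientation == FORWARD
    side = DOWNSTREAM if clockwise == forward_i else UPSTREAM
    return (distance, side)


# -- construction ----------------------------------------------------------


def random_genome(
    n_per_type: int,
    gene_length: int,
    intergene: int,
    sigma_basal: float,
    rng: np.random.Generator,
    basal_expression: float = 1.0,
) -> Genome:
    """Draw a random equally-spaced circular genome with ``3 * n_per_type`` genes.

    Gene types are a uniformly random permutation of the multiset
    {A, B, AB} x n_per_type; each orientation is a fair coin flip; ids are
    assigned clockwise from position 0.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    n = 3 * n_per_type
    types = np.repeat(np.arange(3), n_per_type)
    rng.shuffle(types)
    orients = rng.integers(0, 2, size=n)
    spacing = gene_length + intergene
    genes = [
        Gene(
            id=k,
            gene_type=GENE_TYPES[types[k]],
            begin=k * spacing,
            length=gene_length,
            orientation=FORWARD if orients[k] else REVERSE,
            basal_expression=basal_expression,
        )
        for k in range(n)
    ]
    return Genome(genes, total_length=n * spacing, sigma_basal=sigma_basal)


# -- inversions ------------------------------------------------------------


def sample_inversion(genome: Genome, rng: np.random.Generator) -> InversionEvent:
    """Draw two inversion breakpoints uniformly over all intergenic bp positions.

    Both endpoints may fall in the same intergenic segment, which yields a
    phenotypically neutral inversion.
    """
    starts, cum = genome._intergenic_arrays
    if not cum or cum[-1] <= 0:
        raise ValueError("genome has no intergenic material to break")
    total = cum[-1]
    L = genome.total_length
    points = []
    for u in rng.integers(0, total, size=2):
        k = bisect_right(cum, u)
        prev = cum[k - 1] if k else 0
        points.append(int((starts[k] + (int(u) - prev)) % L))
    a, b = sorted(points)
    return InversionEvent(a, b)


def apply_inversion(genome: Genome, event: InversionEvent) -> Genome:
    """Invert the non-wrapping arc [a, b): genes inside are mirrored within the
    segment and their orientations flipped; everything else is unchanged."""
    a, b = sorted((event.start_bp, event.end_bp))
    L = genome.total_length
    begins = genome._begins
    lengths = genome._lengths
    # a breakpoint cuts *before* its position; it splits a gene only if it is
    # strictly interior (a cut exactly at gene.begin leaves the gene whole)
    for p in (a, b):
        off = (p - begins) % L
        if ((0 < off) & (off < lengths)).any():
            k = int(np.argmax((0 < off) & (off < lengths)))
            raise ValueError(f"inversion endpoint falls inside gene {genome._ids[k]}")
    inside = (begins >= a) & (begins + lengths <= b)
    if not inside.any():
        return Genome._from_arrays(
            genome._ids, genome._types, begins, lengths, genome._orients,
            genome._basal, L, genome.sigma_basal,
        )
    # genes fully inside [a, b) form a contiguous run of the begin-sorted
    # arrays; mirroring reverses their order, so sortedness is preserved
    (idx,) = np.nonzero(inside)
    i0, i1 = int(idx[0]), int(idx[-1]) + 1
    sl = slice(i0, i1)
    rev = slice(i1 - 1, i0 - 1 if i0 > 0 else None, -1)
    new_begins = begins.copy()
    new_begins[sl] = a + b - (begins[rev] + lengths[rev])
    new_lengths = lengths.copy()
    new_lengths[sl] = lengths[rev]
    new_orients = genome._orients.copy()
    new_orients[sl] = -genome._orients[rev]
    new_ids = genome._ids.copy()
    new_ids[sl] = genome._ids[rev]
    new_types = genome._types.copy()
    new_types[sl] = genome._types[rev]
    new_basal = genome._basal.copy()
    new_basal[sl] = genome._basal[rev]
    return Genome._from_arrays(
        new_ids, new_types, new_begins, new_lengths, new_orients, new_basal,
        L, genome.sigma_basal,
    )


def mutate(genome: Genome, lam: float, rng: np.random.Generator) -> Genome:
    """Apply K ~ Poisson(lam) sequential random inversions.

    Endpoints of each inversion are drawn uniformly over the intergenic
    positions of the genome as mutated so far (the total amount of intergenic
    material is invariant, so all draws share one range).
    """
    k = int(rng.poisson(lam)) if lam > 0 else 0
    if k == 0:
        return genome
    total = genome.intergenic_total
    if total <= 0:
        raise ValueError("genome has no intergenic material to break")
    draws = rng.integers(0, total, size=(k, 2))
    begins, lengths, orients, perm = mutate_arrays_kernel(
        genome._begins, genome._lengths, genome._orients,
        genome.total_length, draws,
    )
    return Genome._from_arrays(
        genome._ids[perm], genome._types[perm], begins, lengths, orients,
        genome._basal[perm], genome.total_length, genome.sigma_basal,
    )


# -- symmetry helpers (used by tests and analyses) -------------------------


def rotate_genome(genome: Genome, offset: int) -> Genome:
    """Shift every coordinate by ``offset`` (mod L); dynamics are invariant."""
    from dataclasses import replace

    L = genome.total_length
    genes = [replace(g, begin=(g.begin + offset) % L) for g in genome.genes]
    return Genome(genes, L, genome.sigma_basal)


def mirror_genome(genome: Genome) -> Genome:
    """Reflect all coordinates and flip all orientations; dynamics are invariant."""
    from dataclasses import replace

    L = genome.total_length
    genes = [
        replace(
            g,
            begin=(L - (g.begin + g.length)) % L,
            orientation=REVERSE if g.orientation == FORWARD else FORWARD,
        )
        for g in genome.genes
    ]
    return Genome(genes, L, genome.sigma_basal)
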