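# Model and methods

`tscevo` simulates the evolution of bacterial genome organization under the
*transcription–supercoiling coupling* (TSC): the mutual feedback between gene
transcription and local DNA supercoiling. This note documents the model, its
parameters, the numerical choices, and what the synthetic study conditions do
and do not capture.

## Individual-level model

An individual is a single circular chromosome of `n` non-overlapping,
oriented, typed genes separated by non-coding intergenic segments. Genes carry
no sequence; only their relative positions and orientations matter. The
phenotype of an individual in an environment is the vector of equilibrium
expression levels `e`, defined as a fixed point of three coupled maps:

1. **Local supercoiling.** Following the twin-domain picture, a transcribing
   polymerase pushes positive supercoils ahead of itself and negative
   supercoils behind. The supercoiling felt at gene *i*'s promoter is

       sigma_i = sigma_basal + delta_sigma_env + sum_j (d sigma_i / d e_j) e_j

   with interaction coefficients

       d sigma_i / d e_j = eta * c * max(1 - d(i,j)/d_max, 0)

   where `d(i,j)` is the shortest circular distance from gene *i*'s promoter
   to gene *j*'s middle (the mean polymerase position), and the sign `eta`
   is +1 when *j* is upstream of *i* on the same strand or downstream on the
   opposite strand, −1 otherwise. Self-interaction is excluded (zero
   diagonal), and an exact antipodal tie (`d = L/2`) is defined to contribute
   0 — unreachable at the default parameters, but it makes toy genomes
   well-defined.

2. **Promoter opening.** Negative supercoiling favors strand opening; the
   opening free energy is a sigmoid of the local supercoiling,
   `U_i = 1 / (1 + exp((sigma_i - sigma_half)/epsilon))`.

3. **Expression.** `e_i = exp(m (U_i - 1))`, spanning `[exp(-m), 1]`.

A gene is *activated* when its expression strictly exceeds the midpoint
`e_half = (exp(-m) + 1)/2`. A knockout pins a gene's transcription rate to
exactly 0 — below the physical floor `exp(-m)` — so it generates no
supercoiling while the genome's geometry is untouched.

## Parameters

| parameter | symbol-free name | default | notes |
|---|---|---|---|
| `gene_length` | gene length (bp) | 1000 | typical bacterial ORF scale |
| `intergene` | initial intergenic distance (bp) | 125 | founder genomes are equally spaced |
| `n_genes_per_type` | genes per type | 20 | 60 genes total; L = 67.5 kb |
| `c` | torsional drag coefficient | 0.03 | sets the TSC magnitude comparable to the environmental shifts |
| `d_max` | supercoiling transmission distance (bp) | 5000 | linear decay to zero |
| `sigma_basal` | basal supercoiling | −0.066 | negatively supercoiled, *E. coli*-like |
| `sigma_half` | promoter opening threshold | −0.042 | sigmoid midpoint |
| `epsilon` | opening sensitivity | 0.005 | sigmoid width |
| `m` | inverse effective thermal energy | 2.5 | expression floor exp(−2.5) ≈ 0.082 |
| `delta_sigma_A/B` | environment shifts | +0.01 / −0.01 | A relaxes DNA, B adds negative supercoiling |
| `k_selection` | selection intensity | 50 | see below |
| `lam` | inversions per offspring (Poisson) | 2 | |
| `pop_size` | population size N | 100 | |

`k_selection` has no canonical literature value; 50 was chosen once so that
typical founder gaps (g ≈ 0.5–1.2) map to strong but not instantly fixing
fitness differences (`f = exp(-k g)`), and it is exposed in every config.

## Evolutionary loop

Non-overlapping generations: evaluate every genome in both environments,
compute the gap `g` (summed squared distance between per-type mean expression
and its target: 1 for types that must be on, `exp(-m)` for types that must be
off), draw N parents proportionally to `f = exp(-k g)` with replacement, and
mutate each offspring with K ~ Poisson(lam) genomic inversions. Inversions
draw both breakpoints uniformly per-bp over the intergenic positions (longer
intergenes receive proportionally more breakpoints; both endpoints in one
intergene is allowed and neutral), so genes are never split; the inverted
segment is the non-wrapping arc, which is without loss of generality because
this distance-and-orientation model is invariant under rotation and
reflection. One seeded generator per replicate drives all randomness in a
fixed order (selection indices, then each offspring's inversion count and
breakpoints), making runs bit-reproducible, checkpointable, and resumable.

The best-individual log records the *evaluated parents* of each generation;
the final generation's individuals are evaluated once more so the log has
`n_generations + 1` rows.

## Fixed-point solver

The expression equilibrium is computed by synchronous substitution
`e <- F(e)` from the uniform start `e = e_half`, with convergence declared
when the max-norm residual `|F(e) - e|` falls below `solver_tol = 1e-10`.
Two practical issues shape the implementation:

- **Oscillation.** Near the activation threshold the map's local gain
  `|dF/de|` can exceed 1 (up to `c · m / (4 epsilon)` per interacting pair),
  and the undamped synchronous map often locks into a stable period-2 cycle
  instead of converging — for roughly half of *random* 60-gene genomes in the
  negatively supercoiled environment. The solver therefore retries
  deterministically along a damping ladder (1, 0.5, 0.25, …, 0.005), each
  attempt restarted from `e_half` with an iteration budget that scales with
  1/damping. A point accepted at any damping satisfies the *undamped*
  residual criterion, so it is a genuine fixed point of the original system;
  damping only selects the path, not the equations.
- **Slow tails.** Once the residual shrinks steadily, or is already small,
  the remaining geometric tail is collapsed by a Newton polish on
  `F(e) - e = 0` started from the current iterate. The polish is accepted
  only if it converges within a small step bound and lands close to the
  iterate (max-norm < 0.1), i.e. inside the basin the iteration had already
  entered; otherwise plain iteration continues. Attempts that stagnate
  (period-2 lock-in, or no residual improvement over ~100 iterations) abort
  early and fall through to the next damping.

With several stable fixed points possible (convergent gene pairs are
bistable toggles), the phenotype is *defined* as the point this deterministic
procedure reaches from `e_half`. On small systems (n ≤ 5), damped iteration
from many random starting vectors empirically reaches the same point (tested;
disagreements would be reported by the suite, not silenced). If no damping
converges, the state is returned with `converged=False` and a
`ConvergenceWarning` — never silently.

The same solver runs all analyses; the evolutionary loop calls a batched,
numba-compiled version of it (plus a batched interaction-matrix builder and an
array-based inversion kernel) whose semantics are checked against the plain
path in the test suite.

## Analyses

- **Pair census**: every adjacent pair on the circle yields two oriented
  records (each gene once as focal), classified as convergent, divergent,
  focal-upstream or focal-downstream; supercoiling contributions are the
  equilibrium `(d sigma_target / d e_focal) * e_focal`, summed per
  (focal type, target type, environment) and split by sign.
- **Triplet census**: each of the n consecutive triples maps to a canonical
  class — reverse the triple and flip all orientations when the central gene
  is on the reverse strand — quotienting the 216 raw (type, orientation)
  classes to 108.
- **Minimal subnetworks**: for odd k, the k genes centered on a focal gene
  are re-evaluated as a *linear* arrangement that preserves the original arc
  distances (no wrap-around interactions; circularizing the excerpt would
  create couplings absent from the genome). The reported size is the
  smallest odd k < n whose central activation state matches the full genome,
  or n if none does (the full circular genome trivially matches).
- **Knockout graph**: knocking out each gene in turn adds an edge to every
  gene whose activation state switches in either environment; a pair
  switched in both environments keeps one edge, labelled `mixed` if the
  directions disagree. Connectivity statistics (weakly connected components,
  in/out degrees by type) ignore labels.
- **Environment sweep**: equilibrium per-type mean expression over a grid of
  supercoiling shifts (default −0.02 … +0.02 in 0.001 steps), with the
  closed-form isolated-gene response and a random-genome average as
  baselines.

## Study conditions and scaling

The synthetic study conditions follow the defaults above: populations of 100
individuals with 60 genes (20 per type), two environments at ±0.01, λ = 2.
The reference campaign for the full phenomenon is 30 populations × 10^6
generations; the bundled tests and the acceptance script run scaled-down
versions (5 × 1500 and 3 × 2500 generations respectively), which demonstrate
the *direction* of adaptation — rising fitness, activation counts moving
toward their targets, evolved knockout graphs denser than random ones — but
not the fully converged end-state statistics (near-complete activation
patterns, single whole-genome connected components, the detailed census
enrichments). Conclusions about those end states require the full campaign,
which the engine supports unchanged via configuration.

What the generator does not emulate: real promoter diversity (all genes share
one response curve; the stored per-gene basal expression level is carried in
the genome schema but enters no equation), topological barriers and
topoisomerase dynamics, transcriptional read-through, stochastic expression
noise, and any mutation other than inversions (gene gain/loss is taken to be
lethal).

## Known limitations

- The fixed-point phenotype definition is algorithmic; a different iteration
  scheme could, for bistable arrangements, select the other branch. All
  results in this package are defined relative to the documented scheme.
- Genuinely non-convergent systems (limit cycles of the underlying dynamics)
  are flagged, and their last iterate is used for fitness; at the default
  parameters this occurs in a small fraction of *random* genomes' solves at
  the deepest damping rungs and vanishes in evolved lineages, but it is a
  model boundary, not a solved case.
- Distances use promoter-to-gene-middle geometry; genes are points of
  polymerase activity, not extended occupancy profiles.
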