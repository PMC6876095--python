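# Methods

## Overview

`probpfp` builds a protein multiple sequence alignment in three phases:
(1) estimate, for every sequence pair, the posterior probability that
residue i of one sequence pairs with residue j of the other, using two
independent models — an affine-gap partition function and a pair hidden
Markov model trained by particle swarm optimisation; (2) fuse the two
estimates by their root mean square; (3) feed the fused posteriors into a
standard consistency/progressive stack: maximal-expected-accuracy (MEA)
pairwise scores, a distance matrix, a UPGMA guide tree with
ClustalW-style weights, a probabilistic consistency transformation,
profile–profile alignment along the tree, and random-bipartition
refinement.

## Partition-function posteriors

An alignment *l* of sequences x, y is scored A(l) by BLOSUM62 with affine
gap penalties; its Boltzmann weight is e^{A(l)/T}. The alignment space is
the set of all global alignment column sequences over {match, gap-in-y,
gap-in-x}; adjacent mutual gaps in either order are distinct alignments
and are included (the enumeration oracle in the test suite fixes this
convention, and the dynamic program matches it). A maximal gap run in one
sequence costs open + (len−1)·extend; switching gap direction re-opens.

Because a single prefix/suffix partition value is ambiguous under affine
gaps, the recursion keeps three state-resolved matrices (last column =
match / gap-in-y / gap-in-x), forward over prefixes and mirrored over
suffixes. The match posterior is

    P^b(i,j) = Z_prefix(i−1,j−1) · e^{s(x_i,y_j)/T} · Z_suffix(i+1,j+1) / Z,

with prefix and suffix factors summed over their three end states. This
is exact: an alignment containing the match (i,j) decomposes uniquely
into a prefix alignment, the match column, and a suffix alignment, and
gap runs never span a match column.

Parameters: T = 5 (score units per thermal unit), gap open −11, extend
−1, BLOSUM62. The matrix and penalties are the single documented scoring
set used throughout the package (they also score the sum-of-pairs
fitness); T = 5 is of the order of the log-odds scale of BLOSUM62
half-bits and is exposed in the configuration, as are the penalties.

## Pair-HMM posteriors

Three states: M emits an aligned residue pair, X emits a residue of x
against a gap, Y one of y. Transitions: M→(M,X,Y) = (1−2δ, δ, δ);
X→(X,M) = (ε, 1−ε); Y symmetric. Direct X↔Y transitions are forbidden
(the simplest topology in which gap open and extend are the only two gap
penalties), so alignments with adjacent mutual gaps are outside this
model's path set — one of the ways the HMM and partition-function views
genuinely differ before fusion. There is no explicit begin/end state:
the initial distribution (π_M, π_X, π_Y), with π_X = π_Y = (1−π_M)/2,
plays the begin role, and paths terminate after both sequences are fully
emitted, with no end factor. The Forward/Backward recursions and the
exhaustive path-enumeration oracle in the tests share these conventions
exactly.

Emissions are fixed, not trained: the joint match table inverts the
BLOSUM62 log-odds relation, p(a,b) ∝ q(a) q(b) 2^{s(a,b)/2}, against an
embedded published background frequency set q, renormalised; the single
emission q is the marginal of p, so the two tables are consistent. The
ambiguity placeholder X is a 21st letter with a small nominal background
mass. Training emissions would require far more signal than one input
family provides; the gap geometry (δ, ε) and π_M are what the swarm can
usefully fit.

## Particle swarm training

Positions are θ = (δ, ε, π_M) in the box δ ∈ [1e−4, 0.3],
ε ∈ [1e−4, 0.9], π_M ∈ [0.1, 1−1e−4] (bounds keep every transition row a
strictly positive distribution with margin). Updates are the canonical

    v' = w v + f1 r1 (p_best − x) + f2 r2 (g_best − x),   x' = x + v',

with w = 0.729 and f1 = f2 = 1.49445 — the constriction-equivalent
setting with well-studied convergence — and fresh r1, r2 ~ U[0,1] per
particle, per iteration, per component. Walls are absorbing: positions
clamp to the box and the clamped velocity component is zeroed. Defaults:
10 particles, 30 iterations.

Fitness of a position is the summed sum-of-pairs score (BLOSUM62,
open −11, extend −1) of the MEA pairwise alignments induced by the
resulting HMM posteriors. Pairwise fitness — rather than a full
progressive alignment per particle — keeps one evaluation at
O(n² L²); on families with more than 10 pairs, 10 pairs are subsampled
once, deterministically from the run's seed. Initial positions are
uniform in the box, initial velocities uniform within ±10% of each
component's span. The initial positions are evaluated before the first
move, so a zero-iteration run returns the best random start, and the
global-best trace (one value per iteration) is non-decreasing by
construction.

## Fusion, distances, guide tree

Fusion is entrywise root mean square, P = sqrt((P^a² + P^b²)/2), which
lies between min and max of its inputs and equals them when they agree.
Entries below 0.01 are then zeroed (sparsity cutoff, configurable).
MEA alignment maximises A(i,j) = max(A(i−1,j−1) + P(i,j), A(i−1,j),
A(i,j−1)); GS = A(|x|,|y|) is the expected number of correctly matched
residues, so dis(x,y) = 1 − GS/min(|x|,|y|) lies in [0,1] and is 0 for
identical sequences with confident posteriors.

UPGMA merges the closest pair of clusters; the merged-to-other distance
is the size-weighted average (|N_i| d_il + |N_j| d_jl)/(|N_i|+|N_j|),
which the tests verify equals the direct mean over all cross-cluster
leaf pairs at every step. Merge height is half the merge distance
(ultrametric output). A leaf's weight is the sum over its root-to-leaf
path of branch length divided by the number of leaves below that branch,
normalised to mean 1; an all-zero-height tree (identical sequences)
falls back to uniform weights.

## Consistency transformation and progressive alignment

One pass (configurable) of P'_xy = Σ_z w_z (P_xz P_zy) / Σ_z w_z over
all sequences z, with P_xx the identity — so with two sequences the
transform is the identity. Entries below the cutoff are re-zeroed after
each pass.

Profile columns are scored by the weighted mean transformed posterior
over all row pairs; a gapped row contributes zero to the numerator but
its weight pair still counts in the denominator (the literal reading of
the mean over all row pairs; renormalising over ungapped pairs only is
available behind the `gap_renorm` flag). Gap moves in the profile DP
score zero, as in the pairwise MEA recursion. Profiles merge along the
guide tree in post-order; output rows are restored to input order.

Refinement: each iteration splits the rows into two non-empty groups by
fair coin flips (re-drawn until both groups are non-empty), strips
all-gap columns from each sub-profile, re-aligns the two profiles, and
keeps the result only if its sum-of-pairs score is at least the current
one — so refinement never lowers SoP. Ten iterations by default; the
keep-if-not-worse rule can be disabled (`refine_accept_all`) to accept
every re-alignment. Re-scoring uses SoP rather than the posterior-based
GS so that refinement optimises the same objective the swarm does.

## Sum-of-pairs and SP/TC conventions

SoP projects each row pair, deletes columns gapped in both rows, scores
residue–residue columns by the matrix, and charges open for the first
column of each gap run in the projection and extend for the rest.
Terminal gaps pay the same penalties as internal ones (simplest
consistent convention; nothing in the score definition distinguishes
run position). SP counts reference residue–residue pairs reproduced in
the test alignment; TC counts fully gap-free reference columns
reproduced as identical residue-index tuples. Vacuous denominators (a
reference with no residue pairs, or no gap-free columns) score 1.0, so
an alignment always scores (1,1) against itself.

## Synthetic families

The simulator draws an ancestor from the background frequencies and
evolves each descendant independently: per surviving site, substitution
with probability `p_sub`, the replacement drawn from the
BLOSUM62-derived conditional p(b|a) excluding b = a (so the realised
substitution fraction matches `p_sub`); per site, an indel event with
probability `p_indel`, equally likely insertion or deletion, geometric
length with mean `mean_indel` (default 2). The edit histories imply a
true alignment: one column per surviving ancestor site plus private
insertion columns — insertions from different descendants are never
stacked, since they are not homologous. Reference conditions used by the
acceptance script and the end-to-end test: 8 sequences, ancestral length
120, 10% substitution, 2% indel — a moderately diverged, star-like
family whose sequences remain clearly alignable.

What this does and does not show: descendants are independent draws from
a single ancestor (a star phylogeny), so the benchmark probes posterior
quality, tree construction, consistency and refinement on realistic
divergence levels, but not deep hierarchical structure, domain
shuffling, long terminal extensions, repeats or compositional bias found
in curated structural benchmarks. Accuracy numbers on these families are
therefore upper-end estimates, not predictions for hard real-world sets.

## Numerical choices

- All partition-function and HMM lattices run in log space with explicit
  log-sum-exp, compiled with numba; no overflow for any realistic length.
- Forward and reverse (or backward) totals are cross-checked at
  tolerance 1e−6 (partition) / 1e−9 (HMM) relative, warning on
  disagreement; posteriors are clamped to [0,1] after exponentiation.
- Posterior row sums may exceed 1 only by numerical noise; violations
  beyond 1e−6 log a warning rather than raising (clamping can in
  principle push sums past the analytic bound).
- Traceback ties prefer the diagonal, then advancing the first sequence,
  then the second — all discrete outputs are deterministic.
- UPGMA ties break toward the lowest cluster-index pair in creation
  order.
- All randomness (swarm initialisation, r1/r2, pair subsampling,
  refinement splits, simulation) flows from one seed via independent
  spawned streams; identical seeds give byte-identical output FASTA.

## Known limitations

- O(L²) dense posterior matrices per pair and O(n²) pairs: intended for
  families of tens of sequences of ordinary protein length, not
  thousands of sequences or very long sequences (no banding).
- The pair-HMM shares one (δ, ε, π_M) for the whole family; strongly
  heterogeneous families might benefit from per-pair parameters.
- Emission tables are fixed to the BLOSUM62 inversion; no local or
  double-affine HMM variants.
- The swarm optimises a non-convex objective from random starts; the
  seed is part of the result's definition. With the default budget the
  trace typically plateaus early on easy families.
- Guide trees are UPGMA-only (no neighbour joining), and sequence
  weights are the single ClustalW-style scheme used for both the
  consistency transform and profile scoring.
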