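# Methods

## Gene-order profiles

A genome is reduced to its *gene-order profile*: the sequence of gene-family
labels of its protein-coding genes in ascending start-coordinate order
(ties broken by end coordinate, then gene id), with an optional parallel
strand vector and a circularity flag. Coordinates are 1-based inclusive
(GFF3 convention); the TSV dialect mirrors it. Genes spanning the origin of
a circular chromosome (end < start) are placed by their start coordinate —
a deterministic rule for a rare situation.

Family labels come from HMM searches of gene products against a family
database (pVOGs in the intended application). Each gene takes the hit with
the smallest E-value below the cutoff (default 1e-2); ties prefer the larger
bit score, then the lexicographically smallest family id, so assignment is
reproducible for any input ordering. Genes without a passing hit receive a
unique per-gene label `ORFAN:<genome>:<gene>`. Uniqueness matters: two
unannotated genes should never count as a match during alignment. A flag
(`include_orfans=False` in `assign_families`) drops unassigned genes from
profiles instead, since it is equally defensible to exclude them; including
them as singletons is the default because it preserves spacing information
(an unmatched gene still displaces its neighbours).

Core families are the exact intersection of per-genome family sets with
ORFAN singletons excluded; the result is sorted and shrinks monotonically as
genomes are added.

## Substitution matrix

Profile–profile comparison tools report directed query→target scores. The
substitution matrix entry for families i, j is the average of the two
reciprocal hits, with a missing direction counted as zero — this makes the
matrix exactly symmetric by construction and conservative for one-sided
hits. Families without a self-hit get their diagonal set to the row maximum
(or 1 if the row is empty) so every self-score is strictly positive, which
the distance formula requires. Raw scores are used untransformed; which
statistic of the upstream tool is used (raw score, probability, −log E) is
left to the column-mapping configuration, and all downstream distances are
invariant to a global rescaling of the matrix because the default gap
penalty is matrix-relative (below).

When a profile contains labels absent from the matrix (typically ORFANs),
the matrix is auto-extended: new labels get off-diagonal 0 and a diagonal
equal to the median self-score of the known families, letting unassigned
genes match only themselves without dominating the score. Auto-extension
can be disabled, in which case an unknown label raises an error naming it.

## Alignment and distance

The aligner is a semiglobal (free-end-gap) dynamic program over the two
label sequences: leading and trailing gaps on both sequences are free, each
internal gap position costs `gap_penalty`, and every aligned label pair
scores its matrix entry (pairs absent from the matrix score 0, never
negative — the matrix holds similarities, not penalties). The default gap
penalty is half the median diagonal of the substitution matrix: skipping
two genes then costs about one average match, and distances are unchanged
if all scores are rescaled.

To absorb the arbitrary cut point of circular assemblies, the optimal score
is maximized over all rotations of the second profile, and over the
reversed label order (antisense) when enabled; strand labels are not
consulted — only gene order carries signal here. Ties prefer the smallest
rotation offset, then sense over antisense; the traceback prefers diagonal
moves, then a gap in the second sequence, to make reported alignments
unique. The search is implemented as a batched row-vectorized DP across all
rotation/orientation candidates; the winning configuration is then re-run
with an explicit traceback so the reported score, aligned pairs and
internal-gap count are mutually consistent (the invariant
`score = Σ pair scores − gap_penalty × internal gaps` is tested). Winner
selection requires an improvement greater than 1e-12 so floating-point
noise cannot override the deterministic tie-break.

A subtlety the design had to confront: a semiglobal score is *not*
invariant to the linearization of the sequence whose rotations are not
searched — in random trials about 40 % of circular pairs change score when
only the first genome's cut point moves. Searching rotations of both
genomes would fix this at quadratic cost in rotations; instead the distance
canonicalizes each circular profile to its lexicographically least rotation
(over both reading directions when the antisense search is on) before
aligning. Rotation and reversal invariance of the distance are then exact
by construction, at negligible cost, while `best_score` itself keeps plain
fixed-first-argument semantics with the rotation offset reported relative
to the second input.

The distance is `D_AB = 1 − (G_AB + G_BA)/(G_AA + G_BB)`, with `G_AB` and
`G_BA` computed as two independent searches and symmetrized by the formula.
Zero self-score is an error (degenerate profile). With similarity-style
matrices `D` lies in [0, 1]; exotic matrices (cross-scores exceeding
self-scores) could push it outside, in which case it is clamped with a
warning rather than raising — such matrices are legal inputs, and a clamped
distance is still usable for tree building.

## Trees

BioNJ (the variance-weighted neighbor-joining variant) is implemented
directly: the classical NJ selection criterion
`Q(i,j) = (r−2)·d(i,j) − S_i − S_j` chooses the pair to agglomerate, branch
lengths follow the standard NJ estimates, and the matrix reduction weights
the two merged rows by `λ = 1/2 + Σ_k(v_jk − v_ik) / (2(r−2)v_ij)` (clamped
to [0, 1]; 1/2 when the pair variance is zero), where the variance matrix
is initialized to the distances and reduced alongside them. For any additive
matrix every λ preserves additivity, so BioNJ recovers topology *and*
branch lengths exactly — a property the tests exercise on random additive
matrices up to 12 leaves. Negative branch-length estimates are zeroed with
the deficit transferred to the sister branch (preserving path lengths
through the joined node); the raw estimates still drive the matrix
reduction. Selection ties are broken by the lexicographically smallest pair
of subtree labels, for reproducibility. The final three nodes are joined by
the closed-form three-point formulas.

Rooting places the root at the midpoint of the outgroup's pendant edge
(the application this package serves roots everything at a designated
distant outlier genome); the unrooted topology is unchanged and the
operation round-trips.

Robinson–Foulds distance counts non-trivial bipartitions present in exactly
one tree. Bipartitions are canonicalized as the side not containing the
lexicographically smallest leaf, so rooted and unrooted inputs compare
consistently. The normalized form divides by the total number of
non-trivial bipartitions across both trees — this reads directly as "the
fraction of partitions present in only one tree" and remains well defined
for multifurcating trees; dividing by the binary maximum `2(n−3)` is
available via `denominator="max"`. Two star trees are identical, so their
normalized distance is defined as 0.

## Simulation model

`EvolutionConfig` fixes the generative conditions. A root profile of
`genome_length` distinct families (drawn from a pool of `n_families`)
evolves along a tree; each branch receives `Poisson(total_rate × length)`
events drawn from the event mix and applied sequentially. Defaults:

| parameter | default | rationale |
|---|---|---|
| `genome_length` | 100 genes | large tailed phages carry roughly 200 ORFs; 100 keeps the same regime (events are local relative to genome size) at desk-scale cost |
| `n_families` | 500 | pool comfortably larger than a genome so root profiles have distinct labels |
| `inversion_rate` | 0.4 | inversions dominate observed gene-order differences between close relatives |
| `transposition_rate` | 0.2 | segment excision/reinsertion, span up to genome/3 |
| `loss_rate` / `gain_rate` | 0.15 / 0.15 | single-gene indels; gains always draw fresh labels so homoplasy cannot occur |
| `rotation_rate` | 0.1 | origin shifts — a nuisance process the aligner must be invariant to |
| `inversion_span` | 2–10 genes | local rearrangements; a whole-genome inversion is separately testable and is invisible to the antisense-searching aligner |

The rates sum to 1.0, so a branch length is the expected number of events
on that branch. One `numpy` RNG stream keyed by the seed drives everything;
event logs are recorded and can be replayed exactly.

What the simulator does *not* emulate: sequence-level divergence (family
assignment is taken as error-free), annotation noise (missed or split
genes), family-similarity structure (synthetic matrices are identity-like
with optional sub-diagonal noise rather than reflecting real HMM–HMM score
distributions), horizontal transfer between lineages, and convergent
rearrangement. Passing tests therefore demonstrate the correctness and
invariances of the algorithms under a clean rearrangement process, not the
robustness of the method to real annotation and homology-detection error.

## Numerical and testing notes

* All DP scores are nonnegative, so the semiglobal table is nonnegative and
  the row-vectorized prefix-max recurrence is exact; traceback comparisons
  use a 1e-9 absolute tolerance against the recomputed cell values.
* The aligner's reference oracle in the test suite is a deliberately
  different algorithm — exhaustive monotone match chaining in O(n²m²) —
  so DP and oracle cannot share a bug; oracle-agreement tests draw matrix
  entries from a 0.25 grid, making both routes float-exact and the
  comparison literal equality.
* Interval coverage for Dice/SI uses an identity-weighted sweep over merged
  intervals (each covered position contributes the maximum fractional
  identity of the hits covering it); minus-strand coordinates are
  normalized to ascending before merging. The exact aggregation formulas of
  the upstream tools this mirrors are not published, so these definitions
  are the documented, tested interpretation and both scores are pluggable.
* Demarcation uses single linkage (connected components of the
  ">threshold" graph): it is the only linkage under which "similarity above
  X %" edges are transitive into clusters, and it makes partitions nest as
  the threshold rises. Cluster labels are the lexicographically smallest
  member id.
* Test and acceptance problem sizes (profiles of 8–30 genes for exhaustive
  oracles, 100 genes for simulations; 20-replicate recovery runs; 50
  additive matrices) were chosen so exhaustive enumeration stays exact and
  full runs complete in minutes on a single core.

## Known limitations

* Gap costs are linear (no affine opening/extension distinction) and local
  alignment is out of scope.
* Topology recovery from gene-order distances degrades at *both* ends of
  the rearrangement-rate scale: at high rates distances saturate, and at
  low rates (expected events per branch well below 1) many internal
  branches receive no events at all, so their bipartitions are
  unrecoverable in principle — a Poisson(0.5) branch is silent with
  probability 0.61. Simulation studies with this package should choose
  rates high enough that every internal branch is likely to be hit.
* The BioNJ implementation targets matrices up to a few hundred taxa
  (dense O(n³) agglomeration); it is not optimized for very large trees.
* Dice/SI values are faithful to the documented interval-union definitions
  but are not claimed to reproduce any specific external tool's internal
  fragmentation heuristics numerically.
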