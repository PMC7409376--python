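# goatalign

Gene-order (synteny) alignment distances, BioNJ trees and genome-similarity
demarcation for comparative genomics of tailed bacteriophages.

Phage genomes are mosaic: horizontal transfer, divergent mutation rates and
frequent rearrangement erase most of the sequence-level signal above the
genus rank. What often survives is the *order* of genes along the (usually
circular) chromosome. `goatalign` turns each genome into a gene-order
profile — the sequence of gene-family labels (e.g. pVOG assignments) in
chromosomal order — and compares profiles with a semiglobal dynamic-
programming alignment that is searched over every circular rotation and both
reading directions, so that arbitrary assembly cut points and whole-genome
inversions do not register as differences. Family-vs-family substitution
scores (averaged reciprocal profile–profile hit scores) let diverged but
homologous families still align.

The optimal alignment score `G_AB` between genomes A and B becomes a
distance

```
D_AB = 1 − (G_AB + G_BA) / (G_AA + G_BB)
```

where `G_AA`, `G_BB` are the self-alignment scores. `D` is 0 for identical
gene orders, symmetric, and (for identity-like substitution matrices) at
most 1. Distance matrices are converted to trees with BioNJ, the
variance-weighted neighbor-joining variant, and tree topologies are compared
with the normalized Robinson–Foulds metric (fraction of non-trivial
bipartitions present in only one tree).

Around this core the package provides:

* **Profiles** — GFF3 / TSV annotation readers, HMM-hit family assignment
  (best E-value under a cutoff, default 1e-2), per-gene `ORFAN` labels for
  unassigned genes, and core-family identification (families shared by every
  genome in a set).
* **Genome similarity** — Dice and symmetrical-identity (SI) percent scores
  aggregated from standard 12-column alignment hit tables
  (identity-weighted merged intervals; translated-hit filters ≥30 %
  identity, ≥30 aa, E ≤ 0.01), and single-linkage taxon demarcation at rank
  thresholds (species >95 % nucleotide identity, genus >50 % SI, subfamily
  ≈25 % translated SI).
* **Simulation** — a seedable generator that evolves gene-order profiles
  along a tree by inversions, transpositions, gene loss/gain and origin
  rotations, with replayable event logs, so every stage can be tested
  against known ground truth.

## Worked example

Simulate four genomes along a known tree, compute gene-order distances, and
rebuild the phylogeny:

```python
from goatalign import (EvolutionConfig, balanced_tree, evolve_along_tree,
                       FamilySimilarityMatrix, distance_matrix, bionj,
                       robinson_foulds)

cfg = EvolutionConfig(seed=7, genome_length=30, n_families=200)
tree = balanced_tree(4, branch_length=2.0)      # ~2 expected events/branch
rng = cfg.rng()
leaves, true_tree, logs = evolve_along_tree(tree, cfg, rng=rng)

labels = sorted({f for p in leaves.values() for f in p.families})
m = FamilySimilarityMatrix.identity(labels)
dm = distance_matrix(list(leaves.values()), m)
print(dm.to_data_frame().round(3))
print("normalized RF vs truth:", robinson_foulds(true_tree, bionj(dm)))
```

Output:

```
       L01    L02    L03    L04
L01  0.000  0.692  0.746  0.637
L02  0.692  0.000  0.779  0.710
L03  0.746  0.779  0.000  0.714
L04  0.637  0.710  0.714  0.000
normalized RF vs truth: 0.0
```

Each off-diagonal entry is the gene-order distance after searching all
rotations and both orientations: about 30 rearrangement/indel events
separate each pair here, so roughly 65–80 % of the optimal self-alignment
score is lost. BioNJ on this matrix reproduces the generating topology
exactly (normalized Robinson–Foulds 0).

The same pipeline is available from the shell:

```bash
goat simulate --leaves 8 --seed 5 --outdir sim/
goat distmat sim/profiles.tsv sim/similarity_matrix.tsv --out dist.tsv
goat tree dist.tsv --out est.nwk --outgroup L01
goat compare est.nwk sim/true_tree.nwk
goat demarcate similarity.tsv --rank genus
```

## Method documentation

See [docs/methods.md](docs/methods.md) for the model, parameter and
numerical-design details, what the simulator does and does not emulate, and
known limitations.
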