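"""Seedable simulation of gene-order evolution with known ground truth.

Profiles evolve along a tree under the rearrangement processes that shape
phage genomes: segmental inversions, transpositions, single-gene loss and
gain, and rotation of the linearization origin of a circular chromosome.
Event counts per branch are Poisson with mean ``total rate x branch
length``; with the default rates summing to one, a branch length is the
expected number of events on that branch.

Every generator is driven by one ``numpy.random.Generator`` stream keyed by
the config seed, so full runs are reproducible.  Gene gain always draws a
fresh label (``GAIN:<k>``), never a previously lost one, so convergent
re-acquisition (homoplasy) cannot occur by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .genomesim import BLAST_COLUMNS
from .profiles import GenomeProfile
from .simmatrix import FamilySimilarityMatrix


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of the gene-order evolution model.

    Rates are relative weights per branch-length unit.  The defaults sum to
    1.0, dominated by inversions (the rearrangement most often observed in
    closely related phage genomes), with origin rotation as a nuisance
    process the aligner should be invariant to.
    """

    n_families: int = 500
    genome_length: int = 100
    inversion_rate: float = 0.4
    transposition_rate: float = 0.2
    loss_rate: float = 0.15
    gain_rate: float = 0.15
    rotation_rate: float = 0.1
    inversion_span: tuple[int, int] = (2, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 2:
            raise ValueError("genome_length must be >= 2")
        rates = (self.inversion_rate, self.transposition_rate, self.loss_rate,
                 self.gain_rate, self.rotation_rate)
        if any(r < 0 for r in rates):
            raise ValueError("rates must be nonnegative")
        if sum(rates) <= 0:
            raise ValueError("at least one rate must be positive")
        lo, hi = self.inversion_span
        if not (1 <= lo <= hi):
            raise ValueError("invalid inversion_span")

    @property
    def total_rate(self) -> float:
        return (self.inversion_rate + self.transposition_rate + self.loss_rate
                + self.gain_rate + self.rotation_rate)

    def event_weights(self) -> tuple[list[str], np.ndarray]:
        kinds = ["inversion", "transposition", "loss", "gain", "rotation"]
        w = np.array([
            self.inversion_rate, self.transposition_rate, self.loss_rate,
            self.gain_rate, self.rotation_rate,
        ])
        return kinds, w / w.sum()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def random_profile(
    config: EvolutionConfig,
    rng: np.random.Generator | None = None,
    genome_id: str = "ancestor",
) -> GenomeProfile:
    """Circular root profile: ``genome_length`` distinct families sampled
    from a pool of ``n_families`` labels ``F0000..``, random strands."""
    if config.genome_length > config.n_families:
        raise ValueError("genome_length exceeds the family pool")
    rng = config.rng() if rng is None else rng
    pool = [f"F{i:04d}" for i in range(config.n_families)]
    picks = rng.choice(config.n_families, size=config.genome_length, replace=False)
    strands = rng.choice(["+", "-"], size=config.genome_length)
    return GenomeProfile(
        genome_id=genome_id,
        families=tuple(pool[i] for i in picks),
        strands=tuple(strands),
        circular=True,
    )


# ---------------------------------------------------------------------------
# events


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _apply_one(
    families: list[str], strands: list[str], event: dict
) -> tuple[list[str], list[str]]:
    kind = event["kind"]
    L = len(families)
    if kind == "inversion":
        s, span = event["start"], event["span"]
        idx = [(s + k) % L for k in range(span)]
        segment = [(families[i], strands[i]) for i in idx]
        for i, (fam, strand) in zip(idx, reversed(segment)):
            families[i] = fam
            strands[i] = _flip(strand)
    elif kind == "transposition":
        s, span, dest = event["start"], event["span"], event["dest"]
        idx = sorted(((s + k) % L for k in range(span)), reverse=True)
        seg = [(families[(s + k) % L], strands[(s + k) % L]) for k in range(span)]
        for i in idx:
            del families[i]
            del strands[i]
        at = dest % (len(families) + 1)
        for fam, strand in reversed(seg):
            families.insert(at, fam)
            strands.insert(at, strand)
    elif kind == "loss":
        i = event["pos"] % L
        del families[i]
        del strands[i]
    elif kind == "gain":
        at = event["pos"] % (L + 1)
        families.insert(at, event["family"])
        strands.insert(at, event["strand"])
    elif kind == "rotation":
        k = event["offset"] % L
        families[:] = families[k:] + families[:k]
        strands[:] = strands[k:] + strands[:k]
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    return families, strands


class _GainCounter:
    """Process-wide counter so gained labels are globally unique."""

    def __init__(self) -> None:
        self.n = 0

    def next_label(self) -> str:
        self.n += 1
        return f"GAIN:{self.n:05d}"


def _sample_event(
    rng: np.random.Generator, config: EvolutionConfig, L: int,
    gains: _GainCounter,
) -> dict:
    kinds, probs = config.event_weights()
    while True:
        kind = kinds[rng.choice(len(kinds), p=probs)]
        if kind in ("loss",) and L <= 2:
            continue  # never let the genome empty out
        break
    if kind == "inversion":
        lo, hi = config.inversion_span
        span = int(rng.integers(lo, min(hi, L) + 1)) if L > lo else max(L - 1, 1)
        return {"kind": kind, "start": int(rng.integers(L)), "span": span}
    if kind == "transposition":
        span = int(rng.integers(1, max(2, L // 3 + 1)))
        return {
            "kind": kind, "start": int(rng.integers(L)), "span": span,
            "dest": int(rng.integers(max(1, L - span + 1))),
        }
    if kind == "loss":
        return {"kind": kind, "pos": int(rng.integers(L))}
    if kind == "gain":
        return {
            "kind": kind, "pos": int(rng.integers(L + 1)),
            "family": gains.next_label(),
            "strand": str(rng.choice(["+", "-"])),
        }
    return {"kind": "rotation", "offset": int(rng.integers(1, L))}


def apply_events(
    profile: GenomeProfile,
    config: EvolutionConfig,
    n_events: int,
    rng: np.random.Generator | None = None,
    _gains: _GainCounter | None = None,
) -> tuple[GenomeProfile, list[dict]]:
    """Apply ``n_events`` sampled events sequentially; return the mutated
    profile and a replayable event log."""
    rng = config.rng() if rng is None else rng
    gains = _gains if _gains is not None else _GainCounter()
    families = list(profile.families)
    strands = list(profile.strands or ["+"] * len(profile))
    log: list[dict] = []
    for _ in range(n_events):
        event = _sample_event(rng, config, len(families), gains)
        _apply_one(families, strands, event)
        log.append(event)
    return (
        GenomeProfile(profile.genome_id, tuple(families), tuple(strands),
                      profile.circular),
        log,
    )


def replay_events(profile: GenomeProfile, log: Sequence[dict]) -> GenomeProfile:
    """Deterministically re-apply a recorded event log."""
    families = list(profile.families)
    strands = list(profile.strands or ["+"] * len(profile))
    for event in log:
        _apply_one(families, strands, event)
    return GenomeProfile(profile.genome_id, tuple(families), tuple(strands),
                         profile.circular)


# ---------------------------------------------------------------------------
# evolution along a tree


def evolve_along_tree(
    tree: TreeNode,
    config: EvolutionConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, GenomeProfile], TreeNode, dict[str, list[dict]]]:
    """Evolve a root profile down a tree with branch lengths.

    The number of events on each branch is Poisson with mean
    ``config.total_rate * branch_length``.  Returns leaf profiles keyed by
    leaf name, the generating tree, and the per-branch event logs keyed by
    the name of the child node (leaves only in the log keys for unnamed
    internals).
    """
    rng = config.rng() if rng is None else rng
    gains = _GainCounter()
    root_profile = random_profile(config, rng=rng, genome_id="root")
    leaves: dict[str, GenomeProfile] = {}
    logs: dict[str, list[dict]] = {}

    def descend(node: TreeNode, profile: GenomeProfile, path: str) -> None:
        for k, child in enumerate(node.children):
            length = child.length or 0.0
            n_events = int(rng.poisson(config.total_rate * length))
            name = child.name or f"{path}.{k}"
            mutated, log = apply_events(
                GenomeProfile(name, profile.families, profile.strands,
                              profile.circular),
                config, n_events, rng=rng, _gains=gains,
            )
            logs[name] = log
            if child.is_tip():
                leaves[name] = mutated
            else:
                descend(child, mutated, name)

    descend(tree, root_profile, "n")
    return leaves, tree, logs


def balanced_tree(n_leaves: int, branch_length: float = 1.0) -> TreeNode:
    """Fully balanced binary tree with uniform branch lengths; leaves are
    ``L01..``.  ``n_leaves`` must be a power of two."""
    if n_leaves < 2 or n_leaves & (n_leaves - 1):
        raise ValueError("n_leaves must be a power of two >= 2")
    counter = iter(range(1, n_leaves + 1))

    def build(k: int) -> TreeNode:
        if k == 1:
            node = TreeNode(name=f"L{next(counter):02d}")
        else:
            node = TreeNode(children=[build(k // 2), build(k // 2)])
        node.length = branch_length
        return node

    root = TreeNode(children=[build(n_leaves // 2), build(n_leaves // 2)])
    return root


def random_tree(
    leaf_names: Sequence[str],
    rng: np.random.Generator,
    min_length: float = 0.1,
    max_length: float = 1.0,
) -> TreeNode:
    """Random binary topology by sequential random joins, with uniform
    branch lengths in ``[min_length, max_length)``."""
    nodes = [TreeNode(name=n) for n in leaf_names]
    for node in nodes:
        node.length = float(rng.uniform(min_length, max_length))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(min_length, max_length))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return TreeNode(children=nodes)


# ---------------------------------------------------------------------------
# synthetic substitution matrices and hit tables


def synth_similarity_matrix(
    labels: Sequence[str],
    noise: float = 0.0,
    diag: float = 1.0,
    rng: np.random.Generator | None = None,
) -> FamilySimilarityMatrix:
    """Identity-like family matrix with optional symmetric off-diagonal
    noise drawn uniformly from ``[0, noise * diag)`` (strictly below the
    diagonal value)."""
    if not 0.0 <= noise < 1.0:
        raise ValueError("noise must be in [0, 1)")
    rng = np.random.default_rng(0) if rng is None else rng
    n = len(labels)
    scores = np.eye(n) * diag
    if noise > 0:
        off = rng.uniform(0.0, noise * diag, size=(n, n))
        off = np.triu(off, k=1)
        scores = scores + off + off.T
    return FamilySimilarityMatrix(list(labels), scores)


def planted_hit_tables(
    genome_a: str,
    genome_b: str,
    len_a: int,
    len_b: int,
    coverage_a: float,
    coverage_b: float,
    identity: float = 100.0,
    evalue: float = 1e-30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reciprocal single-interval hit tables with known coverage.

    Plants one hit covering the first ``round(coverage * len)`` positions of
    each query genome at the given percent identity, so Dice and SI values
    are known by construction:

        dice = 100 * (ca + cb) * identity/100 / (len_a + len_b)
        si   = 50 * (ca/len_a + cb/len_b) * identity/100

    with ``ca = round(coverage_a * len_a)`` etc.
    """

    def table(q, s, qlen, cov):
        span = int(round(cov * qlen))
        if span <= 0:
            return pd.DataFrame(columns=BLAST_COLUMNS)
        row = {
            "qseqid": q, "sseqid": s, "pident": identity, "length": span,
            "mismatch": 0, "gapopen": 0, "qstart": 1, "qend": span,
            "sstart": 1, "send": span, "evalue": evalue, "bitscore": 2.0 * span,
        }
        return pd.DataFrame([row], columns=BLAST_COLUMNS)

    return (
        table(genome_a, genome_b, len_a, coverage_a),
        table(genome_b, genome_a, len_b, coverage_b),
    )


def write_event_logs(logs: dict[str, list[dict]], path) -> None:
    """Event logs as JSON lines: one object per branch event."""
    with open(path, "w") as fh:
        for branch, events in logs.items():
            for k, event in enumerate(events):
                fh.write(json.dumps({"branch": branch, "index": k, **event}) + "\n")
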