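"""Gene-order alignment: semiglobal DP over rotations and orientations.

The score between two genomes is the optimal semiglobal (free-end-gap)
alignment of their gene-family sequences, scored by a family-vs-family
substitution matrix, maximized over every circular rotation of the second
genome and over both reading directions.  Rotation search absorbs the
arbitrary cut point introduced when a circular genome is linearized during
assembly; the antisense search absorbs whole-genome inversions and
strand-of-deposit differences.

The score G_AB for genomes A and B is converted to a distance

    D_AB = 1 - (G_AB + G_BA) / (G_AA + G_BB)

where G_AA and G_BB are the self-alignment scores.  D is symmetric, zero for
identical gene orders, and (for identity-like matrices) at most one.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skbio import DistanceMatrix

from .profiles import GenomeProfile
from .simmatrix import FamilySimilarityMatrix

logger = logging.getLogger(__name__)

SENSE = "sense"
ANTISENSE = "antisense"

#: Numerical slack when comparing candidate scores during the
#: rotation/orientation search; ties at this resolution keep the earlier
#: (smaller offset, sense-first) candidate.
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class AlignmentParams:
    """Tuning knobs of the gene-order aligner.

    gap_penalty
        Cost per internal gap position (end gaps are free).  ``None`` means
        half the median diagonal of the substitution matrix, which keeps
        distances invariant under rescaling of the matrix.
    search_rotations
        Try every circular rotation of the second profile (only applies when
        that profile is circular).
    search_antisense
        Also try the second profile read in reverse order.
    """

    gap_penalty: float | None = None
    free_end_gaps: bool = True
    search_rotations: bool = True
    search_antisense: bool = True

    def __post_init__(self) -> None:
        if self.gap_penalty is not None and self.gap_penalty < 0:
            raise ValueError("gap_penalty must be nonnegative")
        if not self.free_end_gaps:
            raise ValueError("only semiglobal (free end gap) alignment is supported")

    def resolve_gap(self, matrix: FamilySimilarityMatrix) -> float:
        if self.gap_penalty is not None:
            return float(self.gap_penalty)
        return 0.5 * matrix.median_diagonal()


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal alignment score with the configuration achieving it.

    ``aligned_pairs`` holds 0-based (position_in_a, position_in_b) index
    pairs; ``position_in_b`` refers to the original (unrotated, sense)
    coordinates of the second profile.
    """

    score: float
    rotation_offset: int = 0
    orientation: str = SENSE
    aligned_pairs: tuple[tuple[int, int], ...] = ()
    n_internal_gaps: int = 0


class MissingLabelError(KeyError):
    """A profile label is absent from the substitution matrix."""


def _require_labels(
    m: FamilySimilarityMatrix, profiles: Iterable[GenomeProfile],
    auto_extend: bool,
) -> FamilySimilarityMatrix:
    profiles = list(profiles)
    if auto_extend:
        return m.extended(profiles)
    for prof in profiles:
        for lab in prof.families:
            if lab not in m:
                raise MissingLabelError(
                    f"label {lab!r} (genome {prof.genome_id}) missing from "
                    "substitution matrix"
                )
    return m


def _score_grid(S: np.ndarray, gap: float) -> np.ndarray:
    """Semiglobal DP table for a precomputed pair-score matrix ``S``.

    Row-vectorized: the horizontal (gap-in-a) chain within a row is resolved
    with a prefix max over ``T + gap*j``.  All entries of ``S`` are
    nonnegative, so every cell is >= 0 and the chain never needs to fall back
    below the diagonal candidate.
    """
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    if m == 0 or n == 0:
        return H
    ar = np.arange(m)
    gar = gap * ar
    for i in range(1, n + 1):
        T = np.maximum(H[i - 1, :-1] + S[i - 1], H[i - 1, 1:] - gap)
        H[i, 1:] = np.maximum.accumulate(T + gar) - gar
    return H


def _best_cell(H: np.ndarray) -> tuple[float, int, int]:
    """Max over last row and last column (free trailing gaps).

    Deterministic tie-break: prefer the cell consuming more of both
    sequences (larger i+j), then the last-column candidate.
    """
    n = H.shape[0] - 1
    m = H.shape[1] - 1
    jb = int(np.argmax(H[n, :]))
    ib = int(np.argmax(H[:, m]))
    best_row = (H[n, jb], n + jb, 0, n, jb)
    best_col = (H[ib, m], ib + m, 1, ib, m)
    score, _, _, i, j = max(best_row, best_col)
    return float(score), i, j


def _traceback(
    H: np.ndarray, S: np.ndarray, gap: float, i: int, j: int
) -> tuple[list[tuple[int, int]], int]:
    """Walk back from the optimal cell, preferring diagonal, then gap-in-b
    (consume a), then gap-in-a.  Returns matched pairs and the number of
    internal gap positions on the path."""
    pairs: list[tuple[int, int]] = []
    gaps = 0
    tol = 1e-9
    while i > 0 and j > 0:
        h = H[i, j]
        if abs(h - (H[i - 1, j - 1] + S[i - 1, j - 1])) <= tol:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif abs(h - (H[i - 1, j] - gap)) <= tol:
            gaps += 1
            i -= 1
        elif abs(h - (H[i, j - 1] - gap)) <= tol:
            gaps += 1
            j -= 1
        else:  # free leading region (h == 0 plateau)
            break
    pairs.reverse()
    return pairs, gaps


def semiglobal_align(
    a: GenomeProfile,
    b: GenomeProfile,
    m: FamilySimilarityMatrix,
    params: AlignmentParams = AlignmentParams(),
    auto_extend: bool = True,
) -> AlignmentResult:
    """Optimal semiglobal gene-order alignment at a single fixed orientation.

    Leading and trailing gaps on both sequences are free; each internal gap
    position costs ``gap_penalty``; matches and mismatches score according to
    the substitution matrix.  No rotation or reversal is explored here.
    """
    m = _require_labels(m, [a, b], auto_extend)
    gap = params.resolve_gap(m)
    S = m.pair_scores(a.families, b.families)
    H = _score_grid(S, gap)
    score, i, j = _best_cell(H)
    pairs, gaps = _traceback(H, S, gap, i, j)
    return AlignmentResult(
        score=score,
        rotation_offset=0,
        orientation=SENSE,
        aligned_pairs=tuple(pairs),
        n_internal_gaps=gaps,
    )


def _oriented(b: GenomeProfile, orientation: str) -> GenomeProfile:
    return b if orientation == SENSE else b.reversed()


def _batched_scores(S_stack: np.ndarray, gap: float) -> np.ndarray:
    """Semiglobal scores for a stack of pair-score matrices (R, n, m).

    Runs the row DP simultaneously for every rotation/orientation slice;
    returns the optimal score per slice.
    """
    R, n, m = S_stack.shape
    H = np.zeros((R, m + 1))
    gar = gap * np.arange(m)
    best_col = np.zeros(R)
    for i in range(n):
        T = np.maximum(H[:, :-1] + S_stack[:, i, :], H[:, 1:] - gap)
        H[:, 1:] = np.maximum.accumulate(T + gar, axis=1) - gar
        best_col = np.maximum(best_col, H[:, m])
    return np.maximum(H.max(axis=1), best_col)


def best_score(
    a: GenomeProfile,
    b: GenomeProfile,
    m: FamilySimilarityMatrix,
    params: AlignmentParams = AlignmentParams(),
    auto_extend: bool = True,
) -> AlignmentResult:
    """Maximum semiglobal score over rotations of ``b`` and both orientations.

    Rotations are explored only when ``b`` is circular and
    ``params.search_rotations`` is set; the antisense direction only when
    ``params.search_antisense`` is set.  Ties prefer the smallest rotation
    offset, then sense over antisense.
    """
    m = _require_labels(m, [a, b], auto_extend)
    gap = params.resolve_gap(m)
    ia = m.indices(a.families)

    orientations = [SENSE] + ([ANTISENSE] if params.search_antisense else [])
    n_rot = len(b) if (b.circular and params.search_rotations) else 1

    # stack every candidate configuration in tie-break order
    # ((offset, sense), (offset, antisense), next offset, ...)
    configs = list(itertools.product(range(n_rot), orientations))
    L = len(b)
    ib_by_orient = {o: m.indices(_oriented(b, o).families) for o in orientations}
    rot_idx = (np.arange(L)[None, :] + np.arange(n_rot)[:, None]) % L
    stacks = []
    for offset, orientation in configs:
        stacks.append(ib_by_orient[orientation][rot_idx[offset]])
    ib_all = np.stack(stacks)  # (R, m) label indices
    S_stack = m.scores[ia[:, None, None], ib_all[None, :, :]].transpose(1, 0, 2)
    scores = _batched_scores(S_stack, gap)

    top = scores.max()
    winner = int(np.nonzero(scores > top - _TIE_EPS)[0][0])
    offset, orientation = configs[winner]
    bb = _oriented(b, orientation).rotated(offset)
    aln = semiglobal_align(a, bb, m, params, auto_extend=False)

    # map pair indices back to original coordinates of b
    L = len(b)
    pairs = []
    for pa, pb in aln.aligned_pairs:
        orig = (pb + offset) % L
        if orientation == ANTISENSE:
            orig = L - 1 - orig
        pairs.append((pa, orig))
    return AlignmentResult(
        score=aln.score,
        rotation_offset=offset,
        orientation=orientation,
        aligned_pairs=tuple(pairs),
        n_internal_gaps=aln.n_internal_gaps,
    )


def canonical_form(p: GenomeProfile, params: AlignmentParams) -> GenomeProfile:
    """Canonical linearization of a circular profile.

    The cut point a circular genome received during assembly is arbitrary,
    and a semiglobal alignment is not invariant to the cut of the sequence
    whose rotations are *not* searched.  Mapping every profile to its
    lexicographically least rotation (over both reading directions when the
    antisense search is enabled) removes that artifact deterministically, so
    distances do not depend on how the input happened to be linearized.
    Linear profiles, and profiles outside the enabled search space, are
    returned unchanged.
    """
    if not (p.circular and params.search_rotations):
        return p
    candidates = [p.rotated(k) for k in range(len(p))]
    if params.search_antisense:
        rev = p.reversed()
        candidates += [rev.rotated(k) for k in range(len(p))]
    return min(candidates, key=lambda q: q.families)


def goat_distance(
    a: GenomeProfile,
    b: GenomeProfile,
    m: FamilySimilarityMatrix,
    params: AlignmentParams = AlignmentParams(),
    auto_extend: bool = True,
    _self_scores: dict[str, float] | None = None,
) -> float:
    """Gene-order distance ``1 - (G_AB + G_BA) / (G_AA + G_BB)``.

    Each circular profile is first mapped to its canonical linearization
    (:func:`canonical_form`), which makes the distance exactly invariant
    under rotation or reversal of either input.  ``G_AB`` and ``G_BA`` are
    then computed as two independent searches (rotation applies to the
    second argument); the formula symmetrizes them.  The result is clamped
    into [0, 1] with a warning if an exotic substitution matrix pushes it
    outside.
    """
    m = _require_labels(m, [a, b], auto_extend)
    a = canonical_form(a, params)
    b = canonical_form(b, params)
    cache = _self_scores if _self_scores is not None else {}

    def self_score(p: GenomeProfile) -> float:
        if p.genome_id not in cache:
            cache[p.genome_id] = best_score(p, p, m, params, auto_extend=False).score
        return cache[p.genome_id]

    g_aa = self_score(a)
    g_bb = self_score(b)
    if g_aa <= 0 or g_bb <= 0:
        raise ValueError(
            f"degenerate profile: zero self-alignment score for "
            f"{a.genome_id if g_aa <= 0 else b.genome_id}"
        )
    g_ab = best_score(a, b, m, params, auto_extend=False).score
    g_ba = best_score(b, a, m, params, auto_extend=False).score
    d = 1.0 - (g_ab + g_ba) / (g_aa + g_bb)
    if d < 0.0 or d > 1.0:
        warnings.warn(
            f"distance {d:.6g} for ({a.genome_id}, {b.genome_id}) outside "
            "[0, 1]; clamped", stacklevel=2,
        )
        d = min(1.0, max(0.0, d))
    return d


def distance_matrix(
    profiles: Sequence[GenomeProfile],
    m: FamilySimilarityMatrix,
    params: AlignmentParams = AlignmentParams(),
    auto_extend: bool = True,
) -> DistanceMatrix:
    """Symmetric pairwise gene-order distance matrix over a genome set."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    ids = [p.genome_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    m = _require_labels(m, profiles, auto_extend)
    n = len(profiles)
    vals = np.zeros((n, n))
    self_scores: dict[str, float] = {}
    for i, j in itertools.combinations(range(n), 2):
        try:
            d = goat_distance(
                profiles[i], profiles[j], m, params,
                auto_extend=False, _self_scores=self_scores,
            )
        except ValueError as exc:
            raise ValueError(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
        vals[i, j] = vals[j, i] = d
        logger.debug("distance(%s, %s) = %.4f", ids[i], ids[j], d)
    return DistanceMatrix(vals, ids)


# ---------------------------------------------------------------------------
# distance-matrix serialization


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a lower-triangle PHYLIP distance file."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for i, gid in enumerate(dm.ids):
            row = " ".join(f"{dm.data[i, j]:.6f}" for j in range(i))
            fh.write(f"{gid}{' ' + row if row else ''}\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a lower-triangle (or square) PHYLIP distance file."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    n = int(tokens[0].split()[0])
    ids: list[str] = []
    rows: list[list[float]] = []
    for line in tokens[1 : n + 1]:
        parts = line.split()
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    vals = np.zeros((n, n))
    for i, row in enumerate(rows):
        if len(row) == n:  # square variant
            vals[i, :] = row
        else:
            for j, v in enumerate(row[:i]):
                vals[i, j] = vals[j, i] = v
    return DistanceMatrix(vals, ids)


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_data_frame().to_csv(path, sep="\t")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index])
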