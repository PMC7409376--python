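"""Independent brute-force references used to validate the implementation.

These deliberately use different algorithms from the package: the aligner
oracle maximizes over all monotone match chains (sparse chaining recurrence)
instead of running a grid DP, and the coverage oracle enumerates positions
one by one instead of sweeping intervals.
"""

from __future__ import annotations

from typing import Callable, Sequence


def chain_best_score(
    a: Sequence[str],
    b: Sequence[str],
    score: Callable[[str, str], float],
    gap: float,
) -> float:
    """Best semiglobal score via exhaustive monotone match chaining.

    Every monotone set of matched index pairs is considered through the
    recurrence M[i, j] = s(i, j) + max(0, max over i' < i, j' < j of
    M[i', j'] - gap * ((i - i' - 1) + (j - j' - 1))).  Leading and trailing
    gaps are free; unmatched positions between consecutive matches are
    internal gaps.  The empty alignment scores 0.
    """
    n, m = len(a), len(b)
    M = [[0.0] * m for _ in range(n)]
    best = 0.0
    for i in range(n):
        for j in range(m):
            prev = 0.0
            for i2 in range(i):
                for j2 in range(j):
                    cand = M[i2][j2] - gap * ((i - i2 - 1) + (j - j2 - 1))
                    if cand > prev:
                        prev = cand
            M[i][j] = score(a[i], b[j]) + prev
            if M[i][j] > best:
                best = M[i][j]
    return best


def brute_best_score(
    a: Sequence[str],
    b: Sequence[str],
    score: Callable[[str, str], float],
    gap: float,
    b_circular: bool = True,
    antisense: bool = True,
) -> float:
    """Chaining oracle maximized over rotations of ``b`` and orientations."""
    candidates = []
    orientations = [list(b)]
    if antisense:
        orientations.append(list(b)[::-1])
    n_rot = len(b) if b_circular else 1
    for seq in orientations:
        for off in range(n_rot):
            rotated = seq[off:] + seq[:off]
            candidates.append(chain_best_score(a, rotated, score, gap))
    return max(candidates)


def canonical_linearization(
    seq: Sequence[str], circular: bool = True, antisense: bool = True
) -> list[str]:
    """Lexicographically least rotation (over both directions if enabled)."""
    seq = list(seq)
    if not circular:
        return seq
    forms = [seq[k:] + seq[:k] for k in range(len(seq))]
    if antisense:
        rev = seq[::-1]
        forms += [rev[k:] + rev[:k] for k in range(len(seq))]
    return min(forms)


def brute_goat_distance(
    a: Sequence[str],
    b: Sequence[str],
    score: Callable[[str, str], float],
    gap: float,
    circular: bool = True,
    antisense: bool = True,
) -> float:
    a = canonical_linearization(a, circular, antisense)
    b = canonical_linearization(b, circular, antisense)
    g_ab = brute_best_score(a, b, score, gap, circular, antisense)
    g_ba = brute_best_score(b, a, score, gap, circular, antisense)
    g_aa = brute_best_score(a, a, score, gap, circular, antisense)
    g_bb = brute_best_score(b, b, score, gap, circular, antisense)
    d = 1.0 - (g_ab + g_ba) / (g_aa + g_bb)
    return min(1.0, max(0.0, d))


def positionwise_weighted_cover(
    intervals: Sequence[tuple[int, int, float]],
) -> float:
    """Identity-weighted union length, counting positions one at a time."""
    norm = [(min(s, e), max(s, e), w) for s, e, w in intervals]
    if not norm:
        return 0.0
    lo = min(s for s, _, _ in norm)
    hi = max(e for _, e, _ in norm)
    total = 0.0
    for pos in range(lo, hi + 1):
        total += max((w for s, e, w in norm if s <= pos <= e), default=0.0)
    return total
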