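"""Pairwise genome similarity from alignment hit tables, and rank demarcation.

Two percent-scale similarity statistics are aggregated from standard
12-column tabular alignment output (BLASTn for nucleotide identity, tBLASTx
for translated similarity):

* the Dice score, from reciprocal translated hits, normalized by the summed
  genome lengths;
* the symmetrical identity (SI), the mean of the two directional
  identity-weighted coverage fractions.

Both use identity-weighted merged intervals: every genome position covered
by at least one filtered hit contributes the maximum fractional identity of
the hits covering it.  Taxon demarcation applies a similarity threshold by
single-linkage clustering (connected components of the ">threshold" graph) —
the only linkage under which threshold edges are transitive into groups.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

#: Standard 12-column tabular alignment output (BLAST ``-outfmt 6``).
BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

#: Hit filters for translated (tBLASTx) genome comparison:
#: identity >= 30 %, alignment length >= 30 aa, E-value <= 0.01.
DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_LENGTH = 30
DEFAULT_MAX_EVALUE = 0.01

#: Rank demarcation presets, percent similarity.  Species: >95 % nucleotide
#: identity; genus: >50 % similarity; subfamily: ~25 % translated similarity.
RANK_THRESHOLDS = {"species": 95.0, "genus": 50.0, "subfamily": 25.0}


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read 12-column tabular alignment output into a typed DataFrame."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=BLAST_COLUMNS,
        dtype={"qseqid": str, "sseqid": str},
    )
    return df


def filter_hits(
    hits: pd.DataFrame,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> pd.DataFrame:
    """Keep hits with identity >= ``min_identity`` %, alignment length >=
    ``min_length`` and E-value <= ``max_evalue``, preserving input order."""
    mask = (
        (hits["pident"] >= min_identity)
        & (hits["length"] >= min_length)
        & (hits["evalue"] <= max_evalue)
    )
    removed = int((~mask).sum())
    if removed:
        logger.info("filter_hits removed %d of %d hits", removed, len(hits))
    return hits[mask]


def _weighted_cover(intervals: Iterable[tuple[int, int, float]]) -> float:
    """Identity-weighted union length of 1-based inclusive intervals.

    Each position covered by >= 1 interval contributes the maximum
    fractional identity among the intervals covering it.
    """
    ivs = []
    for start, end, w in intervals:
        lo, hi = (start, end) if start <= end else (end, start)
        ivs.append((lo, hi, float(w)))
    if not ivs:
        return 0.0
    # sweep over elementary segments between sorted breakpoints
    points = sorted({p for lo, hi, _ in ivs for p in (lo, hi + 1)})
    total = 0.0
    for seg_lo, seg_hi in zip(points[:-1], points[1:]):
        w = max((w for lo, hi, w in ivs if lo <= seg_lo and seg_hi - 1 <= hi),
                default=0.0)
        total += w * (seg_hi - seg_lo)
    return total


def _query_cover(hits: pd.DataFrame) -> float:
    return _weighted_cover(
        (int(q1), int(q2), p / 100.0)
        for q1, q2, p in zip(hits["qstart"], hits["qend"], hits["pident"])
    )


def dice_score(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    len_a: int,
    len_b: int,
) -> float:
    """Dice similarity (percent) from reciprocal hit tables.

    ``100 * (C_AB + C_BA) / (len_a + len_b)`` where ``C_XY`` is the
    identity-weighted merged query coverage of genome X by its filtered hits
    against Y.  Pass hits through :func:`filter_hits` first.
    """
    if len_a <= 0 or len_b <= 0:
        raise ValueError("genome lengths must be positive")
    return 100.0 * (_query_cover(hits_ab) + _query_cover(hits_ba)) / (len_a + len_b)


def symmetrical_identity(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    len_a: int,
    len_b: int,
) -> float:
    """Symmetrical identity (percent): mean of the two directional
    identity-weighted coverage fractions of each genome by its hits."""
    if len_a <= 0 or len_b <= 0:
        raise ValueError("genome lengths must be positive")
    return 50.0 * (_query_cover(hits_ab) / len_a + _query_cover(hits_ba) / len_b)


def similarity_matrix(
    hits: pd.DataFrame,
    lengths: Mapping[str, int],
    kind: str = "dice",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> pd.DataFrame:
    """All-pairs similarity matrix from one pooled hit table.

    ``hits`` holds every directed comparison (qseqid = query genome); rows
    are filtered, split by (query, subject) pair, and aggregated with
    :func:`dice_score` or :func:`symmetrical_identity`.  Diagonal is 100.
    """
    if kind not in ("dice", "si"):
        raise ValueError("kind must be 'dice' or 'si'")
    ids = sorted(lengths)
    kept = filter_hits(hits, min_identity, min_length, max_evalue)
    grouped = {
        (q, s): grp for (q, s), grp in kept.groupby(["qseqid", "sseqid"], sort=False)
    }
    empty = kept.iloc[0:0]
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    np.fill_diagonal(mat.values, 100.0)
    fn = dice_score if kind == "dice" else symmetrical_identity
    for a, b in itertools.combinations(ids, 2):
        val = fn(
            grouped.get((a, b), empty), grouped.get((b, a), empty),
            lengths[a], lengths[b],
        )
        mat.loc[a, b] = mat.loc[b, a] = val
    return mat


def demarcate(matrix: pd.DataFrame, threshold: float) -> dict[str, list[str]]:
    """Partition genomes by single-linkage at a similarity threshold.

    Edges connect pairs with similarity strictly greater than ``threshold``;
    clusters are the connected components, labeled by their smallest member
    id.  Returns ``{label: sorted members}``.
    """
    ids = [str(i) for i in matrix.index]
    if list(matrix.columns.astype(str)) != ids:
        raise ValueError("similarity matrix must be square and labeled")
    vals = matrix.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T):
        raise ValueError("similarity matrix must be symmetric")
    adj = (vals > threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False,
    )
    clusters: dict[int, list[str]] = {}
    for gid, comp in zip(ids, labels):
        clusters.setdefault(int(comp), []).append(gid)
    return {
        min(members): sorted(members)
        for members in clusters.values()
    }


def demarcation_table(
    matrix: pd.DataFrame,
    thresholds: Mapping[str, float] = RANK_THRESHOLDS,
) -> pd.DataFrame:
    """Cluster membership of every genome at each named rank threshold."""
    out = pd.DataFrame(index=[str(i) for i in matrix.index])
    for rank, thr in thresholds.items():
        part = demarcate(matrix, thr)
        member_to_label = {
            m: label for label, members in part.items() for m in members
        }
        out[rank] = [member_to_label[g] for g in out.index]
    return out
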