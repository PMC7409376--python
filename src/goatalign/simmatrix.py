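"""Family-vs-family substitution matrices from profile-profile hit scores.

Profile HMM comparison tools (HHsearch and relatives) report directed
query→target scores.  The substitution matrix used by the gene-order
alignment averages the two reciprocal directions, treating a missing
direction as zero, which makes the matrix exactly symmetric by construction.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import GenomeProfile, is_orfan

logger = logging.getLogger(__name__)


class FamilySimilarityMatrix:
    """Symmetric nonnegative substitution scores between gene families.

    Diagonal entries (self-scores) are strictly positive for every label so
    self-alignments have positive score.
    """

    def __init__(self, labels: Sequence[str], scores: np.ndarray):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(labels), len(labels)):
            raise ValueError("scores shape does not match labels")
        if (scores < 0).any():
            raise ValueError("scores must be nonnegative")
        if not np.allclose(scores, scores.T):
            raise ValueError("scores must be symmetric")
        self.labels = list(labels)
        self.scores = scores
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != len(self.labels):
            raise ValueError("duplicate labels")

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return len(self.labels)

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self._index[a], self._index[b]])

    def median_diagonal(self) -> float:
        """Median self-score over non-ORFAN families (falls back to all)."""
        diag = np.diag(self.scores)
        real = [d for lab, d in zip(self.labels, diag) if not is_orfan(lab)]
        vals = real if real else list(diag)
        return float(np.median(vals))

    def indices(self, labels: Iterable[str]) -> np.ndarray:
        return np.fromiter((self._index[l] for l in labels), dtype=np.intp)

    def pair_scores(self, a_labels: Sequence[str], b_labels: Sequence[str]) -> np.ndarray:
        """Dense (len(a), len(b)) score lookup for two label sequences."""
        ia = self.indices(a_labels)
        ib = self.indices(b_labels)
        return self.scores[np.ix_(ia, ib)]

    def extended(
        self, profiles: Iterable[GenomeProfile], orfan_diag: float | None = None
    ) -> "FamilySimilarityMatrix":
        """Matrix augmented with labels found in ``profiles`` but not here.

        New labels (typically per-gene ORFAN singletons) get off-diagonal 0
        and a diagonal equal to the median self-score of the known families
        (or ``orfan_diag``), so unassigned genes can match only themselves
        without dominating the alignment score.
        """
        extra: list[str] = []
        seen = set(self._index)
        for prof in profiles:
            for lab in prof.families:
                if lab not in seen:
                    seen.add(lab)
                    extra.append(lab)
        if not extra:
            return self
        diag_val = self.median_diagonal() if orfan_diag is None else orfan_diag
        n, k = len(self.labels), len(extra)
        scores = np.zeros((n + k, n + k))
        scores[:n, :n] = self.scores
        scores[np.arange(n, n + k), np.arange(n, n + k)] = diag_val
        return FamilySimilarityMatrix(self.labels + extra, scores)

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilySimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("matrix TSV must be square with matching labels")
        return cls([str(l) for l in df.index], df.to_numpy(dtype=float))

    @classmethod
    def identity(cls, labels: Sequence[str], diag: float = 1.0) -> "FamilySimilarityMatrix":
        """Identity-like matrix: ``diag`` on the diagonal, zero elsewhere."""
        return cls(list(labels), np.eye(len(labels)) * diag)


def read_profile_hits(
    path: str | Path,
    columns: Mapping[str, str | int] | None = None,
) -> dict[tuple[str, str], float]:
    """Read directed (query, target, score) triplets from a tabular file.

    Duplicate (query, target) rows keep the maximum score; rows with a
    negative score are rejected with a warning.  ``columns`` remaps the
    query/target/score columns by name or position (default: first three
    columns of a headered TSV named ``query``, ``target``, ``score``).
    """
    path = Path(path)
    if columns is None:
        columns = {"query": "query", "target": "target", "score": "score"}
    positional = all(isinstance(v, int) for v in columns.values())
    df = pd.read_csv(
        path, sep="\t", header=None if positional else 0, comment="#",
    )
    if df.empty:
        warnings.warn(f"{path}: empty hit file", stacklevel=2)
        return {}
    sel = {k: df[v] for k, v in columns.items()}
    hits: dict[tuple[str, str], float] = {}
    for q, t, s in zip(sel["query"], sel["target"], sel["score"]):
        s = float(s)
        if s < 0:
            logger.warning("negative score for (%s, %s); row rejected", q, t)
            warnings.warn(f"negative score for ({q}, {t}); row rejected",
                          stacklevel=2)
            continue
        key = (str(q), str(t))
        if key not in hits or s > hits[key]:
            hits[key] = s
    return hits


def build_substitution_matrix(
    hits: Mapping[tuple[str, str], float],
    labels: Sequence[str] | None = None,
) -> FamilySimilarityMatrix:
    """Average reciprocal directed hits into a symmetric substitution matrix.

    ``scores[i, j] = (hit(i→j) + hit(j→i)) / 2`` with a missing direction
    counted as 0.  A family without a self-hit gets its diagonal set to the
    maximum of its row (warning), or 1.0 if the row is all zero, keeping every
    self-score strictly positive.
    """
    if labels is None:
        labels = sorted({l for pair in hits for l in pair})
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    scores = np.zeros((n, n))
    for (q, t), s in hits.items():
        if q in index and t in index:
            i, j = index[q], index[t]
            scores[i, j] += s / 2.0
            scores[j, i] += s / 2.0
    for i, lab in enumerate(labels):
        if scores[i, i] <= 0:
            row_max = scores[i].max()
            if row_max > 0:
                logger.warning(
                    "family %s lacks a self-hit; diagonal set to row max %g",
                    lab, row_max,
                )
                scores[i, i] = row_max
            else:
                scores[i, i] = 1.0
    return FamilySimilarityMatrix(labels, scores)
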