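"""Per-genome gene-order profiles and core-family sets.

A gene-order (synteny) profile is the sequence of gene-family labels of a
genome's genes in chromosomal order, ignoring sequence content.  Families are
typically pVOGs (prokaryotic Virus Orthologous Groups) assigned by HMM search;
genes without a passing hit become per-gene singleton "ORFAN" labels so they
can never spuriously match each other during alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ORFAN_PREFIX = "ORFAN:"

#: Default HMM-search E-value cutoff for family assignment.
DEFAULT_EVALUE_MAX = 1e-2


@dataclass(frozen=True)
class GeneRecord:
    """One coding feature on a genome (1-based, inclusive coordinates)."""

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class FamilyAssignment:
    """A single HMM-search hit of a gene against a family model."""

    gene_id: str
    family_id: str
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be nonnegative")
        if self.score < 0:
            raise ValueError("score must be nonnegative")


@dataclass(frozen=True)
class GenomeProfile:
    """Ordered (optionally circular) sequence of gene-family labels.

    ``families`` follows ascending start coordinate.  ``strands``, when
    present, is parallel to ``families``.
    """

    genome_id: str
    families: tuple[str, ...]
    strands: tuple[str, ...] | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.families) == 0:
            raise ValueError(f"profile {self.genome_id}: no families")
        if self.strands is not None and len(self.strands) != len(self.families):
            raise ValueError(f"profile {self.genome_id}: strands length mismatch")

    def __len__(self) -> int:
        return len(self.families)

    def family_set(self, include_orfans: bool = False) -> frozenset[str]:
        fams = self.families if include_orfans else (
            f for f in self.families if not is_orfan(f)
        )
        return frozenset(fams)

    def rotated(self, offset: int) -> "GenomeProfile":
        """New profile with the linearization origin shifted by ``offset``."""
        k = offset % len(self)
        strands = None
        if self.strands is not None:
            strands = self.strands[k:] + self.strands[:k]
        return GenomeProfile(
            self.genome_id, self.families[k:] + self.families[:k], strands,
            self.circular,
        )

    def reversed(self) -> "GenomeProfile":
        """New profile read in the antisense direction (order reversed)."""
        strands = None
        if self.strands is not None:
            strands = tuple("+" if s == "-" else "-" for s in self.strands[::-1])
        return GenomeProfile(
            self.genome_id, self.families[::-1], strands, self.circular
        )


def is_orfan(label: str) -> bool:
    return label.startswith(ORFAN_PREFIX)


def orfan_label(genome_id: str, gene_id: str) -> str:
    return f"{ORFAN_PREFIX}{genome_id}:{gene_id}"


# ---------------------------------------------------------------------------
# readers


def _records_from_frame(df: pd.DataFrame) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    for row in df.itertuples(index=False):
        try:
            records.append(
                GeneRecord(
                    gene_id=str(row.gene_id),
                    genome_id=str(row.genome_id),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand),
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("rejecting gene record %s: %s", row, exc)
            warnings.warn(f"rejecting malformed gene record: {exc}", stacklevel=3)
    records.sort(key=lambda g: (g.genome_id, g.start, g.end, g.gene_id))
    return records


def read_annotations(path: str | Path, dialect: str = "gff3") -> list[GeneRecord]:
    """Read gene coordinates from a GFF3 file or a plain TSV table.

    The TSV dialect expects a header ``genome_id, gene_id, start, end, strand``.
    GFF3 keeps CDS features only; the gene id is taken from the ``ID``
    attribute (falling back to ``locus_tag``, then a positional id).
    Records with impossible coordinates are dropped with a warning; an empty
    file is an error.  Output is sorted by (genome_id, start, end, gene_id).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"genome_id", "gene_id", "start", "end", "strand"}
        if df.empty:
            raise ValueError(f"{path}: no gene records")
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return _records_from_frame(df)
    if dialect == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_gff3(path: Path) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for n, feat in enumerate(db.features_of_type("CDS")):
        gene_id = feat.attributes.get("ID", feat.attributes.get("locus_tag", [None]))[0]
        if gene_id is None:
            gene_id = f"cds_{n + 1}"
        rows.append(
            dict(
                genome_id=feat.seqid, gene_id=gene_id, start=feat.start,
                end=feat.end, strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    if not rows:
        raise ValueError(f"{path}: no CDS features")
    return _records_from_frame(pd.DataFrame(rows))


def read_assignments(
    path: str | Path,
    columns: Mapping[str, str | int] | None = None,
) -> list[FamilyAssignment]:
    """Read gene→family hits from TSV.

    Default layout is the 4-column header ``gene_id, family_id, score,
    evalue``.  ``columns`` remaps names or positions, which accommodates
    HMM-search tabular domain output (e.g. ``{"gene_id": 0, "family_id": 3,
    "evalue": 6, "score": 7}`` with ``header=None`` handled automatically for
    integer maps).
    """
    path = Path(path)
    if columns is None:
        df = pd.read_csv(path, sep="\t")
    else:
        positional = all(isinstance(v, int) for v in columns.values())
        raw = pd.read_csv(
            path, sep=r"\s+" if positional else "\t",
            header=None if positional else 0, comment="#",
        )
        df = pd.DataFrame(
            {name: raw[sel] for name, sel in columns.items()}
        )
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            FamilyAssignment(
                gene_id=str(row.gene_id), family_id=str(row.family_id),
                score=float(row.score), evalue=float(row.evalue),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# assignment and profile construction


def assign_families(
    genes: Sequence[GeneRecord],
    hits: Iterable[FamilyAssignment],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    include_orfans: bool = True,
) -> dict[str, str]:
    """Map each gene to its best-scoring family.

    The winning hit has the smallest E-value passing ``evalue_max``; ties are
    broken by larger bit score, then lexicographic family id.  Genes without a
    passing hit get a unique ``ORFAN:<genome>:<gene>`` label (or are omitted
    when ``include_orfans`` is false).  Hits naming unknown genes are ignored
    with a warning.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    by_gene: dict[str, GeneRecord] = {g.gene_id: g for g in genes}
    best: dict[str, FamilyAssignment] = {}
    for hit in hits:
        if hit.gene_id not in by_gene:
            logger.warning("hit references unknown gene %s; ignored", hit.gene_id)
            warnings.warn(f"hit references unknown gene {hit.gene_id}; ignored",
                          stacklevel=2)
            continue
        if hit.evalue >= evalue_max:
            continue
        cur = best.get(hit.gene_id)
        if cur is None or (hit.evalue, -hit.score, hit.family_id) < (
            cur.evalue, -cur.score, cur.family_id
        ):
            best[hit.gene_id] = hit
    out: dict[str, str] = {}
    for gene in genes:
        if gene.gene_id in best:
            out[gene.gene_id] = best[gene.gene_id].family_id
        elif include_orfans:
            out[gene.gene_id] = orfan_label(gene.genome_id, gene.gene_id)
    return out


def build_profile(
    genome_id: str,
    genes: Sequence[GeneRecord],
    assignment: Mapping[str, str],
    circular: bool = True,
) -> GenomeProfile:
    """Assemble the gene-order profile of one genome.

    Genes are ordered by ascending start (ties: end, then gene id); genes
    absent from ``assignment`` are skipped (the drop-unassigned mode).
    """
    mine = sorted(
        (g for g in genes if g.genome_id == genome_id),
        key=lambda g: (g.start, g.end, g.gene_id),
    )
    if not mine:
        raise ValueError(f"no genes for genome {genome_id}")
    kept = [g for g in mine if g.gene_id in assignment]
    if not kept:
        raise ValueError(f"no assigned genes for genome {genome_id}")
    return GenomeProfile(
        genome_id=genome_id,
        families=tuple(assignment[g.gene_id] for g in kept),
        strands=tuple(g.strand for g in kept),
        circular=circular,
    )


def build_profiles(
    genes: Sequence[GeneRecord],
    assignment: Mapping[str, str],
    circular: bool = True,
) -> dict[str, GenomeProfile]:
    """Build one profile per genome appearing in ``genes``."""
    genome_ids = sorted({g.genome_id for g in genes})
    return {
        gid: build_profile(gid, genes, assignment, circular=circular)
        for gid in genome_ids
    }


def core_families(profiles: Iterable[GenomeProfile]) -> list[str]:
    """Families present in every genome (ORFAN singletons excluded), sorted."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    core = set(profiles[0].family_set())
    for prof in profiles[1:]:
        core &= prof.family_set()
    return sorted(core)


# ---------------------------------------------------------------------------
# serialization


def write_profiles(profiles: Iterable[GenomeProfile], path: str | Path) -> None:
    """Write profiles as TSV ``genome_id, position, family_id, strand``."""
    rows = []
    for prof in profiles:
        strands = prof.strands or ("+",) * len(prof)
        for pos, (fam, strand) in enumerate(zip(prof.families, strands), start=1):
            rows.append((prof.genome_id, pos, fam, strand, int(prof.circular)))
    df = pd.DataFrame(
        rows, columns=["genome_id", "position", "family_id", "strand", "circular"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> dict[str, GenomeProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "family_id": str})
    out: dict[str, GenomeProfile] = {}
    for gid, grp in df.groupby("genome_id", sort=True):
        grp = grp.sort_values("position")
        circular = bool(grp["circular"].iloc[0]) if "circular" in grp else True
        out[str(gid)] = GenomeProfile(
            genome_id=str(gid),
            families=tuple(grp["family_id"]),
            strands=tuple(grp["strand"]) if "strand" in grp else None,
            circular=circular,
        )
    return out
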