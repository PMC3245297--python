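"""Sequence, alignment and reference-table I/O for enzyme-family analysis.

This module holds the plumbing shared by the rest of the package: FASTA /
Stockholm readers, a light alignment container, percent-identity computation
under global alignment, greedy centroid clustering at a fixed identity
threshold (the scheme used to form 30%-identity clusters of an annotated
family), the packaged reference-function table of the FGGY carbohydrate
kinase family, and the mapping of columns from a sub-alignment into a master
alignment of the whole family.

Coordinates are 0-based everywhere in code; 1-based only in written reports.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

__all__ = [
    "AA_ALPHABET",
    "GAP",
    "SequenceRecord",
    "Alignment",
    "ReferenceTable",
    "ClusterAssignment",
    "read_fasta",
    "read_alignment",
    "pairwise_identity",
    "greedy_cluster",
    "load_reference_table",
    "map_column_to_master",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A gap-free protein sequence with optional organism/function metadata."""

    id: str
    residues: str
    organism: str = ""
    genome_id: str = ""
    function_label: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - set(AA_ALPHABET + "X")
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A multiple sequence alignment: equal-length gapped rows keyed by id."""

    row_ids: list[str]
    matrix: list[str]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.matrix):
            raise ValueError("row_ids and matrix length mismatch")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids in alignment")
        lengths = {len(r) for r in self.matrix}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    def row(self, row_id: str) -> str:
        return self.matrix[self.row_ids.index(row_id)]

    def column(self, c: int) -> list[str]:
        return [row[c] for row in self.matrix]

    def degap(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read gap-free sequences from a FASTA file.

    The description line may carry ``key=value`` tokens for ``organism``,
    ``genome`` and ``function``; anything else is ignored.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper().replace(GAP, ""),
                organism=meta.get("organism", ""),
                genome_id=meta.get("genome", ""),
                function_label=meta.get("function", ""),
            )
        )
    return records


def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read an MSA from aligned FASTA (``fmt='fasta'``) or Stockholm."""
    aln = AlignIO.read(str(path), fmt)
    return Alignment(
        row_ids=[rec.id for rec in aln],
        matrix=[str(rec.seq).upper() for rec in aln],
    )


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.row_ids, aln.matrix):
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# pairwise identity and greedy clustering
# ---------------------------------------------------------------------------

def _make_aligner(mode: str = "global") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions under global alignment.

    The denominator is the length of the shorter sequence, so a perfect
    sub-sequence scores 1.0.  Symmetric by construction.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    aligner = _make_aligner("global")
    aln = aligner.align(a, b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        matches += sum(x == y for x, y in zip(a[a0:a1], b[b0:b1]))
    return matches / min(len(a), len(b))


@dataclass
class ClusterAssignment:
    """Greedy-centroid clustering result at a fixed identity threshold."""

    threshold: float
    membership: dict[str, str]          # protein id -> cluster id
    centroids: dict[str, str]           # cluster id -> centroid protein id
    identities: dict[str, float]        # protein id -> identity to its centroid

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, cluster_id: str) -> list[str]:
        return sorted(k for k, v in self.membership.items() if v == cluster_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": pid,
                "cluster_id": cid,
                "centroid_id": self.centroids[cid],
                "identity": self.identities[pid],
            }
            for pid, cid in sorted(self.membership.items())
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def greedy_cluster(
    records: Sequence[SequenceRecord], threshold: float
) -> ClusterAssignment:
    """Greedy centroid clustering, UCLUST-style.

    Sequences are processed in decreasing length order (id-lexicographic tie
    break); each joins the first existing centroid with identity >= threshold,
    otherwise founds a new cluster.  Deterministic.
    """
    if not records:
        raise ValueError("no sequences to cluster")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    centroid_order: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    centroids: dict[str, str] = {}
    identities: dict[str, float] = {}
    for rec in ordered:
        placed = False
        for k, cen in enumerate(centroid_order):
            ident = pairwise_identity(rec.residues, cen.residues)
            if ident >= threshold:
                cid = f"C{k + 1}"
                membership[rec.id] = cid
                identities[rec.id] = ident
                placed = True
                break
        if not placed:
            centroid_order.append(rec)
            cid = f"C{len(centroid_order)}"
            centroids[cid] = rec.id
            membership[rec.id] = cid
            identities[rec.id] = 1.0
    return ClusterAssignment(
        threshold=threshold,
        membership=membership,
        centroids=centroids,
        identities=identities,
    )


# ---------------------------------------------------------------------------
# reference-function table
# ---------------------------------------------------------------------------

_REFERENCE_COLUMNS = [
    "function_name",
    "abbreviation",
    "ec_number",
    "substrate",
    "product",
    "reference_protein_ids",
    "cluster_ids",
    "pdb_ids",
]


@dataclass
class ReferenceTable:
    """The family's literature-supported function table.

    One row per function: abbreviation, EC number, substrate/product, the
    reference protein accessions, the 30%-identity cluster ids, and the PDB
    entries with a solved structure.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REFERENCE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"reference table missing columns: {missing}")
        abbr = self.frame["abbreviation"]
        if abbr.duplicated().any():
            dups = sorted(abbr[abbr.duplicated()])
            raise ValueError(f"duplicate function abbreviations: {dups}")
        for _, row in self.frame.iterrows():
            if not row["reference_protein_ids"]:
                raise ValueError(
                    f"{row['abbreviation']}: no reference proteins"
                )
            if not row["cluster_ids"]:
                raise ValueError(f"{row['abbreviation']}: no cluster ids")

    @staticmethod
    def _split(cell) -> list[str]:
        if isinstance(cell, list):
            return cell
        if pd.isna(cell) or not str(cell).strip():
            return []
        return [tok.strip() for tok in str(cell).split(",") if tok.strip()]

    @property
    def n_functions(self) -> int:
        return len(self.frame)

    @property
    def functions(self) -> list[str]:
        return list(self.frame["abbreviation"])

    def reference_proteins(self, abbreviation: str | None = None) -> list[str]:
        if abbreviation is None:
            out: list[str] = []
            for cell in self.frame["reference_protein_ids"]:
                out.extend(self._split(cell))
            return out
        row = self.frame[self.frame["abbreviation"] == abbreviation]
        return self._split(row.iloc[0]["reference_protein_ids"])

    def cluster_ids(self, abbreviation: str | None = None) -> list[str]:
        if abbreviation is None:
            out: list[str] = []
            for cell in self.frame["cluster_ids"]:
                out.extend(self._split(cell))
            return out
        row = self.frame[self.frame["abbreviation"] == abbreviation]
        return self._split(row.iloc[0]["cluster_ids"])

    def pdb_ids(self, abbreviation: str | None = None) -> list[str]:
        if abbreviation is None:
            out: list[str] = []
            for cell in self.frame["pdb_ids"]:
                out.extend(self._split(cell))
            return out
        row = self.frame[self.frame["abbreviation"] == abbreviation]
        return self._split(row.iloc[0]["pdb_ids"])

    @property
    def n_reference_proteins(self) -> int:
        return len(set(self.reference_proteins()))

    @property
    def n_clusters(self) -> int:
        return len(set(self.cluster_ids()))


def load_reference_table(path: str | Path | None = None) -> ReferenceTable:
    """Load a reference-function table; defaults to the packaged family table."""
    if path is None:
        path = importlib.resources.files("kinevo").joinpath(
            "data/reference_functions.tsv"
        )
    frame = pd.read_csv(str(path), sep="\t", dtype=str).fillna("")
    return ReferenceTable(frame=frame)


# ---------------------------------------------------------------------------
# sub-alignment -> master-alignment column mapping
# ---------------------------------------------------------------------------

UNMAPPABLE = None


def _nongap_ordinals(row: str) -> dict[int, int]:
    """column index -> 0-based ordinal of the non-gap residue at that column."""
    out = {}
    k = 0
    for c, ch in enumerate(row):
        if ch != GAP:
            out[c] = k
            k += 1
    return out


def map_column_to_master(
    sub: Alignment, master: Alignment, shared_row_id: str, sub_column: int
) -> int | None:
    """Map a sub-alignment column to the master-alignment column that holds
    the same residue of a shared row.

    Returns ``None`` if the shared row is gapped at ``sub_column``.
    """
    sub_row = sub.row(shared_row_id)
    master_row = master.row(shared_row_id)
    if sub_row.replace(GAP, "") != master_row.replace(GAP, ""):
        raise ValueError(
            f"{shared_row_id}: degapped rows differ between alignments"
        )
    if not 0 <= sub_column < len(sub_row):
        raise IndexError(f"column {sub_column} out of range")
    if sub_row[sub_column] == GAP:
        return UNMAPPABLE
    ordinal = _nongap_ordinals(sub_row)[sub_column]
    inverse = {v: k for k, v in _nongap_ordinals(master_row).items()}
    return inverse[ordinal]


def map_columns_to_master(
    sub: Alignment, master: Alignment, shared_row_id: str, columns: Iterable[int]
) -> dict[int, int | None]:
    return {
        c: map_column_to_master(sub, master, shared_row_id, c) for c in columns
    }
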