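"""Ligand-bound structures and the distance channel of SDP selection.

Sequence statistics alone over-predict specificity-determining positions:
columns that are group-specific for reasons unrelated to binding rank highly
too.  Intersecting the sequence ranking with residue-to-ligand distances in
co-crystallised structures removes them, while globally conserved catalytic
residues (close to the ligand but invariant across groups) are removed by
the ranking.  A column is selected as an SDP only if it is both significant
in the grouped-alignment ranking and, on average across contributing
structures, within a distance cutoff (default 4 A) of the ligand.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.SeqUtils import seq1

from .family_io import GAP, Alignment, _nongap_ordinals
from .sdp import SdpRanking

logger = logging.getLogger(__name__)

__all__ = [
    "StructureComplex",
    "ColumnDistanceProfile",
    "SdpSelection",
    "parse_structure",
    "residue_ligand_distance",
    "map_structure_to_master",
    "average_column_distance",
    "select_sdps",
]


@dataclass
class StructureComplex:
    """One chain of a ligand-bound structure, heavy atoms only."""

    pdb_id: str
    chain_id: str
    ligand_name: str
    residue_numbers: list[int]
    residue_names: list[str]
    residue_coords: list[np.ndarray]   # (n_atoms, 3) per residue
    ligand_coords: np.ndarray          # (n_atoms, 3)
    sequence: str

    def __post_init__(self) -> None:
        if len(self.ligand_coords) == 0:
            raise ValueError(f"{self.pdb_id}: ligand has no atoms")
        nums = self.residue_numbers
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(
                f"{self.pdb_id}/{self.chain_id}: residue numbers not "
                "strictly increasing"
            )

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)


def _heavy_coords(residue) -> np.ndarray:
    coords = [
        atom.coord for atom in residue.get_atoms()
        if atom.element not in ("H", "D")
    ]
    return np.asarray(coords, dtype=float)


def parse_structure(
    pdb_text: str, chain: str, ligand_name: str, pdb_id: str = ""
) -> StructureComplex:
    """Parse PDB-format text into a single-chain complex.

    Waters are never considered ligands; hydrogens are dropped; alternate
    locations resolve to the highest-occupancy conformer (then 'A'), which
    is the Biopython default.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(pdb_id or "structure", io.StringIO(pdb_text))
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} absent; available: {sorted(chains)}"
        )
    numbers, names, coords, seq_letters = [], [], [], []
    het_names = set()
    ligand_atoms = []
    for res in model.get_residues():
        hetflag, resseq, _ = res.id
        resname = res.get_resname().strip()
        if hetflag.strip() and resname != "HOH":
            het_names.add(resname)
            if resname == ligand_name:
                ligand_atoms.append(_heavy_coords(res))
            continue
        if res.get_parent().id != chain or not is_aa(res, standard=False):
            continue
        numbers.append(resseq)
        names.append(resname)
        coords.append(_heavy_coords(res))
        seq_letters.append(seq1(resname, undef_code="X"))
    if not ligand_atoms:
        raise ValueError(
            f"ligand {ligand_name!r} not found; het groups present: "
            f"{sorted(het_names)}"
        )
    return StructureComplex(
        pdb_id=pdb_id,
        chain_id=chain,
        ligand_name=ligand_name,
        residue_numbers=numbers,
        residue_names=names,
        residue_coords=coords,
        ligand_coords=np.vstack(ligand_atoms),
        sequence="".join(seq_letters),
    )


def residue_ligand_distance(
    residue_atoms: np.ndarray, ligand_atoms: np.ndarray
) -> float:
    """Minimum heavy-atom pair distance (A) between a residue and the ligand."""
    a = np.atleast_2d(np.asarray(residue_atoms, dtype=float))
    b = np.atleast_2d(np.asarray(ligand_atoms, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("empty atom set")
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).min())


def map_structure_to_master(
    sc: StructureComplex,
    master: Alignment,
    row_id: str,
    min_identity: float = 0.90,
) -> dict[int, int]:
    """Map structure residue numbers to master-alignment columns.

    The structure-derived sequence is globally aligned to the degapped
    master row (structures may carry point mutations, so <100% identity is
    tolerated down to ``min_identity`` over the aligned span), and the
    result is composed with the row's gap structure.  Residues that do not
    align are omitted from the map.
    """
    row = master.row(row_id)
    target = row.replace(GAP, "")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(sc.sequence, target)[0]
    pairs = []
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
            if sc.sequence[i] == target[j]:
                matches += 1
    if not pairs or matches / len(pairs) < min_identity:
        got = matches / len(pairs) if pairs else 0.0
        raise ValueError(
            f"structure {sc.pdb_id} maps to row {row_id} at "
            f"{got:.2%} identity (< {min_identity:.0%})"
        )
    ordinal_to_column = {v: k for k, v in _nongap_ordinals(row).items()}
    return {
        sc.residue_numbers[i]: ordinal_to_column[j] for i, j in pairs
    }


@dataclass
class ColumnDistanceProfile:
    """Mean residue-to-ligand distance per master column across structures."""

    mean_distance: dict[int, float]
    n_structures: dict[int, int]

    def distance(self, column: int) -> float:
        return self.mean_distance.get(column, math.nan)

    @property
    def columns(self) -> list[int]:
        return sorted(self.mean_distance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column_1based": [c + 1 for c in self.columns],
                "mean_distance_A": [self.mean_distance[c] for c in self.columns],
                "n_structures": [self.n_structures[c] for c in self.columns],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def structure_column_distances(
    sc: StructureComplex, master: Alignment, row_id: str,
    min_identity: float = 0.90,
) -> dict[int, float]:
    """Per-master-column ligand distance for one structure."""
    resmap = map_structure_to_master(sc, master, row_id, min_identity)
    by_number = dict(zip(sc.residue_numbers, sc.residue_coords))
    out = {}
    for resnum, column in resmap.items():
        coords = by_number[resnum]
        if coords.size == 0:
            continue
        out[column] = residue_ligand_distance(coords, sc.ligand_coords)
    return out


def average_column_distance(
    per_structure: list[dict[int, float]]
) -> ColumnDistanceProfile:
    """Arithmetic mean of per-structure column distances."""
    if not per_structure:
        raise ValueError("need at least one structure")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for dists in per_structure:
        for column, d in dists.items():
            sums[column] = sums.get(column, 0.0) + d
            counts[column] = counts.get(column, 0) + 1
    return ColumnDistanceProfile(
        mean_distance={c: sums[c] / counts[c] for c in sums},
        n_structures=counts,
    )


@dataclass
class SdpSelection:
    """Columns passing both the ranking and the ligand-distance criterion."""

    columns: list[int]
    table: pd.DataFrame  # column, rank, z, mean_distance
    distance_cutoff: float
    cutoff_k: int

    def write(self, tsv_path, json_path=None) -> None:
        out = self.table.copy()
        out["column_1based"] = out["column"] + 1
        out[["column_1based", "rank", "z", "mean_distance"]].to_csv(
            tsv_path, sep="\t", index=False
        )
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(
                    {
                        "distance_cutoff_A": self.distance_cutoff,
                        "cutoff_k": self.cutoff_k,
                        "selected_columns_1based": [c + 1 for c in self.columns],
                    },
                    fh,
                    indent=2,
                )


def select_sdps(
    ranking: SdpRanking,
    profile: ColumnDistanceProfile | None,
    distance_cutoff: float = 4.0,
) -> SdpSelection:
    """Intersect the sequence ranking with the ligand-distance profile.

    Selected columns satisfy ``rank <= cutoff_k`` and
    ``mean_distance <= distance_cutoff``.  With ``profile=None`` the
    selection degrades to sequence-only mode (a logged, non-canonical
    fallback that admits binding-unrelated group-specific columns).
    """
    significant = ranking.significant
    if profile is None:
        logger.warning(
            "no structures supplied: sequence-only SDP selection (distance "
            "criterion skipped)"
        )
        sub = ranking.table.set_index("column").loc[significant]
        table = pd.DataFrame(
            {
                "column": significant,
                "rank": sub["rank"].to_numpy(),
                "z": sub["z"].to_numpy(),
                "mean_distance": np.nan,
            }
        )
        return SdpSelection(
            columns=significant,
            table=table,
            distance_cutoff=math.inf,
            cutoff_k=ranking.cutoff_k,
        )
    universe = set(ranking.table["column"])
    if universe.isdisjoint(profile.mean_distance):
        raise ValueError(
            "ranking and distance profile share no columns; are they on the "
            "same master alignment?"
        )
    selected = [
        c for c in significant
        if not math.isnan(profile.distance(c))
        and profile.distance(c) <= distance_cutoff
    ]
    sub = ranking.table.set_index("column")
    table = pd.DataFrame(
        {
            "column": selected,
            "rank": [int(sub.loc[c, "rank"]) for c in selected],
            "z": [float(sub.loc[c, "z"]) for c in selected],
            "mean_distance": [profile.distance(c) for c in selected],
        }
    )
    return SdpSelection(
        columns=selected,
        table=table,
        distance_cutoff=distance_cutoff,
        cutoff_k=ranking.cutoff_k,
    )
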