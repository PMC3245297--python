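import math

import numpy as np
import pandas as pd
import pytest

from kinevo.family_io import Alignment
from kinevo.sdp import SdpRanking
from kinevo.structure import (
    average_column_distance,
    map_structure_to_master,
    parse_structure,
    residue_ligand_distance,
    select_sdps,
    structure_column_distances,
)

ATOM = (
    "{kind:<6s}{serial:>5d} {name:^4s} {resname:>3s} {chain:1s}"
    "{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {el:>2s}"
)


def pdb_text(lines):
    return "\n".join(lines + ["END"]) + "\n"


def toy_pdb():
    """Three CA residues (ALA, ARG, GLY) plus one ligand atom and a water."""
    lines = [
        ATOM.format(kind="ATOM", serial=1, name=" CA ", resname="ALA",
                    chain="A", resseq=1, x=5.0, y=0.0, z=0.0, occ=1.0, b=0.0,
                    el="C"),
        ATOM.format(kind="ATOM", serial=2, name=" CA ", resname="ARG",
                    chain="A", resseq=2, x=0.0, y=3.0, z=0.0, occ=1.0, b=0.0,
                    el="C"),
        ATOM.format(kind="ATOM", serial=3, name=" CA ", resname="GLY",
                    chain="A", resseq=3, x=0.0, y=0.0, z=9.0, occ=1.0, b=0.0,
                    el="C"),
        ATOM.format(kind="HETATM", serial=4, name=" O  ", resname="HOH",
                    chain="W", resseq=1, x=1.0, y=1.0, z=1.0, occ=1.0, b=0.0,
                    el="O"),
        ATOM.format(kind="HETATM", serial=5, name=" C1 ", resname="LIG",
                    chain="L", resseq=1, x=0.0, y=0.0, z=0.0, occ=1.0, b=0.0,
                    el="C"),
    ]
    return pdb_text(lines)


class TestParseStructure:
    def test_toy_counts(self):
        sc = parse_structure(toy_pdb(), "A", "LIG", "TOY")
        assert sc.n_residues == 3
        assert len(sc.ligand_coords) == 1
        assert sc.sequence == "ARG"[0] + "R" + "G"  # A, R, G one-letter

    def test_water_never_a_ligand(self):
        with pytest.raises(ValueError, match="het groups"):
            parse_structure(toy_pdb(), "A", "HOH")

    def test_missing_ligand_lists_het_groups(self):
        with pytest.raises(ValueError, match="LIG"):
            parse_structure(toy_pdb(), "A", "ATP")

    def test_missing_chain(self):
        with pytest.raises(ValueError, match="chain"):
            parse_structure(toy_pdb(), "B", "LIG")

    def test_altloc_resolved_to_single_atom(self):
        lines = [
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40"
            "  0.00           C",
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60"
            "  0.00           C",
            ATOM.format(kind="HETATM", serial=3, name=" C1 ", resname="LIG",
                        chain="L", resseq=1, x=0.0, y=0.0, z=0.0, occ=1.0,
                        b=0.0, el="C"),
        ]
        sc = parse_structure(pdb_text(lines), "A", "LIG")
        assert sc.n_residues == 1
        assert sc.residue_coords[0].shape == (1, 3)
        # highest occupancy conformer (B) retained
        assert sc.residue_coords[0][0, 0] == pytest.approx(9.0)


class TestResidueLigandDistance:
    @pytest.mark.parametrize(
        "res, lig, expected",
        [
            ([(0, 0, 0)], [(3, 4, 0)], 5.0),
            ([(0, 0, 0), (1, 0, 0)], [(1.5, 0, 0)], 0.5),
            ([(1, 2, 3)], [(1, 2, 3)], 0.0),
        ],
    )
    def test_min_atom_pairs(self, res, lig, expected):
        assert residue_ligand_distance(
            np.array(res, float), np.array(lig, float)
        ) == pytest.approx(expected)

    def test_symmetric_and_rigid_motion_invariant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(3, 3))
        d = residue_ligand_distance(a, b)
        assert residue_ligand_distance(b, a) == pytest.approx(d)
        # random rotation + translation applied to both sets
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(size=3)
        assert residue_ligand_distance(a @ q + t, b @ q + t) == pytest.approx(
            d
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            residue_ligand_distance(np.empty((0, 3)), np.ones((1, 3)))


class TestStructureMapping:
    def _structure(self, seq, offset=0):
        lines = [
            ATOM.format(kind="ATOM", serial=i + 1, name=" CA ",
                        resname={"A": "ALA", "R": "ARG", "N": "ASN",
                                 "D": "ASP", "C": "CYS", "M": "MET",
                                 "K": "LYS", "L": "LEU", "V": "VAL",
                                 "W": "TRP"}[aa],
                        chain="A", resseq=i + 1 + offset, x=float(i), y=0.0,
                        z=0.0, occ=1.0, b=0.0, el="C")
            for i, aa in enumerate(seq)
        ]
        lines.append(
            ATOM.format(kind="HETATM", serial=99, name=" C1 ", resname="LIG",
                        chain="L", resseq=1, x=0.0, y=0.0, z=0.0, occ=1.0,
                        b=0.0, el="C")
        )
        return parse_structure(pdb_text(lines), "A", "LIG")

    def test_identical_sequence_bijective(self):
        master = Alignment(["x"], ["MK-LVWA"])
        sc = self._structure("MKLVWA")
        mapping = map_structure_to_master(sc, master, "x")
        assert sorted(mapping.values()) == [0, 1, 3, 4, 5, 6]

    def test_missing_n_terminal_residues_shift(self):
        master = Alignment(["x"], ["MKLVWARNDC"])
        sc = self._structure("LVWARNDC", offset=2)
        mapping = map_structure_to_master(sc, master, "x")
        assert 1 not in mapping and 2 not in mapping
        assert mapping[3] == 2   # residue 3 is the L at master column 2
        assert mapping[10] == 9

    def test_unrelated_sequence_rejected(self):
        master = Alignment(["x"], ["MKLVWMKLVW"])
        sc = self._structure("DNDNDNDNDN")
        with pytest.raises(ValueError, match="identity"):
            map_structure_to_master(sc, master, "x")


class TestAverageAndSelect:
    def _ranking(self, stats, cutoff_k):
        # stats: list of (column, z, rank)
        table = pd.DataFrame(
            {
                "column": [c for c, _, _ in stats],
                "mi_bits": [abs(z) for _, z, _ in stats],
                "z": [z for _, z, _ in stats],
                "p": [0.001 for _ in stats],
                "n_effective": [40 for _ in stats],
                "rank": [r for _, _, r in stats],
            }
        )
        return SdpRanking(table=table, cutoff_k=cutoff_k)

    def test_mean_across_structures(self):
        profile = average_column_distance([{2: 3.0, 5: 1.0}, {2: 5.0}])
        assert profile.distance(2) == pytest.approx(4.0)
        assert profile.distance(5) == pytest.approx(1.0)
        assert profile.n_structures[2] == 2
        assert math.isnan(profile.distance(7))

    def test_dual_criterion(self):
        ranking = self._ranking(
            [(0, 9.0, 2), (1, 8.0, 3), (2, 0.1, 50)], cutoff_k=5
        )
        profile = average_column_distance([{0: 3.5, 1: 5.0, 2: 2.0}])
        sel = select_sdps(ranking, profile, 4.0)
        # rank ok + close -> kept; rank ok + distal -> out; close + low rank -> out
        assert sel.columns == [0]

    def test_sequence_only_fallback(self):
        ranking = self._ranking([(0, 9.0, 1), (1, 0.1, 2)], cutoff_k=1)
        sel = select_sdps(ranking, None)
        assert sel.columns == [0]

    def test_disjoint_universes_rejected(self):
        ranking = self._ranking([(0, 9.0, 1)], cutoff_k=1)
        profile = average_column_distance([{99: 1.0}])
        with pytest.raises(ValueError, match="share no columns"):
            select_sdps(ranking, profile)


class TestGeneratorContract:
    def test_planted_close_distal_far(self, default_family,
                                      default_structures):
        cfg, galn, truth = default_family
        per = [
            structure_column_distances(
                parse_structure(ts.pdb_text, ts.chain, ts.ligand_name,
                                ts.pdb_id),
                galn.alignment,
                ts.row_id,
            )
            for ts in default_structures
        ]
        profile = average_column_distance(per)
        for c in truth.binding_columns:
            assert profile.distance(c) <= 4.0
        for c in truth.distal_columns:
            assert profile.distance(c) > 4.0
        far = [
            c for c in profile.columns
            if c not in truth.binding_columns
        ]
        assert all(profile.distance(c) > 4.0 for c in far)
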