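"""Synthetic inputs with known ground truth for every pipeline stage.

The family generator emulates the column structure of a grouped alignment
of a multi-functional family:

* planted SDP columns — one distinct residue per isofunctional group,
  located at the binding site in the toy structures;
* distal group-specific columns — the same group-conserved pattern but far
  from the ligand (sequence-only false positives of SDP selection);
* catalytic columns — one residue conserved across all groups, close to
  the ligand (structure-only false positives);
* background columns — residues drawn per column from a Dirichlet profile
  shared by all groups, so they carry no group signal but realistic,
  column-specific conservation.

Within-group noise flips any non-background residue to a random other
residue with probability epsilon.  Toy structures are CA-only chains with a
single-atom ligand placed so that binding columns fall within 4 A and all
others beyond it.  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode
from Bio.SeqUtils import seq3

from .context import GeneRecord, PathwayContextMap
from .family_io import AA_ALPHABET, Alignment, load_reference_table
from .phylo import LabeledTree
from .sdp import GroupedAlignment

__all__ = [
    "SimulationConfig",
    "FamilyTruth",
    "ToyStructure",
    "simulate_family",
    "simulate_structures",
    "simulate_function_evolution",
    "simulate_genomes",
    "make_reference_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic family.

    Defaults describe a two-group family of 20 sequences each over 200
    columns with five planted SDPs, three catalytic and three distal
    group-specific columns, and 5% within-group substitution noise.  The
    background Dirichlet concentration (0.5 per residue) makes background
    columns moderately conserved, as in a real family alignment, so their
    mutual information is small but not zero.
    """

    n_groups: int = 2
    n_seqs_per_group: int = 20
    alignment_length: int = 200
    n_planted_sdps: int = 5
    n_catalytic_columns: int = 3
    n_distal_specific_columns: int = 3
    within_group_noise: float = 0.05
    background_concentration: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        special = (
            self.n_planted_sdps
            + self.n_catalytic_columns
            + self.n_distal_specific_columns
        )
        if special > self.alignment_length:
            raise ValueError("special columns exceed alignment length")
        if not 0 <= self.within_group_noise <= 1:
            raise ValueError("noise must lie in [0, 1]")
        if self.n_groups < 2:
            raise ValueError("need at least two groups")
        if self.n_groups > 20:
            raise ValueError("at most 20 groups (distinct residues required)")


@dataclass
class FamilyTruth:
    """Ground truth of one simulated family."""

    planted_columns: list[int]
    catalytic_columns: list[int]
    distal_columns: list[int]
    group_residues: dict[str, str]   # group -> residues at planted+distal cols
    catalytic_residues: str
    group_labels: list[str]
    representative_rows: dict[str, str]  # group -> row id used for structures

    @property
    def binding_columns(self) -> list[int]:
        return sorted(self.planted_columns + self.catalytic_columns)


def _group_name(g: int) -> str:
    return f"F{g + 1}"


def simulate_family(
    cfg: SimulationConfig,
) -> tuple[GroupedAlignment, FamilyTruth]:
    """Generate a grouped alignment with planted SDP structure."""
    rng = np.random.default_rng(cfg.seed)
    L, G, N = cfg.alignment_length, cfg.n_groups, cfg.n_seqs_per_group
    aa = np.array(list(AA_ALPHABET))

    cols = rng.choice(L, size=cfg.n_planted_sdps + cfg.n_catalytic_columns
                      + cfg.n_distal_specific_columns, replace=False)
    planted = sorted(int(c) for c in cols[: cfg.n_planted_sdps])
    catalytic = sorted(
        int(c)
        for c in cols[cfg.n_planted_sdps: cfg.n_planted_sdps
                      + cfg.n_catalytic_columns]
    )
    distal = sorted(int(c) for c in cols[cfg.n_planted_sdps
                                         + cfg.n_catalytic_columns:])

    group_specific = planted + distal
    # background: one Dirichlet profile per column, shared by all groups
    profiles = rng.dirichlet(
        np.full(20, cfg.background_concentration), size=L
    )
    special = set(group_specific) | set(catalytic)
    matrix = np.empty((G * N, L), dtype="<U1")
    for c in range(L):
        if c in special:
            continue
        matrix[:, c] = rng.choice(aa, size=G * N, p=profiles[c])
    catalytic_picks = []
    for c in catalytic:
        pick = str(rng.choice(aa))
        catalytic_picks.append(pick)
        matrix[:, c] = pick
    group_res: dict[str, list[str]] = {_group_name(g): [] for g in range(G)}
    for c in sorted(group_specific):
        picks = rng.choice(20, size=G, replace=False)
        for g in range(G):
            matrix[g * N: (g + 1) * N, c] = aa[picks[g]]
            group_res[_group_name(g)].append(str(aa[picks[g]]))
    # within-group substitution noise on group-specific and catalytic columns
    eps = cfg.within_group_noise
    if eps > 0:
        for c in special:
            flip = rng.random(G * N) < eps
            for i in np.where(flip)[0]:
                current = matrix[i, c]
                others = [x for x in AA_ALPHABET if x != current]
                matrix[i, c] = others[rng.integers(len(others))]

    row_ids, labels = [], []
    for g in range(G):
        for i in range(N):
            row_ids.append(f"{_group_name(g)}_s{i + 1}")
            labels.append(_group_name(g))
    aln = Alignment(row_ids=row_ids, matrix=["".join(r) for r in matrix])
    galn = GroupedAlignment(alignment=aln, group_labels=labels)
    truth = FamilyTruth(
        planted_columns=planted,
        catalytic_columns=catalytic,
        distal_columns=distal,
        group_residues={g: "".join(v) for g, v in group_res.items()},
        catalytic_residues="".join(catalytic_picks),
        group_labels=labels,
        representative_rows={
            _group_name(g): f"{_group_name(g)}_s1" for g in range(G)
        },
    )
    return galn, truth


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

@dataclass
class ToyStructure:
    pdb_id: str
    chain: str
    ligand_name: str
    row_id: str
    pdb_text: str


_PDB_ATOM = (
    "{kind:<6s}{serial:>5d} {name:^4s} {resname:>3s} {chain:1s}"
    "{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}"
)

BINDING_RADIUS = 3.5
DISTAL_RADIUS = 8.0


def _sphere_directions(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit vectors."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta),
         np.cos(phi)], axis=1
    )


def simulate_structures(
    galn: GroupedAlignment, truth: FamilyTruth, cfg: SimulationConfig
) -> list[ToyStructure]:
    """One CA-only ligand complex per group, honouring the 4-A contract.

    The chain sequence is the group's representative alignment row (so the
    structure maps back onto the master alignment exactly); the single
    ligand atom sits at the origin, binding-column residues on a 3.5-A
    shell and every other residue at 8 A or beyond.
    """
    binding = set(truth.binding_columns)
    structures = []
    for gi, (group, row_id) in enumerate(sorted(
        truth.representative_rows.items()
    )):
        seq = galn.alignment.degap(row_id)
        n = len(seq)
        dirs = _sphere_directions(n)
        lines = []
        serial = 1
        for i, aa in enumerate(seq):
            radius = (
                BINDING_RADIUS if i in binding
                else DISTAL_RADIUS + 0.01 * i
            )
            x, y, z = dirs[i] * radius
            lines.append(
                _PDB_ATOM.format(
                    kind="ATOM", serial=serial, name=" CA ",
                    resname=seq3(aa).upper(), chain="A", resseq=i + 1,
                    x=x, y=y, z=z, occ=1.0, b=0.0, element="C",
                )
            )
            serial += 1
        lines.append(
            _PDB_ATOM.format(
                kind="HETATM", serial=serial, name=" C1 ", resname="LIG",
                chain="L", resseq=1, x=0.0, y=0.0, z=0.0, occ=1.0, b=0.0,
                element="C",
            )
        )
        lines.append("END")
        structures.append(
            ToyStructure(
                pdb_id=f"TOY{gi + 1}",
                chain="A",
                ligand_name="LIG",
                row_id=row_id,
                pdb_text="\n".join(lines) + "\n",
            )
        )
    return structures


# ---------------------------------------------------------------------------
# function evolution on a random tree
# ---------------------------------------------------------------------------

def simulate_function_evolution(
    n_leaves: int,
    n_functions: int = 9,
    change_rate: float = 0.02,
    seed=None,
) -> tuple[LabeledTree, dict[str, int]]:
    """Evolve function states root-to-tip on a random bifurcating tree.

    Each edge switches to a uniformly chosen different function with
    probability ``change_rate``.  Returns the labelled tree and the true
    origin count per function: the number of gain edges plus one for the
    root's own state.  Functions gained but later completely overwritten
    still count, so at high change rates the truth may exceed what any
    leaf-based method can see.
    """
    if n_leaves < 4:
        raise ValueError("need at least four leaves")
    rng = np.random.default_rng(seed)
    root = TreeNode(children=[TreeNode(length=1.0), TreeNode(length=1.0)])
    tips = list(root.children)
    while len(tips) < n_leaves:
        k = int(rng.integers(len(tips)))
        node = tips.pop(k)
        left, right = TreeNode(length=1.0), TreeNode(length=1.0)
        node.extend([left, right])
        tips.extend([left, right])
    for i, tip in enumerate(root.tips()):
        tip.name = f"T{i + 1}"

    functions = [f"fn{i + 1}" for i in range(n_functions)]
    root_state = functions[int(rng.integers(n_functions))]
    origins: dict[str, int] = {root_state: 1}
    labels: dict[str, str] = {}

    def descend(node: TreeNode, state: str) -> None:
        for child in node.children:
            child_state = state
            if rng.random() < change_rate:
                others = [f for f in functions if f != state]
                child_state = others[int(rng.integers(len(others)))]
                origins[child_state] = origins.get(child_state, 0) + 1
            if child.is_tip():
                labels[child.name] = child_state
            else:
                descend(child, child_state)

    descend(root, root_state)
    return LabeledTree(tree=root, labels=labels), origins


# ---------------------------------------------------------------------------
# operonised gene tables
# ---------------------------------------------------------------------------

def simulate_genomes(
    candidates: list[tuple[str, str]],
    ctx: PathwayContextMap,
    seed=None,
    n_decoys: int = 0,
    genome_id: str = "G1",
) -> tuple[list[GeneRecord], dict[str, list[str]]]:
    """Gene tables with planted operon context and shuffled-context decoys.

    Each ``(gene_id, function)`` candidate is placed on its own contig next
    to a same-strand pathway partner within operon distance.  Decoys get a
    neighbour whose label is NOT a partner of their nominal function.
    Returns the gene list and a truth map with ``planted`` and ``decoy``
    gene ids.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    planted_ids, decoy_ids = [], []
    all_labels = sorted({p for ps in ctx.partners.values() for p in ps})
    contig_no = 0

    def place(gene_id: str, fn: str, neighbor_label: str) -> None:
        nonlocal contig_no
        contig_no += 1
        contig = f"c{contig_no}"
        start = int(rng.integers(1000, 5000))
        length = int(rng.integers(700, 1200))
        gap = int(rng.integers(20, 250))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(
                gene_id=gene_id, genome_id=genome_id, contig=contig,
                start=start, end=start + length, strand=strand,
                function_label="",
            )
        )
        nstart = start + length + gap
        genes.append(
            GeneRecord(
                gene_id=f"{gene_id}_nbr", genome_id=genome_id, contig=contig,
                start=nstart, end=nstart + 900, strand=strand,
                function_label=neighbor_label,
            )
        )

    for gene_id, fn in candidates:
        partner = sorted(ctx[fn])[int(rng.integers(len(ctx[fn])))]
        place(gene_id, fn, partner)
        planted_ids.append(gene_id)
    for d in range(n_decoys):
        fn = candidates[d % len(candidates)][1]
        non_partners = [x for x in all_labels if x not in ctx[fn]] or ["orf"]
        label = non_partners[int(rng.integers(len(non_partners)))]
        gene_id = f"decoy{d + 1}"
        place(gene_id, fn, label)
        decoy_ids.append(gene_id)
    return genes, {"planted": planted_ids, "decoy": decoy_ids}


def make_reference_fixture(path=None):
    """The packaged family reference table (optionally copied to ``path``)."""
    table = load_reference_table()
    if path is not None:
        table.frame.to_csv(path, sep="\t", index=False)
    return table
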