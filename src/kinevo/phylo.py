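"""Trees, rooting, bootstrap support, and counting function origins.

The central evolutionary question for a multi-functional family is whether
each substrate specificity arose once (simple divergent evolution) or was
re-invented in separate lineages (convergent evolution).  With function
labels on the leaves of a rooted protein tree, Fitch small parsimony gives
the minimal number of label changes; for each function the module reports
the minimal number of independent origins over all most-parsimonious
reconstructions (the root's state counts as one origin) and whether the
function's leaves are monophyletic.

Externally inferred trees (Newick) are first-class inputs; a native
neighbour-joining builder is provided for desk-scale distance matrices, and
bootstrap support comes from column resampling with NJ per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .family_io import GAP, Alignment

logger = logging.getLogger(__name__)

INF = float("inf")

__all__ = [
    "LabeledTree",
    "OriginReport",
    "nj_tree",
    "root_with_outgroup",
    "bootstrap_support",
    "fitch_origins",
    "taxon_distribution",
    "p_distance_matrix",
]


@dataclass
class LabeledTree:
    """A rooted tree whose leaves carry function labels."""

    tree: TreeNode
    labels: dict[str, str]

    def __post_init__(self) -> None:
        tips = {t.name for t in self.tree.tips()}
        unlabeled = tips - set(self.labels)
        if unlabeled:
            raise ValueError(f"unlabeled leaves: {sorted(unlabeled)}")

    @property
    def functions(self) -> list[str]:
        return sorted(set(self.labels.values()))


def nj_tree(dm: DistanceMatrix | np.ndarray, ids=None) -> TreeNode:
    """Canonical neighbour joining; returns an unrooted (trifurcating) tree."""
    if not isinstance(dm, DistanceMatrix):
        arr = np.asarray(dm, dtype=float)
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be symmetric")
        dm = DistanceMatrix(arr, ids=list(ids))
    return _skbio_nj(dm)


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise p-distances (fraction of differing, mutually non-gap sites)."""
    rows = np.array([list(r) for r in aln.matrix])
    n = len(rows)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (rows[i] != GAP) & (rows[j] != GAP)
            m = int(ok.sum())
            d = float((rows[i][ok] != rows[j][ok]).mean()) if m else 1.0
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids=list(aln.row_ids))


def _tipset(node: TreeNode) -> frozenset[str]:
    if node.is_tip():
        return frozenset([node.name])
    return frozenset(t.name for t in node.tips())


def root_with_outgroup(
    tree: TreeNode,
    outgroup,
    labels: dict[str, str] | None = None,
    remove_outgroup: bool = False,
) -> TreeNode | LabeledTree:
    """Root an unrooted tree on the edge separating the outgroup.

    The outgroup leaves must form one side of an edge of the unrooted tree.
    With ``remove_outgroup=True`` the outgroup subtree is pruned after
    rooting.  If ``labels`` is given, a :class:`LabeledTree` over the
    retained leaves is returned.
    """
    outgroup = frozenset(outgroup)
    tips = _tipset(tree)
    if not outgroup or not outgroup <= tips:
        raise ValueError("outgroup must be a non-empty subset of the leaves")
    if outgroup == tips:
        raise ValueError("outgroup cannot contain every leaf")
    target = None
    for node in tree.traverse(include_self=False):
        side = _tipset(node)
        # the outgroup is a clade if it is either side of some edge
        if side == outgroup or tips - side == outgroup:
            target = node
            if side == outgroup:
                break
    if target is None:
        raise ValueError("outgroup does not form a clade in the unrooted tree")
    rooted = tree.root_at(target, above=True, reset=True)
    if remove_outgroup:
        keep = sorted(tips - outgroup)
        rooted = rooted.shear(keep)
        rooted.prune()
    if labels is not None:
        kept = {t.name for t in rooted.tips()}
        return LabeledTree(
            tree=rooted, labels={k: v for k, v in labels.items() if k in kept}
        )
    return rooted


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalised to the side not holding
    the alphabetically first taxon."""
    tips = sorted(_tipset(tree))
    anchor = tips[0]
    out = set()
    for node in tree.non_tips(include_self=False):
        side = _tipset(node)
        if len(side) <= 1 or len(side) >= len(tips) - 1:
            continue
        if anchor in side:
            side = frozenset(tips) - side
        out.add(side)
    return out


def bootstrap_support(
    aln: Alignment, n_reps: int = 100, seed=None
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree plus column-resampling bootstrap support per bipartition.

    Support is the percentage (0-100) of replicate NJ trees containing each
    bipartition of the original tree; it is written onto the internal node
    names of the returned tree.
    """
    if aln.length < 2:
        raise ValueError("alignment must have at least two columns")
    rng = np.random.default_rng(seed)
    base = nj_tree(p_distance_matrix(aln))
    target = _bipartitions(base)
    hits = {bp: 0 for bp in target}
    L = aln.length
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rows = ["".join(r[c] for c in cols) for r in aln.matrix]
        rep = nj_tree(p_distance_matrix(Alignment(list(aln.row_ids), rows)))
        found = _bipartitions(rep)
        for bp in target & found:
            hits[bp] += 1
    support = {bp: 100.0 * hits[bp] / n_reps for bp in target}
    tips = sorted(_tipset(base))
    anchor = tips[0]
    for node in base.non_tips(include_self=False):
        side = _tipset(node)
        if len(side) <= 1 or len(side) >= len(tips) - 1:
            continue
        key = side if anchor not in side else frozenset(tips) - side
        node.name = f"{support[key]:.0f}"
    return base, support


# ---------------------------------------------------------------------------
# Fitch parsimony origin counting
# ---------------------------------------------------------------------------

def _resolved_copy(node: TreeNode) -> TreeNode:
    """Deterministically bifurcated deep copy (children folded in the order
    of their smallest tip name)."""
    if node.is_tip():
        return TreeNode(name=node.name, length=node.length)
    children = [_resolved_copy(ch) for ch in node.children]
    children.sort(key=lambda ch: min(t.name for t in ch.tips(include_self=True)))
    while len(children) > 2:
        a = children.pop(0)
        b = children.pop(0)
        merged = TreeNode(children=[a, b], length=0.0)
        children.insert(0, merged)
    return TreeNode(name=node.name, length=node.length, children=children)


@dataclass
class OriginReport:
    """Parsimony summary: origins and monophyly per function."""

    total_changes: int
    origins: dict[str, int]
    monophyletic: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "function": sorted(self.origins),
                "origins": [self.origins[f] for f in sorted(self.origins)],
                "monophyletic": [
                    self.monophyletic[f] for f in sorted(self.origins)
                ],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fitch_origins(ltree: LabeledTree) -> OriginReport:
    """Minimal changes and per-function minimal origin counts.

    Dynamic programming over unordered states.  For each function ``f`` the
    origin count is the minimum, across most-parsimonious reconstructions,
    of the number of edges whose child gains state ``f``, plus one if the
    root itself carries ``f``.  Multifurcations are resolved
    deterministically (label order) beforehand; a monophyletic function
    always has exactly one origin.
    """
    states = ltree.functions
    idx = {s: i for i, s in enumerate(states)}
    S = len(states)
    tree = _resolved_copy(ltree.tree)

    cost: dict[int, np.ndarray] = {}
    gains: dict[int, np.ndarray] = {}  # (S states) x (S functions)
    for node in tree.postorder(include_self=True):
        key = id(node)
        if node.is_tip():
            c = np.full(S, INF)
            c[idx[ltree.labels[node.name]]] = 0.0
            cost[key] = c
            gains[key] = np.zeros((S, S))
            continue
        c = np.zeros(S)
        g = np.zeros((S, S))
        for ch in node.children:
            cc, cg = cost[id(ch)], gains[id(ch)]
            # edge cost of assigning child state t given parent state s
            trans = cc[None, :] + (1.0 - np.eye(S))  # (s, t)
            best = trans.min(axis=1)
            c += best
            # min gains among optimal child states, per function f
            gain_edge = np.zeros((S, S, S))  # (s, t, f)
            for t in range(S):
                gain_edge[:, t, t] += 1.0
                gain_edge[t, t, t] -= 1.0  # no gain if parent already has f
            tot = cg[None, :, :] + gain_edge  # (s, t, f)
            optimal = trans <= best[:, None] + 1e-9  # (s, t)
            masked = np.where(optimal[:, :, None], tot, INF)
            g += masked.min(axis=1)
        cost[key] = c
        gains[key] = g

    root_cost = cost[id(tree)]
    root_gain = gains[id(tree)]
    total = root_cost.min()
    best_states = np.where(root_cost <= total + 1e-9)[0]
    origins: dict[str, int] = {}
    present = sorted(set(ltree.labels.values()))
    for f in present:
        fi = idx[f]
        vals = [root_gain[s, fi] + (1.0 if s == fi else 0.0) for s in best_states]
        origins[f] = int(round(min(vals)))

    monophyletic = {}
    for f in present:
        members = [k for k, v in ltree.labels.items() if v == f]
        if len(members) == 1:
            monophyletic[f] = True
            continue
        lca = ltree.tree.lca(members)
        monophyletic[f] = _tipset(lca) == frozenset(members)

    return OriginReport(
        total_changes=int(round(total)),
        origins=origins,
        monophyletic=monophyletic,
    )


# ---------------------------------------------------------------------------
# species-tree function projection
# ---------------------------------------------------------------------------

def taxon_distribution(
    annotations: pd.DataFrame,
    species_tree: TreeNode,
    collapse_level: int = 1,
    functions=None,
) -> pd.DataFrame:
    """Fraction of species per taxonomic group carrying each function.

    ``annotations`` needs columns ``genome_id``, ``species`` and
    ``function``: one row per protein.  Strains (distinct genomes of one
    species) are averaged into a single species entry first; the taxonomic
    group of a species is the named ancestor at depth ``collapse_level``
    from the root of the species tree (the species itself if shallower).
    Species absent from the tree are excluded with a warning.
    """
    required = {"genome_id", "species", "function"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotations need columns {sorted(required)}")
    tip_names = {t.name for t in species_tree.tips()}
    taxon_of: dict[str, str] = {}
    for tip in species_tree.tips():
        anc = list(tip.ancestors())[::-1]  # root first
        path = anc[1:] + [tip]             # drop root
        node = path[min(collapse_level - 1, len(path) - 1)]
        taxon_of[tip.name] = node.name or tip.name

    frame = annotations.copy()
    missing = sorted(set(frame["species"]) - tip_names)
    if missing:
        logger.warning("species absent from tree, excluded: %s", missing)
        frame = frame[~frame["species"].isin(missing)]
    if functions is None:
        functions = sorted(set(frame["function"]))

    strains = (
        frame[["species", "genome_id"]]
        .drop_duplicates()
        .groupby("species")["genome_id"]
        .apply(set)
        .to_dict()
    )
    rows = []
    species_by_taxon: dict[str, set[str]] = {}
    for sp in strains:
        species_by_taxon.setdefault(taxon_of[sp], set()).add(sp)
    has = (
        frame[["species", "genome_id", "function"]]
        .drop_duplicates()
        .groupby(["species", "function"])["genome_id"]
        .apply(set)
        .to_dict()
    )
    for taxon in sorted(species_by_taxon):
        members = sorted(species_by_taxon[taxon])
        for fn in functions:
            frac = float(
                np.mean(
                    [
                        len(has.get((sp, fn), set())) / len(strains[sp])
                        for sp in members
                    ]
                )
            )
            rows.append((taxon, fn, frac, len(members)))
    return pd.DataFrame(
        rows, columns=["taxon", "function", "fraction", "n_species"]
    )
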