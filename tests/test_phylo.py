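import itertools
from io import StringIO

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from kinevo.family_io import Alignment
from kinevo.phylo import (
    LabeledTree,
    _bipartitions,
    _resolved_copy,
    bootstrap_support,
    fitch_origins,
    nj_tree,
    root_with_outgroup,
    taxon_distribution,
)
from kinevo.synth import simulate_function_evolution


def tree(newick):
    return TreeNode.read(StringIO(newick))


def exhaustive_min_changes(ltree):
    """Oracle: minimise changes over every internal labeling."""
    t = _resolved_copy(ltree.tree)
    internals = [n for n in t.traverse(include_self=True) if not n.is_tip()]
    states = sorted(set(ltree.labels.values()))
    best = float("inf")
    for combo in itertools.product(states, repeat=len(internals)):
        assign = dict(zip(map(id, internals), combo))
        changes = 0
        for n in t.traverse(include_self=True):
            if n.parent is None:
                continue
            s = ltree.labels[n.name] if n.is_tip() else assign[id(n)]
            changes += s != assign[id(n.parent)]
        best = min(best, changes)
    return best


class TestNjTree:
    def test_additive_four_taxon_matrix_inverted(self):
        # distances from ((A:1,B:2):1,(C:3,D:1):2)
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 7, 5], [3, 0, 8, 6], [7, 8, 0, 4], [5, 6, 4, 0]],
            dtype=float,
        )
        assert _bipartitions(nj_tree(d, ids)) == {frozenset({"C", "D"})}

    def test_three_taxa_star(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        t = nj_tree(d, ["a", "b", "c"])
        assert _bipartitions(t) == set()

    def test_cherry_pairs_from_ultrametric_matrix(self):
        ids = ["a", "b", "c", "d"]
        d = np.array(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 1], [4, 4, 1, 0]],
            dtype=float,
        )
        assert _bipartitions(nj_tree(d, ids)) == {frozenset({"c", "d"})} or \
            _bipartitions(nj_tree(d, ids)) == {frozenset({"a", "b"})}

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1], [2, 0]], dtype=float), ["a", "b"])


class TestRooting:
    def test_single_leaf_outgroup(self):
        rooted = root_with_outgroup(tree("((a,b),(c,o));"), ["o"])
        sides = [frozenset(t.name for t in ch.tips()) or frozenset([ch.name])
                 for ch in rooted.children]
        assert frozenset(["o"]) in [
            s if s else frozenset() for s in sides
        ] or any(ch.name == "o" for ch in rooted.children)

    def test_two_leaf_outgroup_clade(self):
        rooted = root_with_outgroup(
            tree("((a,b),(c,(o1,o2)));"), ["o1", "o2"]
        )
        sides = [
            frozenset(t.name for t in ch.tips()) for ch in rooted.children
        ]
        assert frozenset(["o1", "o2"]) in sides

    def test_all_leaves_rejected(self):
        with pytest.raises(ValueError):
            root_with_outgroup(tree("(a,b,c);"), ["a", "b", "c"])

    def test_non_clade_rejected(self):
        with pytest.raises(ValueError, match="clade"):
            root_with_outgroup(tree("((a,o1),(b,o2));"), ["o1", "o2"])

    def test_outgroup_removal_and_labels(self):
        lt = root_with_outgroup(
            tree("((a,b),(c,(o1,o2)));"),
            ["o1", "o2"],
            labels={"a": "f1", "b": "f1", "c": "f2"},
            remove_outgroup=True,
        )
        assert isinstance(lt, LabeledTree)
        assert {t.name for t in lt.tree.tips()} == {"a", "b", "c"}


class TestFitchOrigins:
    def test_uniform_labels(self):
        lt = LabeledTree(
            tree=tree("((a,b),(c,d));"),
            labels=dict.fromkeys("abcd", "f1"),
        )
        rep = fitch_origins(lt)
        assert rep.total_changes == 0
        assert rep.origins == {"f1": 1}
        assert rep.monophyletic == {"f1": True}

    def test_two_clades(self):
        lt = LabeledTree(
            tree=tree("((a,b),(c,d));"),
            labels={"a": "f1", "b": "f1", "c": "f2", "d": "f2"},
        )
        rep = fitch_origins(lt)
        assert rep.total_changes == 1
        assert rep.origins == {"f1": 1, "f2": 1}
        assert rep.monophyletic == {"f1": True, "f2": True}

    def test_interleaved_clades(self):
        # ((f1,f2),(f1,f2)): two changes; each function can be ancestral in
        # some most-parsimonious labeling, so each has minimal origin 1
        lt = LabeledTree(
            tree=tree("((a,b),(c,d));"),
            labels={"a": "f1", "b": "f2", "c": "f1", "d": "f2"},
        )
        rep = fitch_origins(lt)
        assert rep.total_changes == 2
        assert rep.origins == {"f1": 1, "f2": 1}
        assert rep.monophyletic == {"f1": False, "f2": False}

    def test_forced_double_origin(self):
        # f2 twice, separated by two f1 cherries: f2 cannot be ancestral
        lt = LabeledTree(
            tree=tree("(((a,b),(c,e)),((d,f),(g,h)));"),
            labels={
                "a": "f1", "b": "f1", "c": "f2", "e": "f1",
                "d": "f1", "f": "f1", "g": "f2", "h": "f1",
            },
        )
        rep = fitch_origins(lt)
        assert rep.total_changes == 2
        assert rep.origins["f2"] == 2

    def test_unlabeled_leaf_rejected(self):
        with pytest.raises(ValueError, match="unlabeled"):
            LabeledTree(tree=tree("(a,b);"), labels={"a": "f1"})

    def test_matches_exhaustive_oracle_small_trees(self):
        rng = np.random.default_rng(1)
        for s in range(40):
            n = int(rng.integers(4, 9))
            lt, _ = simulate_function_evolution(
                n, n_functions=3, change_rate=0.5, seed=500 + s
            )
            if len(set(lt.labels.values())) < 2:
                continue
            assert fitch_origins(lt).total_changes == exhaustive_min_changes(
                lt
            )

    def test_origin_accounting_identity(self):
        rng = np.random.default_rng(2)
        for s in range(30):
            lt, _ = simulate_function_evolution(
                int(rng.integers(4, 12)), 4, 0.4, seed=900 + s
            )
            rep = fitch_origins(lt)
            assert sum(rep.origins.values()) <= rep.total_changes + 1
            assert all(v >= 1 for v in rep.origins.values())
            for fn, mono in rep.monophyletic.items():
                if mono:
                    assert rep.origins[fn] == 1


class TestBootstrap:
    def test_clean_signal_full_support(self):
        rows = ["AAAAAAAAAA", "AAAAAAAAAA", "AAAAATTTTT",
                "TTTTTTTTTT", "TTTTTTTTTT"]
        aln = Alignment(["a", "b", "e", "c", "d"], rows)
        _, support = bootstrap_support(aln, n_reps=50, seed=0)
        assert support
        assert all(0 <= v <= 100 for v in support.values())
        assert max(support.values()) == 100.0

    def test_no_signal_low_support(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACDE"), size=30)) for _ in range(8)]
        aln = Alignment([f"s{i}" for i in range(8)], rows)
        _, support = bootstrap_support(aln, n_reps=50, seed=1)
        assert min(support.values()) < 60.0


class TestTaxonDistribution:
    def _tree(self):
        return tree("((sp1,sp2)taxA,(sp3,sp4)taxB)root;")

    def test_simple_fraction(self):
        ann = pd.DataFrame(
            {
                "genome_id": ["g1", "g2", "g3", "g4"],
                "species": ["sp1", "sp2", "sp3", "sp4"],
                "function": ["GlpK", "XylB", "GlpK", "GlpK"],
            }
        )
        dist = taxon_distribution(ann, self._tree(), collapse_level=1)
        out = dist.set_index(["taxon", "function"])["fraction"]
        assert out["taxA", "GlpK"] == pytest.approx(0.5)
        assert out["taxB", "GlpK"] == pytest.approx(1.0)
        assert out["taxB", "XylB"] == pytest.approx(0.0)

    def test_strain_averaging(self):
        # two strains of sp1, one carrying the function -> half a species
        ann = pd.DataFrame(
            {
                "genome_id": ["g1a", "g1b", "g2"],
                "species": ["sp1", "sp1", "sp2"],
                "function": ["GlpK", "none", "none"],
            }
        )
        dist = taxon_distribution(
            ann, self._tree(), collapse_level=1, functions=["GlpK"]
        )
        out = dist.set_index(["taxon", "function"])["fraction"]
        assert out["taxA", "GlpK"] == pytest.approx(0.25)  # (0.5 + 0)/2

    def test_unmapped_species_excluded(self, caplog):
        ann = pd.DataFrame(
            {
                "genome_id": ["g1", "gX"],
                "species": ["sp1", "spX"],
                "function": ["GlpK", "GlpK"],
            }
        )
        with caplog.at_level("WARNING"):
            dist = taxon_distribution(ann, self._tree(), collapse_level=1)
        assert "spX" in caplog.text
        assert set(dist["taxon"]) == {"taxA"}
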