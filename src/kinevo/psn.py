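"""Protein similarity networks (PSNs) on full and signature sequences.

Nodes are function-labelled proteins; an edge joins two proteins whose
pairwise alignment is more significant than an E-value threshold.  Full
sequences are compared by Smith-Waterman local alignment (BLOSUM62, affine
gaps); signature sequences, being short and equal-length, by an ungapped
positional BLOSUM62 sum.  Raw scores are converted to bit scores with fixed
ungapped Karlin-Altschul constants and to E-values as ``m * n * 2^-bits``;
the E-values are comparative devices for threshold sweeps, not calibrated
database statistics.

Comparing the component structure of the full-sequence and the
signature-sequence networks quantifies how much of the functional
partitioning survives the reduction to a handful of SDP residues.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from sklearn.metrics import adjusted_rand_score

from .family_io import GAP

__all__ = [
    "KARLIN_LAMBDA",
    "KARLIN_K",
    "pairwise_score",
    "build_score_table",
    "build_network",
    "functional_purity",
    "partition_agreement",
    "component_partition",
    "sweep_thresholds",
]

# Ungapped Karlin-Altschul constants for BLOSUM62 (documented fixed values).
KARLIN_LAMBDA = 0.3176
KARLIN_K = 0.134

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _bits_and_evalue(score: float, m: int, n: int) -> tuple[float, float]:
    bits = (KARLIN_LAMBDA * score - math.log(KARLIN_K)) / math.log(2.0)
    return bits, m * n * 2.0 ** (-bits)


def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_score(
    a: str, b: str, mode: str = "full"
) -> tuple[float, float, float]:
    """Score one sequence pair: ``(raw_score, bit_score, evalue)``.

    ``mode='full'``: Smith-Waterman local alignment with affine gaps.
    ``mode='signature'``: ungapped positional BLOSUM62 sum over equal-length
    signatures; positions where either signature is gapped contribute 0.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if mode == "full":
        score = float(_local_aligner().score(a, b))
    elif mode == "signature":
        if len(a) != len(b):
            raise ValueError("signature mode requires equal lengths")
        score = float(
            sum(
                _BLOSUM62[x, y]
                for x, y in zip(a, b)
                if x != GAP and y != GAP
            )
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    bits, evalue = _bits_and_evalue(score, len(a), len(b))
    return score, bits, evalue


def build_score_table(
    sequences: dict[str, str], mode: str = "full"
) -> pd.DataFrame:
    """All-against-all pairwise scores (unordered pairs, symmetric)."""
    rows = []
    for i, j in itertools.combinations(sorted(sequences), 2):
        score, bits, evalue = pairwise_score(sequences[i], sequences[j], mode)
        rows.append((i, j, score, bits, evalue, mode))
    return pd.DataFrame(
        rows, columns=["id1", "id2", "score", "bits", "evalue", "mode"]
    )


def build_network(
    scores: pd.DataFrame,
    threshold: float,
    labels: dict[str, str] | None = None,
) -> nx.Graph:
    """Thresholded similarity graph: edge iff ``evalue < threshold``.

    Every protein appearing in the score table (and every labelled protein)
    is a node, so isolates are kept and purity/partition statistics run on
    a fixed universe.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    net = nx.Graph(threshold=threshold)
    universe = set(scores["id1"]) | set(scores["id2"])
    if labels:
        universe |= set(labels)
    for node in sorted(universe):
        net.add_node(node, function=(labels or {}).get(node, ""))
    hits = scores[scores["evalue"] < threshold]
    for row in hits.itertuples():
        net.add_edge(row.id1, row.id2, evalue=row.evalue, bits=row.bits)
    return net


def functional_purity(net: nx.Graph) -> float:
    """Fraction of edges whose endpoints share a function label."""
    if net.number_of_edges() == 0:
        raise ValueError("purity undefined for an edgeless network")
    same = sum(
        1
        for u, v in net.edges
        if net.nodes[u]["function"] == net.nodes[v]["function"]
    )
    return same / net.number_of_edges()


def component_partition(net: nx.Graph) -> dict[str, int]:
    """Connected-component index per node, deterministic by sorted node id."""
    out: dict[str, int] = {}
    comps = sorted(
        (sorted(c) for c in nx.connected_components(net)), key=lambda c: c[0]
    )
    for k, comp in enumerate(comps):
        for node in comp:
            out[node] = k
    return out


def partition_agreement(net1: nx.Graph, net2: nx.Graph) -> float:
    """Adjusted Rand index between the component partitions of two PSNs."""
    if set(net1.nodes) != set(net2.nodes):
        raise ValueError("networks must share an identical node set")
    nodes = sorted(net1.nodes)
    p1 = component_partition(net1)
    p2 = component_partition(net2)
    return float(
        adjusted_rand_score([p1[n] for n in nodes], [p2[n] for n in nodes])
    )


def sweep_thresholds(
    scores: pd.DataFrame,
    labels: dict[str, str],
    ladder=None,
) -> pd.DataFrame:
    """Evaluate the component partition along a threshold ladder.

    For each threshold: number of edges and components, edge purity (NaN if
    edgeless), and whether the components coincide exactly with the function
    labels.  Default ladder: midpoints between consecutive distinct
    E-values, bracketed by extremes, so every achievable network appears.
    """
    if ladder is None:
        ev = np.sort(scores["evalue"].unique())
        mids = np.sqrt(ev[:-1] * ev[1:]) if len(ev) > 1 else np.array([])
        ladder = np.concatenate(([ev[0] * 0.5], mids, [ev[-1] * 2.0]))
    want = {n: lab for n, lab in labels.items()}
    rows = []
    for thr in ladder:
        net = build_network(scores, float(thr), labels)
        part = component_partition(net)
        exact = adjusted_rand_score(
            [want[n] for n in sorted(want)], [part[n] for n in sorted(want)]
        ) == 1.0 and len(set(part.values())) == len(set(want.values()))
        try:
            purity = functional_purity(net)
        except ValueError:
            purity = math.nan
        rows.append(
            (
                float(thr),
                net.number_of_edges(),
                len(set(part.values())),
                purity,
                bool(exact),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "threshold", "n_edges", "n_components", "purity",
            "matches_functions",
        ],
    )


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def write_edge_list(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False)
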