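"""Signature sequences, per-cluster PWMs, and signature clustering.

A protein's signature is the concatenation of its residues at the selected
SDP columns (length 5 in the FGGY kinase family).  Each 30%-identity cluster
of an isofunctional group gets a 20 x k position weight matrix (PWM) of
residue frequencies over its signatures; PWMs are compared by the Pearson
correlation of their flattened entries (the 2-D ``corr2`` statistic) and
grouped by average-linkage hierarchical clustering on 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .family_io import AA_ALPHABET, GAP, Alignment

__all__ = [
    "SignatureSequence",
    "PositionWeightMatrix",
    "SignatureDendrogram",
    "extract_signature",
    "build_pwm",
    "pwm_correlation",
    "cluster_signatures",
    "column_information_content",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@dataclass(frozen=True)
class SignatureSequence:
    """Residues of one protein at the selected SDP columns, sequence order."""

    protein_id: str
    residues: str
    group_label: str = ""
    cluster_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)


def extract_signature(
    master: Alignment,
    row_id: str,
    selected_columns,
    group_label: str = "",
    cluster_id: str = "",
) -> SignatureSequence:
    """Read a row's residues off the selected columns, ascending order.

    Columns gapped in the row contribute '-'.
    """
    row = master.row(row_id)
    cols = sorted(selected_columns)
    for c in cols:
        if not 0 <= c < len(row):
            raise IndexError(f"column {c} out of range for alignment")
    return SignatureSequence(
        protein_id=row_id,
        residues="".join(row[c] for c in cols),
        group_label=group_label,
        cluster_id=cluster_id,
    )


@dataclass
class PositionWeightMatrix:
    """20 x k residue-frequency matrix over one cluster's signatures.

    Rows follow the alphabetical amino-acid order; each column is normalised
    over its contributing (non-gap) signatures, so columns sum to 1.
    """

    matrix: np.ndarray
    n_sequences: int
    label: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 20:
            raise ValueError("PWM must have 20 rows")
        if ((self.matrix < 0) | (self.matrix > 1)).any():
            raise ValueError("PWM entries must lie in [0, 1]")

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=list(AA_ALPHABET),
            columns=[f"pos{j + 1}" for j in range(self.k)],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def build_pwm(signatures, label: str = "") -> PositionWeightMatrix:
    """Raw per-column residue frequencies of one cluster's signatures.

    Gaps carry no frequency mass (the 20-row shape is fixed); no
    pseudocounts are added.
    """
    sigs = list(signatures)
    if not sigs:
        raise ValueError("need at least one signature")
    k = len(sigs[0])
    if any(len(s) != k for s in sigs):
        raise ValueError("signatures differ in length")
    counts = np.zeros((20, k))
    for s in sigs:
        for j, aa in enumerate(s.residues):
            if aa == GAP:
                continue
            counts[_AA_INDEX[aa], j] += 1
    colsum = counts.sum(axis=0)
    if (colsum == 0).any():
        bad = np.where(colsum == 0)[0] + 1
        raise ValueError(f"signature position(s) {list(bad)} entirely gapped")
    return PositionWeightMatrix(
        matrix=counts / colsum, n_sequences=len(sigs), label=label
    )


def pwm_correlation(
    m1: PositionWeightMatrix, m2: PositionWeightMatrix
) -> float:
    """Pearson correlation over all 20 x k entries flattened (corr2)."""
    a = m1.matrix.ravel()
    b = m2.matrix.ravel()
    if a.shape != b.shape:
        raise ValueError("PWMs differ in shape")
    if a.std() < 1e-12 or b.std() < 1e-12:
        raise ValueError("correlation undefined for a constant PWM")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class SignatureDendrogram:
    """Average-linkage merge tree over PWM labels at height 1 - r."""

    labels: list[str]
    linkage: np.ndarray
    correlation: pd.DataFrame  # symmetric heat-map matrix

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            length = node.dist
            parts = ",".join(
                f"{render(ch)}:{length - ch.dist:.6f}"
                for ch in (node.get_left(), node.get_right())
            )
            return f"({parts})"

        return render(root) + ";"


def cluster_signatures(pwms) -> SignatureDendrogram:
    """Hierarchically cluster PWMs at distance 1 - corr2, average linkage.

    Input order breaks ties, so label the PWMs and pass them in a fixed
    order for reproducibility.  Also emits the symmetric correlation matrix
    used for heat-map display.
    """
    pwms = list(pwms)
    if len(pwms) < 2:
        raise ValueError("need at least two PWMs to cluster")
    labels = [
        p.label if p.label else f"pwm{i + 1}" for i, p in enumerate(pwms)
    ]
    n = len(pwms)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            corr[i, j] = corr[j, i] = pwm_correlation(pwms[i], pwms[j])
    dist = 1.0 - corr
    condensed = dist[np.triu_indices(n, k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    return SignatureDendrogram(
        labels=labels,
        linkage=linkage,
        correlation=pd.DataFrame(corr, index=labels, columns=labels),
    )


def column_information_content(column) -> float:
    """Information content (bits) of one PWM column: log2(20) - H.

    No small-sample correction is applied.
    """
    p = np.asarray(list(column), dtype=float)
    if p.ndim != 1 or abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
        raise ValueError("column must be a normalised frequency vector")
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return float(np.log2(20) - entropy)
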