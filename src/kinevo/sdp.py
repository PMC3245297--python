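"""Sequence-based scoring of specificity-determining positions (SDPs).

An SDP is an alignment column conserved within each isofunctional group of a
family but differing between groups.  Given a grouped alignment, each column
is scored by the plug-in mutual information (in bits) between residue
identity and group label, calibrated against a permutation null obtained by
shuffling the group labels across rows.  Columns are ranked by the
permutation z-score, and the number of significant columns is chosen by the
global minimum of a Bernoulli (union-bound) estimator over the sorted
p-values.

Gapped rows are excluded from a column's counts: a gap reflects alignment
uncertainty, not residue chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .family_io import GAP, Alignment

__all__ = [
    "GroupedAlignment",
    "SdpRanking",
    "column_mutual_information",
    "permutation_null",
    "rank_columns",
    "bernoulli_cutoff",
]


@dataclass
class GroupedAlignment:
    """An alignment whose rows carry isofunctional group labels."""

    alignment: Alignment
    group_labels: list[str]
    representative: list[bool] = None

    def __post_init__(self) -> None:
        if len(self.group_labels) != self.alignment.n_rows:
            raise ValueError("one group label required per alignment row")
        if len(set(self.group_labels)) < 2:
            raise ValueError("need at least two distinct groups")
        if not self.representative:
            self.representative = [True] * self.alignment.n_rows

    @property
    def length(self) -> int:
        return self.alignment.length

    @property
    def n_rows(self) -> int:
        return self.alignment.n_rows

    def column(self, c: int) -> list[str]:
        return self.alignment.column(c)


def _encode_column(
    residues, labels
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Drop gapped rows and integer-encode residues and labels."""
    res = np.asarray(list(residues))
    lab = np.asarray(list(labels))
    if res.shape != lab.shape:
        raise ValueError("residues and labels differ in length")
    keep = res != GAP
    if not keep.any():
        raise ValueError("column is entirely gapped")
    res, lab = res[keep], lab[keep]
    r_codes = np.unique(res, return_inverse=True)[1]
    groups, g_codes = np.unique(lab, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("fewer than two groups remain after gap exclusion")
    return r_codes, g_codes, int(r_codes.max()) + 1, len(groups)


def _mi_from_joint(counts: np.ndarray) -> np.ndarray:
    """MI in bits from joint count arrays of shape (..., R, G)."""
    n = counts.sum(axis=(-2, -1), keepdims=True)
    f = counts / n
    fr = f.sum(axis=-1, keepdims=True)
    fg = f.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = f * (np.log2(f) - np.log2(fr * fg))
    terms = np.where(f > 0, terms, 0.0)
    return np.maximum(terms.sum(axis=(-2, -1)), 0.0)


def column_mutual_information(residues, labels) -> float:
    """Plug-in mutual information (bits) between residue and group label.

    Rows gapped at this column are excluded; zero-count cells contribute 0.
    """
    r, g, n_res, n_grp = _encode_column(residues, labels)
    joint = np.zeros((n_res, n_grp))
    np.add.at(joint, (r, g), 1.0)
    return float(_mi_from_joint(joint))


def _null_mi(
    r: np.ndarray, g: np.ndarray, n_res: int, n_grp: int, n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """MI of ``n_perm`` label shuffles, fully vectorised via one bincount."""
    perms = rng.permuted(np.tile(g, (n_perm, 1)), axis=1)
    cell = n_res * n_grp
    idx = (np.arange(n_perm)[:, None] * cell) + r[None, :] * n_grp + perms
    counts = np.bincount(idx.ravel(), minlength=n_perm * cell).astype(float)
    return _mi_from_joint(counts.reshape(n_perm, n_res, n_grp))


def permutation_null(
    residues, labels, n_perm: int = 999, seed=None
) -> tuple[float, float, float, float]:
    """Permutation calibration of a column's MI.

    Group labels are shuffled across (non-gapped) rows ``n_perm`` times.
    Returns ``(null_mean, null_sd, z, p)`` with ``z = 0`` when the null is
    degenerate and the add-one permutation p-value
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    r, g, n_res, n_grp = _encode_column(residues, labels)
    joint = np.zeros((n_res, n_grp))
    np.add.at(joint, (r, g), 1.0)
    obs = float(_mi_from_joint(joint))
    null = _null_mi(r, g, n_res, n_grp, n_perm, rng)
    mean = float(null.mean())
    sd = float(null.std(ddof=0))
    z = 0.0 if sd == 0.0 else (obs - mean) / sd
    p = (1.0 + int((null >= obs - 1e-12).sum())) / (1.0 + n_perm)
    return mean, sd, z, p


def bernoulli_cutoff(p_values, n_columns: int | None = None) -> int:
    """Number of significant columns by the global minimum of a Bernoulli
    (union-bound) estimator.

    With p-values sorted ascending, ``B(k) = min(1, C(L, k) * p_(k)^k)``;
    the cutoff is the ``k`` minimising ``B`` (smallest ``k`` on ties), or 0
    if the minimum never drops below 1.
    """
    p = np.sort(np.asarray(list(p_values), dtype=float))
    if p.size == 0:
        return 0
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    L = n_columns if n_columns is not None else p.size
    k = np.arange(1, p.size + 1)
    log_comb = gammaln(L + 1) - gammaln(k + 1) - gammaln(L - k + 1)
    with np.errstate(divide="ignore"):
        log_b = log_comb + k * np.log(p)
    log_b = np.minimum(log_b, 0.0)  # cap at B = 1
    i = int(np.argmin(log_b))      # argmin returns the first (smallest k) tie
    if log_b[i] >= 0.0:
        return 0
    return int(k[i])


@dataclass
class SdpRanking:
    """Per-column SDP statistics over one grouped alignment."""

    table: pd.DataFrame  # columns: column, mi, z, p, rank, n_effective
    cutoff_k: int

    @property
    def significant(self) -> list[int]:
        t = self.table
        return sorted(t.loc[t["rank"] <= self.cutoff_k, "column"].tolist())

    def rank_of(self, column: int) -> int:
        return int(self.table.set_index("column").loc[column, "rank"])

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out["column_1based"] = out["column"] + 1
        out["significant"] = out["rank"] <= self.cutoff_k
        out[
            ["column_1based", "mi_bits", "z", "p", "rank", "n_effective",
             "significant"]
        ].rename(columns={"mi_bits": "mi_bits"}).to_csv(
            path, sep="\t", index=False
        )


def rank_columns(
    galn: GroupedAlignment, n_perm: int = 999, seed=None
) -> SdpRanking:
    """Rank every alignment column by permutation z-score of its MI.

    Ties are broken by descending MI, then ascending column index.  Columns
    that are degenerate (entirely gapped, or single-group after gap
    exclusion) receive MI 0, z 0, p 1.  The significance cutoff is the
    Bernoulli-estimator global minimum over the sorted p-values.
    """
    L = galn.length
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(L)
    labels = galn.group_labels
    rows = []
    for c in range(L):
        residues = galn.column(c)
        try:
            r, g, n_res, n_grp = _encode_column(residues, labels)
        except ValueError:
            rows.append((c, 0.0, 0.0, 1.0, 0))
            continue
        n_eff = len(r)
        joint = np.zeros((n_res, n_grp))
        np.add.at(joint, (r, g), 1.0)
        obs = float(_mi_from_joint(joint))
        rng = np.random.default_rng(children[c])
        null = _null_mi(r, g, n_res, n_grp, n_perm, rng)
        sd = float(null.std(ddof=0))
        z = 0.0 if sd == 0.0 else (obs - float(null.mean())) / sd
        p = (1.0 + int((null >= obs - 1e-12).sum())) / (1.0 + n_perm)
        rows.append((c, obs, z, p, n_eff))
    table = pd.DataFrame(
        rows, columns=["column", "mi_bits", "z", "p", "n_effective"]
    )
    order = table.sort_values(
        ["z", "mi_bits", "column"], ascending=[False, False, True]
    ).index
    ranks = pd.Series(np.arange(1, L + 1), index=order)
    table["rank"] = ranks.sort_index().to_numpy()
    cutoff = bernoulli_cutoff(table["p"].to_numpy(), L)
    return SdpRanking(table=table, cutoff_k=cutoff)
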