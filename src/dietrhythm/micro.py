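"""Feature-table processing and diversity.

Rarefaction, prevalence filtering, CLR, alpha diversity (Shannon, Pielou,
observed features, Faith's PD), unweighted UniFrac and PCoA.  Tables are
samples x taxa integer counts; trees are rooted ``skbio.TreeNode`` objects
whose tip names cover the table's taxa.

Shannon is reported in bits (log base 2, switchable), matching the QIIME 2
convention used by q2-diversity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Samples x taxa counts with optional per-taxon taxonomy strings."""

    data: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("sample and taxon IDs must be unique")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.data.index.name = "sample_id"
        self.data.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    @classmethod
    def from_biom(cls, path: str | Path) -> "FeatureTable":
        import biom  # optional dependency

        tbl = biom.load_table(str(path))
        df = pd.DataFrame(
            tbl.matrix_data.toarray().T,
            index=list(tbl.ids("sample")),
            columns=list(tbl.ids("observation")),
        )
        return cls(df.astype(int))


def _as_frame(table) -> pd.DataFrame:
    return table.data if isinstance(table, FeatureTable) else table


def rarefy(table, depth: int = 15000, seed: int | None = None) -> FeatureTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    df = _as_frame(table)
    rng = np.random.default_rng(seed)
    keep = df.sum(axis=1) >= depth
    sub = df.loc[keep]
    out = np.empty(sub.shape, dtype=np.int64)
    counts = sub.to_numpy(dtype=np.int64)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return FeatureTable(pd.DataFrame(out, index=sub.index, columns=sub.columns))


def prevalence_filter(table, min_samples: int) -> FeatureTable:
    """Keep taxa present (count > 0) in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    df = _as_frame(table)
    keep = (df > 0).sum(axis=0) >= min_samples
    return FeatureTable(df.loc[:, keep].copy())


def clr_transform(table, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform: log(x + pc) centered per sample."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    df = _as_frame(table)
    logx = np.log(df.to_numpy(dtype=float) + pseudocount)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=df.index, columns=df.columns)


def _tree_presence(df: pd.DataFrame, tree: TreeNode):
    """Per-node observed flags for each sample.

    Returns (lengths, presence) over non-root nodes in postorder, where
    ``presence[k, s]`` is True when node k's subtree contains a taxon
    observed in sample s.  Taxa in the table but absent from the tree raise.
    """
    tips = {t.name for t in tree.tips()}
    missing = set(df.columns) - tips
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)[:5]} ...")
    col_idx = {name: j for j, name in enumerate(df.columns)}
    observed = df.to_numpy() > 0  # samples x taxa

    nodes = [n for n in tree.postorder() if n is not tree]
    lengths = np.array([n.length if n.length is not None else 0.0 for n in nodes])
    presence = np.zeros((len(nodes), df.shape[0]), dtype=bool)
    node_row = {id(n): k for k, n in enumerate(nodes)}
    for k, n in enumerate(nodes):
        if n.is_tip():
            j = col_idx.get(n.name)
            if j is not None:
                presence[k] = observed[:, j]
        else:
            for child in n.children:
                presence[k] |= presence[node_row[id(child)]]
    return lengths, presence


def alpha_metrics(table, tree: TreeNode | None = None, base: float = 2.0) -> pd.DataFrame:
    """Per-sample alpha diversity.

    Columns: ``shannon`` (log ``base``), ``pielou`` (NaN for single-taxon
    samples), ``observed_features`` and, when a tree is supplied,
    ``faith_pd`` (total branch length spanned by observed taxa and the root).
    """
    df = _as_frame(table)
    counts = df.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("alpha_metrics: sample with zero total count")
    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1) / np.log(base)
    observed = (counts > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pielou = np.where(observed > 1, shannon / (np.log(observed) / np.log(base)), np.nan)
    out = pd.DataFrame(
        {"shannon": shannon, "pielou": pielou, "observed_features": observed},
        index=df.index,
    )
    if tree is not None:
        lengths, presence = _tree_presence(df, tree)
        out["faith_pd"] = presence.T @ lengths
    return out


def unweighted_unifrac(table, tree: TreeNode) -> pd.DataFrame:
    """Pairwise unweighted UniFrac distances (presence/absence).

    For samples A, B: (branch length unique to one) / (branch length
    observed in either).
    """
    df = _as_frame(table)
    if ((df.to_numpy() > 0).sum(axis=1) == 0).any():
        raise ValueError("unweighted_unifrac: sample observing no taxa")
    lengths, presence = _tree_presence(df, tree)
    A = presence.astype(float)  # nodes x samples
    s = lengths @ A  # observed branch length per sample
    P = (A * lengths[:, None]).T @ A  # shared branch length per pair
    xor = s[:, None] + s[None, :] - 2.0 * P
    union = s[:, None] + s[None, :] - P
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(union > 0, xor / union, 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=df.index, columns=df.index)


def pcoa(dist: pd.DataFrame, atol: float = 1e-8) -> tuple[pd.DataFrame, pd.Series]:
    """Principal coordinates via Gower double-centering of -D^2/2.

    Negative eigenvalues are dropped (logged); ``proportion_explained`` is
    taken over the positive eigenvalues only.
    """
    D = np.asarray(dist, dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(D - D.T).max() > atol:
        raise ValueError("distance matrix asymmetric beyond tolerance")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(eigval.max(), 0) * 1e-12
    n_neg = int((eigval < 0).sum())
    if n_neg:
        logger.info("pcoa: dropped %d negative eigenvalues", n_neg)
    eigval, eigvec = eigval[pos], eigvec[:, pos]
    coords = eigvec * np.sqrt(eigval)
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    return (
        pd.DataFrame(coords, index=index, columns=axes),
        pd.Series(eigval / eigval.sum(), index=axes, name="proportion_explained"),
    )


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path))


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))
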