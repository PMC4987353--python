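"""Alpha and beta diversity: observed OTUs, Faith's PD, UniFrac, PCoA, ANOSIM.

All phylogenetic metrics run off a single edge index built once per
(tree, table) pair: each non-root branch is a row, and a postorder
accumulation turns per-tip counts into per-branch descendant counts. From
that matrix every metric is plain array arithmetic:

* Faith's PD of a sample is the summed length of branches with at least one
  present descendant tip (the minimal subtree spanning the present tips and
  the root).
* Unweighted UniFrac between two samples is (branch length unique to one
  community) / (branch length present in either).
* Raw weighted UniFrac is ``sum_b L_b * |p1_b - p2_b]`` where ``p_b`` is the
  fraction of a community's reads descending from branch ``b``; the
  normalized variant divides by ``sum_b L_b * (p1_b + p2_b)`` and lies in
  [0, 1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .model import CountTable, PhyloTree

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "AnosimResult",
    "TreeIndex",
    "observed_otus",
    "faith_pd",
    "unifrac",
    "distance_matrix",
    "alpha_diversity",
    "pcoa",
    "anosim",
]

METRICS = ("unweighted_unifrac", "weighted_unifrac", "weighted_unifrac_raw")


@dataclass
class DistanceMatrix:
    """Square symmetric distance matrix with aligned sample ids."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if d.shape[0] != len(self.sample_ids):
            raise ValueError("ids and matrix size disagree")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(d < -1e-12):
            raise ValueError("distances must be non-negative")
        self.d = np.clip((d + d.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)])


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame      # samples x retained axes
    eigenvalues: np.ndarray        # all eigenvalues, sorted descending
    proportion_explained: np.ndarray  # over positive eigenvalues only


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: int | None


# ------------------------------------------------------------------ alpha

def observed_otus(column: np.ndarray | pd.Series) -> int:
    """Number of OTUs with count > 0 in one (rarefied) sample."""
    return int(np.count_nonzero(np.asarray(column) > 0))


class TreeIndex:
    """Edge-indexed view of ``tree`` aligned to an OTU id order.

    Tips not in ``otu_ids`` are pruned; OTU ids missing from the tree raise.
    """

    def __init__(self, tree: PhyloTree, otu_ids: list[str]):
        tips = set(tree.tip_names)
        missing = [o for o in otu_ids if o not in tips]
        if missing:
            raise KeyError(f"OTU {missing[0]!r} is not a tip of the tree")
        if set(otu_ids) != tips:
            tree = tree.sheared(set(otu_ids))
        self.otu_ids = list(otu_ids)
        otu_pos = {o: i for i, o in enumerate(self.otu_ids)}

        nodes = list(tree.tree.postorder(include_self=False))
        self.lengths = np.array([n.length for n in nodes], dtype=float)
        self._node_index = {id(n): i for i, n in enumerate(nodes)}
        self._nodes = nodes
        self._tip_rows = np.array(
            [otu_pos[n.name] if n.is_tip() else -1 for n in nodes], dtype=np.int64
        )

    def edge_counts(self, counts: np.ndarray) -> np.ndarray:
        """Per-branch descendant counts: (n_edges, n_samples).

        ``counts`` is the tip-by-sample count (or proportion) matrix in
        ``otu_ids`` order.
        """
        counts = np.atleast_2d(np.asarray(counts, dtype=float))
        if counts.shape[0] != len(self.otu_ids):
            counts = counts.T
        n_samples = counts.shape[1]
        A = np.zeros((len(self._nodes), n_samples), dtype=float)
        for i, node in enumerate(self._nodes):
            if node.is_tip():
                A[i] = counts[self._tip_rows[i]]
            else:
                for child in node.children:
                    A[i] += A[self._node_index[id(child)]]
        return A


def _scoped_index(tree: PhyloTree, otu_ids: list[str],
                  counts: np.ndarray) -> TreeIndex:
    """TreeIndex over the tree sheared to the full OTU id set.

    Zero-count OTUs are kept so that branch context (shared stem edges,
    root-ward paths) is identical for every sample of the same table; OTUs
    with reads that are not tree tips are a hard error.
    """
    tips = set(tree.tip_names)
    counts = np.atleast_2d(counts)
    if counts.shape[0] != len(otu_ids):
        counts = counts.T
    for i, otu in enumerate(otu_ids):
        if otu not in tips and counts[i].sum() > 0:
            raise KeyError(f"present OTU {otu!r} is not a tip of the tree")
    kept = [o for o in otu_ids if o in tips]
    return TreeIndex(tree, kept)


def faith_pd(column: pd.Series | np.ndarray, tree: PhyloTree,
             otu_ids: list[str] | None = None) -> float:
    """Faith's phylogenetic diversity of one sample.

    Total branch length of the minimal subtree connecting every present tip
    and the root (the root-ward path is included). An empty sample has PD 0.
    """
    if isinstance(column, pd.Series):
        otu_ids = list(column.index)
        column = column.to_numpy()
    if otu_ids is None:
        raise ValueError("otu_ids required when column is a bare array")
    column = np.asarray(column, dtype=float)
    if not (column > 0).any():
        return 0.0
    idx = _scoped_index(tree, otu_ids, column.reshape(-1, 1))
    kept = [o in set(idx.otu_ids) for o in otu_ids]
    A = idx.edge_counts(column[kept].reshape(-1, 1))
    return float(idx.lengths[A[:, 0] > 0].sum())


def alpha_diversity(table: CountTable, tree: PhyloTree | None = None) -> pd.DataFrame:
    """Observed OTUs and (if a tree is given) Faith's PD per sample."""
    out = pd.DataFrame(index=table.sample_ids)
    out["observed_otus"] = [observed_otus(table.data[s]) for s in table.sample_ids]
    if tree is not None:
        idx = _scoped_index(tree, table.otu_ids, table.counts)
        A = idx.edge_counts(table.data.loc[idx.otu_ids].to_numpy())
        out["faith_pd"] = (idx.lengths[:, None] * (A > 0)).sum(axis=0)
    return out


# ------------------------------------------------------------------- unifrac

def _pair_unifrac(lengths: np.ndarray, a1: np.ndarray, a2: np.ndarray,
                  t1: float, t2: float,
                  weighted: bool, normalized: bool) -> float:
    if weighted:
        p1 = a1 / t1
        p2 = a2 / t2
        raw = float((lengths * np.abs(p1 - p2)).sum())
        if not normalized:
            return raw
        denom = float((lengths * (p1 + p2)).sum())
        return raw / denom if denom > 0 else 0.0
    b1 = a1 > 0
    b2 = a2 > 0
    union = float(lengths[b1 | b2].sum())
    unique = float(lengths[b1 ^ b2].sum())
    return unique / union if union > 0 else 0.0


def unifrac(
    s1: pd.Series,
    s2: pd.Series,
    tree: PhyloTree,
    weighted: bool = False,
    normalized: bool = True,
) -> float:
    """UniFrac distance between two samples (aligned Series over OTU ids)."""
    if not s1.index.equals(s2.index):
        raise ValueError("samples must share an OTU id index")
    if s1.sum() == 0 or s2.sum() == 0:
        raise ValueError("a community with zero total count has no UniFrac distance")
    stacked = np.column_stack([s1.to_numpy(float), s2.to_numpy(float)])
    idx = _scoped_index(tree, list(s1.index), stacked)
    kept = [o in set(idx.otu_ids) for o in s1.index]
    A = idx.edge_counts(stacked[kept])
    return _pair_unifrac(
        idx.lengths, A[:, 0], A[:, 1],
        float(s1.sum()), float(s2.sum()), weighted, normalized,
    )


def distance_matrix(
    table: CountTable,
    tree: PhyloTree,
    metric: str = "unweighted_unifrac",
) -> DistanceMatrix:
    """All pairwise UniFrac distances for the samples of ``table``."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    sums = table.column_sums()
    empty = list(sums.index[sums == 0])
    if empty:
        raise ValueError(f"sample {empty[0]!r} is empty; no UniFrac distance")
    idx = _scoped_index(tree, table.otu_ids, table.counts)
    A = idx.edge_counts(table.data.loc[idx.otu_ids].to_numpy())
    n = table.n_samples
    weighted = metric.startswith("weighted")
    normalized = metric == "weighted_unifrac"
    totals = sums.to_numpy(dtype=float)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = _pair_unifrac(
            idx.lengths, A[:, i], A[:, j], totals[i], totals[j],
            weighted, normalized,
        )
    return DistanceMatrix(table.sample_ids, d)


# ---------------------------------------------------------------------- pcoa

def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-10) -> PcoaResult:
    """Principal coordinates analysis (metric MDS).

    Gower-centers ``-0.5 * D∘D``, eigendecomposes, and keeps axes for
    positive eigenvalues only (coordinates are eigenvectors scaled by the
    square root of their eigenvalue). Negative eigenvalues — which arise when
    D is not Euclidean-embeddable — are reported unchanged; no Lingoes or
    Cailliez correction is applied.
    """
    n = dm.n
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    D2 = dm.d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    pos = eigvals > eig_tol * scale
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    prop = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    coord_df = pd.DataFrame(
        coords,
        index=dm.sample_ids,
        columns=[f"PC{k + 1}" for k in range(coords.shape[1])],
    )
    return PcoaResult(coord_df, eigvals, prop)


# -------------------------------------------------------------------- anosim

def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    """ANOSIM statistic from condensed-rank vector and within-group mask."""
    M = ranks.size
    if within.all() or not within.any():
        raise ValueError("ANOSIM needs both within- and between-group pairs")
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return float((r_b - r_w) / (M / 2.0))


def _within_mask(labels: np.ndarray) -> np.ndarray:
    n = labels.size
    same = labels[:, None] == labels[None, :]
    return squareform(same & ~np.eye(n, dtype=bool), checks=False)


def anosim(
    dm: DistanceMatrix,
    groups: list[str] | np.ndarray,
    n_permutations: int | str = 999,
    seed: int | None = 0,
) -> AnosimResult:
    """Analysis of similarities: rank-based test of group separation.

    R = (mean rank of between-group distances − mean rank of within-group
    distances) / (M/2) with M = n(n−1)/2 and average ranks for ties; R is 0
    for a constant distance matrix. The p-value permutes group labels:
    ``p = (1 + #{R_perm ≥ R_obs}) / (1 + n_permutations)`` so it is never 0
    and never below 1/(n_permutations+1). Pass ``n_permutations="exact"`` to
    enumerate every distinct labelling instead (p = fraction of labellings
    with R at least the observed, observed included).
    """
    labels = np.asarray(list(groups))
    if labels.size != dm.n:
        raise ValueError("one label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts.argmin()]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    cond = dm.condensed()
    ranks = rankdata(cond)  # average ranks over ties
    if np.ptp(cond) == 0:
        return AnosimResult(0.0, 1.0, 0, seed if isinstance(seed, int) else None)
    r_obs = _anosim_r(ranks, _within_mask(labels))

    if n_permutations == "exact":
        seen: set[tuple] = set()
        n_ge = 0
        for perm in itertools.permutations(labels):
            if perm in seen:
                continue
            seen.add(perm)
            if _anosim_r(ranks, _within_mask(np.asarray(perm))) >= r_obs - 1e-12:
                n_ge += 1
        return AnosimResult(r_obs, n_ge / len(seen), len(seen), None)

    n_perm = int(n_permutations)
    if n_perm < 1:
        raise ValueError("n_permutations must be positive")
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, _within_mask(perm)) >= r_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return AnosimResult(r_obs, p, n_perm, seed)
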