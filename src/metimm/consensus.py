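"""Resampled consensus clustering of genes on Spearman correlation distance.

Gene modules are discovered by repeatedly subsampling genes (and optionally
samples), hierarchically clustering each subsample with Ward.D2 linkage on
1 - Spearman correlation, and summarizing pair stability in a consensus
matrix: the fraction of co-sampled runs in which two genes landed in the
same cluster.  Final module assignments cut a Ward.D2 tree built on
1 - consensus.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSet

__all__ = [
    "ConsensusParams",
    "ConsensusResult",
    "spearman_distance",
    "subsample_stream",
    "consensus_cluster",
    "select_coexpressed",
]


@dataclass(frozen=True)
class ConsensusParams:
    """Resampling and clustering parameters.

    Defaults: 100 resampling repetitions at an 0.8 gene (item) sampling
    fraction with all samples retained, cut at k = 5 — Ward.D2 linkage on
    1 - Spearman distance throughout.
    """

    reps: int = 100
    p_item: float = 0.8
    p_feature: float = 1.0
    k: int = 5
    linkage: str = "ward.D2"
    distance: str = "one-minus-spearman"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (0 < self.p_item <= 1):
            raise ValueError("p_item must lie in (0, 1]")
        if not (0 < self.p_feature <= 1):
            raise ValueError("p_feature must lie in (0, 1]")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.linkage != "ward.D2":
            raise ValueError("only ward.D2 linkage is supported")
        if self.distance != "one-minus-spearman":
            raise ValueError("only one-minus-spearman distance is supported")


@dataclass
class ConsensusResult:
    """Consensus matrix, resampling accounting, and final assignments."""

    item_ids: list[str]
    consensus: np.ndarray
    assignments: pd.Series  # item -> cluster label in 1..k
    sampling_counts: np.ndarray  # times each pair was co-sampled

    def __post_init__(self) -> None:
        c = self.consensus
        if not np.allclose(c, c.T):
            raise ValueError("consensus matrix must be symmetric")
        if c.min() < 0 or c.max() > 1:
            raise ValueError("consensus entries must lie in [0, 1]")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("consensus diagonal must be 1")
        if set(self.assignments.index) != set(self.item_ids):
            raise ValueError("assignments must cover exactly the clustered items")


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, values)


def spearman_distance(
    expr: ExpressionMatrix, genes: Sequence[str]
) -> pd.DataFrame:
    """Pairwise 1 - Spearman rank correlation between genes, across samples.

    Symmetric with zero diagonal, entries in [0, 2].  A gene constant across
    samples has no defined rank correlation and raises a ValueError naming it.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples")
    sub = expr.subset_genes(genes)
    ranks = _rank_rows(sub.values)
    sd = ranks.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"gene {genes[constant[0]]!r} is constant across samples; "
            "Spearman correlation undefined"
        )
    corr = np.corrcoef(ranks)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(dist, index=genes, columns=genes)


def subsample_stream(
    params: ConsensusParams, n_items: int, n_samples: int
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """The seeded per-repetition (item indices, sample indices) stream.

    Exposed so the resampling accounting can be tallied independently of
    :func:`consensus_cluster`; both draw the identical stream for a given
    (params, n_items, n_samples).
    """
    rng = np.random.default_rng(params.seed)
    m = math.ceil(params.p_item * n_items)
    s = math.ceil(params.p_feature * n_samples)
    for _ in range(params.reps):
        items = np.sort(rng.choice(n_items, size=m, replace=False))
        samples = np.sort(rng.choice(n_samples, size=s, replace=False))
        yield items, samples


def _ward_cut(dist: np.ndarray, k: int) -> np.ndarray:
    """Ward.D2 linkage on a precomputed distance matrix, cut into k clusters."""
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="ward")
    return fcluster(tree, t=k, criterion="maxclust")


def consensus_cluster(
    expr: ExpressionMatrix, genes: Sequence[str], params: ConsensusParams
) -> ConsensusResult:
    """Consensus clustering of `genes` over resampled Ward.D2 solutions.

    Genes are canonicalized to sorted order before the seeded subsample
    stream is drawn, so the result is invariant to input gene order.
    consensus(i, j) = co-cluster count / co-sample count; pairs never
    co-sampled get 0 with a warning.  Final assignments cut a Ward.D2 tree
    on 1 - consensus at k.
    """
    genes = sorted(set(genes))
    missing = sorted(set(genes) - set(expr.gene_ids))
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    n_items = len(genes)
    if n_items < params.k:
        raise ValueError(f"need at least k={params.k} genes, got {n_items}")

    cocluster = np.zeros((n_items, n_items))
    cosample = np.zeros((n_items, n_items), dtype=int)
    sub_all = expr.subset_genes(genes)

    for item_idx, sample_idx in subsample_stream(params, n_items, expr.n_samples):
        values = sub_all.values[np.ix_(item_idx, sample_idx)]
        sub = ExpressionMatrix(
            [genes[i] for i in item_idx],
            [expr.sample_ids[j] for j in sample_idx],
            values,
        )
        dist = spearman_distance(sub, sub.gene_ids).to_numpy()
        labels = _ward_cut(dist, min(params.k, len(item_idx)))
        cosample[np.ix_(item_idx, item_idx)] += 1
        same = labels[:, None] == labels[None, :]
        cocluster[np.ix_(item_idx, item_idx)] += same

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(cosample > 0, cocluster / np.maximum(cosample, 1), 0.0)
    never = (cosample == 0) & ~np.eye(n_items, dtype=bool)
    if never.any():
        warnings.warn(
            f"{int(never.sum() // 2)} gene pairs were never co-sampled; "
            "their consensus entries are set to 0"
        )
    consensus = (consensus + consensus.T) / 2.0
    np.fill_diagonal(consensus, 1.0)

    final_labels = _ward_cut(1.0 - consensus, params.k)
    assignments = pd.Series(final_labels, index=genes, name="cluster")
    return ConsensusResult(genes, consensus, assignments, cosample)


def select_coexpressed(
    result: ConsensusResult, expr: ExpressionMatrix, min_size: int = 5
) -> GeneSet:
    """Pick the most coherently co-expressed cluster from a consensus solution.

    Among clusters of size >= min_size, returns the one maximizing the mean
    pairwise Spearman correlation of its members; ties break to the smaller
    cluster label.  Raises if no cluster reaches min_size.
    """
    scores: dict[int, float] = {}
    members: dict[int, list[str]] = {}
    for label in sorted(result.assignments.unique()):
        genes = list(result.assignments.index[result.assignments == label])
        if len(genes) < min_size:
            continue
        corr = 1.0 - spearman_distance(expr, genes).to_numpy()
        off = corr[~np.eye(len(genes), dtype=bool)]
        scores[int(label)] = float(off.mean())
        members[int(label)] = genes
    if not scores:
        raise ValueError(f"no cluster reaches min_size={min_size}")
    best = max(sorted(scores), key=lambda lab: (scores[lab], -lab))
    return GeneSet(f"cluster_{best}", tuple(members[best]))
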