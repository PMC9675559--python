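"""Per-sample signature scoring.

Implements single-sample GSEA (rank-weighted running-sum enrichment),
weighted-signature scores (sum of weighted z-scored expression, the
T-cell-inflamed score convention), stromal/immune/purity scores in the
ESTIMATE style, and hypergeometric over-representation analysis with
Benjamini-Hochberg adjustment.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSet, WeightedGeneSet

__all__ = [
    "ScoreParams",
    "OraParams",
    "ssgsea_score",
    "score_collection",
    "weighted_signature_score",
    "estimate_scores",
    "ora_enrichment",
    "PURITY_INTERCEPT",
    "PURITY_SLOPE",
]

#: published cosine purity formula constants
PURITY_INTERCEPT = 0.6049872018
PURITY_SLOPE = 0.0001467884


@dataclass(frozen=True)
class ScoreParams:
    """ssGSEA conventions: rank-weight exponent and global normalization.

    alpha = 0.25 and division of all scores by the global (max - min) score
    range follow the conventional single-sample GSEA defaults.
    """

    alpha: float = 0.25
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def _ssgsea_raw_sample(x: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Raw enrichment score of one sample.

    Genes are walked in decreasing-expression order; the score is the summed
    difference between the in-set cumulative weight (weights = rank
    statistic ** alpha, average ranks for ties, normalized to total 1 over
    set members) and the out-of-set cumulative fraction.
    """
    ranks = rankdata(x)  # ascending: top-expressed gene holds the largest rank
    order = np.argsort(-x, kind="stable")
    inset_ord = in_set[order]
    weights = np.where(inset_ord, ranks[order] ** alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    out = (~inset_ord).astype(float)
    p_out = np.cumsum(out) / out.sum()
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    expr: ExpressionMatrix,
    sig: GeneSet | WeightedGeneSet,
    params: ScoreParams = ScoreParams(),
) -> pd.Series:
    """Single-sample GSEA scores for one signature, one score per sample.

    Raw scores depend on each sample's expression only through within-sample
    ranks; with ``params.normalize`` all scores are divided by the
    (max - min) raw-score range across samples.
    """
    present = [g for g in sig.genes if g in set(expr.gene_ids)]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in matrix")
    if len(present) == expr.n_genes:
        raise ValueError(
            f"signature {sig.name!r} covers every gene; out-of-set is empty"
        )
    in_set = np.zeros(expr.n_genes, dtype=bool)
    in_set[expr.gene_index(present)] = True
    raw = np.array(
        [
            _ssgsea_raw_sample(expr.values[:, j], in_set, params.alpha)
            for j in range(expr.n_samples)
        ]
    )
    scores = raw
    if params.normalize:
        span = raw.max() - raw.min()
        if span > 0:
            scores = raw / span
        else:
            warnings.warn(
                f"signature {sig.name!r}: zero score range; normalization skipped"
            )
    return pd.Series(scores, index=list(expr.sample_ids), name=sig.name)


def score_collection(
    expr: ExpressionMatrix,
    collection: Mapping[str, GeneSet],
    params: ScoreParams = ScoreParams(),
) -> pd.DataFrame:
    """Samples x signatures ssGSEA score matrix.

    With normalization on, the whole matrix is divided by one global
    (max - min) raw-score range, mirroring the usual multi-signature
    convention.
    """
    raw_params = ScoreParams(alpha=params.alpha, normalize=False)
    columns = {
        name: ssgsea_score(expr, sig, raw_params) for name, sig in collection.items()
    }
    matrix = pd.DataFrame(columns)
    if params.normalize:
        span = matrix.to_numpy().max() - matrix.to_numpy().min()
        if span > 0:
            matrix = matrix / span
        else:
            warnings.warn("zero global score range; normalization skipped")
    return matrix


def weighted_signature_score(
    expr: ExpressionMatrix, sig: WeightedGeneSet
) -> pd.Series:
    """Weighted sum of cohort z-scored expression: sum_g w_g * z_g(sample)."""
    missing = sorted(set(sig.genes) - set(expr.gene_ids))
    if missing:
        raise ValueError(f"signature {sig.name!r} genes absent from matrix: {missing}")
    sub = expr.subset_genes(list(sig.genes))
    mean = sub.values.mean(axis=1, keepdims=True)
    sd = sub.values.std(axis=1, ddof=0, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(
            f"signature gene {sig.genes[flat[0]]!r} has zero variance across the cohort"
        )
    z = (sub.values - mean) / sd
    scores = np.asarray(sig.weights) @ z
    return pd.Series(scores, index=list(expr.sample_ids), name=sig.name)


def estimate_scores(
    expr: ExpressionMatrix,
    stromal_sig: GeneSet,
    immune_sig: GeneSet,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Stromal, immune, combined scores and cosine-formula tumor purity.

    Stromal and immune scores are unnormalized ssGSEA scores; the combined
    (ESTIMATE) score is their sum and purity applies the published
    cos(0.6049872018 + 0.0001467884 * score) formula.  Purity values outside
    [0, 1] are reported with ``purity_in_range = False``, never clipped.
    """
    params = ScoreParams(alpha=alpha, normalize=False)
    stromal = ssgsea_score(expr, stromal_sig, params)
    immune = ssgsea_score(expr, immune_sig, params)
    combined = stromal + immune
    purity = np.cos(PURITY_INTERCEPT + PURITY_SLOPE * combined)
    return pd.DataFrame(
        {
            "stromal_score": stromal,
            "immune_score": immune,
            "estimate_score": combined,
            "tumor_purity": purity,
            "purity_in_range": (purity >= 0) & (purity <= 1),
        }
    )


@dataclass(frozen=True)
class OraParams:
    """Over-representation analysis settings.

    Terms are intersected with the universe, then filtered to sizes in
    [min_set, max_set]; significance is declared at raw p <= alpha with BH
    q-values reported alongside.
    """

    universe: GeneSet = None  # type: ignore[assignment]
    min_set: int = 5
    max_set: int = 5000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.universe is None or len(self.universe) == 0:
            raise ValueError("ORA requires a non-empty universe")
        if not (1 <= self.min_set <= self.max_set):
            raise ValueError("need 1 <= min_set <= max_set")


def ora_enrichment(
    query: GeneSet,
    collections: Mapping[str, GeneSet],
    params: OraParams,
) -> pd.DataFrame:
    """Hypergeometric over-representation of `query` in each term.

    p = P(X >= k) for k = |query & term| drawn from a universe of N genes
    containing K term genes, with n = |query| draws.  Rows sorted by p.
    """
    universe = params.universe.as_set()
    query_genes = set(query.genes) & universe
    if not query_genes:
        raise ValueError("query has no genes inside the universe")
    dropped = set(query.genes) - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the universe were dropped"
        )
    N, n = len(universe), len(query_genes)
    rows = []
    for name, term in collections.items():
        term_genes = term.as_set() & universe
        K = len(term_genes)
        if not (params.min_set <= K <= params.max_set):
            continue
        k = len(term_genes & query_genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": name, "k": k, "K": K, "n": n, "N": N, "p": p})
    result = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(result):
        result["q"] = multipletests(result["p"], method="fdr_bh")[1]
        result["significant"] = result["p"] <= params.alpha
        result = result.sort_values(["p", "term"]).reset_index(drop=True)
    else:
        result["q"] = []
        result["significant"] = []
    return result
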