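"""Metabolic quadrant subtyping, immuno-hot/cold split, and EGFR strata.

The quadrant rule classifies each sample from the signed per-sample medians
of its (centered) glycolytic and cholesterol module expression:

* quiescent   — glycolytic <= 0 and cholesterol <= 0
* glycolytic  — glycolytic > 0 and glycolytic > cholesterol
* cholesterol — cholesterol > 0 and cholesterol > glycolytic

An exact positive tie (gly = chol > 0) falls outside the printed rule and is
reported as ``unclassified`` with a warning — a measure-zero event for
continuous scores.  Genes are z-scored cohort-wise before taking medians so
that 0 anchors to cohort-average expression.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet

__all__ = [
    "zscore_genes",
    "median_center_genes",
    "pathway_median_score",
    "assign_metabolic_subtype",
    "assign_subtypes",
    "assign_immune_phenotype",
    "stratify_samples",
]

SUBTYPE_LABELS = ("quiescent", "glycolytic", "cholesterol", "unclassified")
STRATA = ("EGFR-mutant", "WT-hot", "WT-cold")


def zscore_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-wise z-scoring: each retained gene has mean 0 and SD 1.

    Constant genes have no z-score and are dropped with a warning; an
    all-constant matrix is an error.
    """
    sd = expr.values.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes are constant; nothing to z-score")
    if not keep.all():
        dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
        warnings.warn(f"dropped {len(dropped)} constant gene(s): {dropped[:5]}")
    values = expr.values[keep]
    values = (values - values.mean(axis=1, keepdims=True)) / values.std(
        axis=1, ddof=0, keepdims=True
    )
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(expr.sample_ids), values)


def median_center_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Alternative centering: subtract each gene's cohort median."""
    values = expr.values - np.median(expr.values, axis=1, keepdims=True)
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), values)


def pathway_median_score(centered: ExpressionMatrix, sig: GeneSet) -> pd.Series:
    """Per-sample median of centered expression over the signature's genes.

    Uses the genes of `sig` present in the matrix; an even member count
    takes the mean of the two central values.
    """
    present = [g for g in sig.genes if g in set(centered.gene_ids)]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in matrix")
    sub = centered.subset_genes(present)
    med = np.median(sub.values, axis=0)
    return pd.Series(med, index=list(centered.sample_ids), name=sig.name)


def assign_metabolic_subtype(gly: float, chol: float) -> str:
    """Quadrant rule for one sample; see module docstring."""
    if not (math.isfinite(gly) and math.isfinite(chol)):
        raise ValueError(f"non-finite module score: gly={gly}, chol={chol}")
    if gly <= 0 and chol <= 0:
        return "quiescent"
    if gly > 0 and gly > chol:
        return "glycolytic"
    if chol > 0 and chol > gly:
        return "cholesterol"
    warnings.warn(f"exact positive tie gly = chol = {gly}; sample unclassified")
    return "unclassified"


def assign_subtypes(gly: pd.Series, chol: pd.Series) -> pd.Series:
    """Vectorized quadrant rule over matched sample indices."""
    if not gly.index.equals(chol.index):
        raise ValueError("glycolytic and cholesterol scores index different samples")
    labels = [assign_metabolic_subtype(g, c) for g, c in zip(gly, chol)]
    return pd.Series(labels, index=gly.index, name="metabolic_subtype")


def assign_immune_phenotype(scores: pd.Series) -> pd.Series:
    """Top-50% split: the ceil(n/2) highest-scoring samples are immuno-hot.

    Ties in score break by sample-id lexicographic order, making the split
    deterministic for any input.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to split")
    order = sorted(scores.index, key=lambda s: (-scores[s], str(s)))
    n_hot = math.ceil(len(scores) / 2)
    hot = set(order[:n_hot])
    return pd.Series(
        ["hot" if s in hot else "cold" for s in scores.index],
        index=scores.index,
        name="immune_phenotype",
    )


def stratify_samples(clinical: pd.DataFrame, phenotype: pd.Series) -> pd.Series:
    """EGFR-based strata: mutant trumps phenotype; WT splits by hot/cold."""
    strata = {}
    for sample, status in clinical["egfr_status"].items():
        if status == "mutant":
            strata[sample] = "EGFR-mutant"
        else:
            if sample not in phenotype.index:
                raise ValueError(f"EGFR-WT sample {sample!r} has no immune phenotype")
            strata[sample] = "WT-hot" if phenotype[sample] == "hot" else "WT-cold"
    return pd.Series(strata, name="stratum").reindex(clinical.index)
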