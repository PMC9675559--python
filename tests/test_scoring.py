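"""Signature scoring: ssGSEA oracles, weighted scores, purity, ORA."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from metimm.io import ExpressionMatrix, GeneSet, WeightedGeneSet
from metimm.scoring import (
    OraParams,
    PURITY_INTERCEPT,
    ScoreParams,
    estimate_scores,
    ora_enrichment,
    score_collection,
    ssgsea_score,
    weighted_signature_score,
)

RAW = ScoreParams(normalize=False)


def ssgsea_oracle(x: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Direct-summation single-sample enrichment, coded independently.

    Walks genes from highest to lowest expression accumulating the weighted
    in-set CDF minus the uniform out-of-set CDF.  Ranks computed by explicit
    tie-group averaging over a sorted copy.
    """
    n = len(x)
    # average ranks, 1 = lowest expression
    ranks = np.empty(n)
    by_value = sorted(range(n), key=lambda i: x[i])
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[by_value[j + 1]] == x[by_value[i]]:
            j += 1
        avg = (i + 1 + j + 1) / 2.0
        for idx in by_value[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    walk = sorted(range(n), key=lambda i: (-x[i], i))
    total_w = sum(ranks[i] ** alpha for i in walk if in_set[i])
    n_out = sum(1 for i in walk if not in_set[i])
    score, cum_in, cum_out = 0.0, 0.0, 0.0
    for i in walk:
        if in_set[i]:
            cum_in += ranks[i] ** alpha / total_w
        else:
            cum_out += 1.0 / n_out
        score += cum_in - cum_out
    return score


class TestSsgsea:
    def test_shift_invariance_of_raw_score(self, toy_expression):
        sig = GeneSet("sig", ("G1", "G4", "G7"))
        base = ssgsea_score(toy_expression, sig, RAW)
        shifted = toy_expression.to_frame()
        shifted["S2"] += 100.0
        again = ssgsea_score(ExpressionMatrix.from_frame(shifted), sig, RAW)
        pd.testing.assert_series_equal(base, again)

    def test_monotone_transform_invariance(self, toy_expression):
        """Raw scores depend only on within-sample ranks."""
        sig = GeneSet("sig", ("G2", "G5"))
        base = ssgsea_score(toy_expression, sig, RAW)
        frame = toy_expression.to_frame()
        transformed = ExpressionMatrix.from_frame(np.exp(frame / 3.0))
        again = ssgsea_score(transformed, sig, RAW)
        np.testing.assert_allclose(base.to_numpy(), again.to_numpy(), atol=1e-9)

    def test_top_ranks_maximize_over_all_placements(self):
        """With the 2 signature genes at ranks {1,2}, the score dominates
        every other placement of a 2-gene set among 5 genes."""
        x = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        scores = {}
        for placement in itertools.combinations(range(5), 2):
            in_set = np.zeros(5, dtype=bool)
            in_set[list(placement)] = True
            expr = ExpressionMatrix(
                [f"G{i}" for i in range(5)], ["S1"], x[:, None]
            )
            sig = GeneSet("sig", tuple(f"G{i}" for i in placement))
            scores[placement] = ssgsea_score(expr, sig, RAW).iloc[0]
        assert max(scores, key=scores.get) == (0, 1)

    def test_matches_direct_summation_oracle(self, toy_expression):
        sig = GeneSet("sig", ("G1", "G3", "G8"))
        in_set = np.array([g in sig.genes for g in toy_expression.gene_ids])
        scores = ssgsea_score(toy_expression, sig, RAW)
        for j, sample in enumerate(toy_expression.sample_ids):
            expected = ssgsea_oracle(toy_expression.values[:, j], in_set, RAW.alpha)
            assert scores[sample] == pytest.approx(expected, abs=1e-9)

    def test_sample_permutation_permutes_scores(self, toy_expression):
        sig = GeneSet("sig", ("G1", "G2"))
        base = ssgsea_score(toy_expression, sig, RAW)
        frame = toy_expression.to_frame()[["S3", "S1", "S2"]]
        permuted = ssgsea_score(ExpressionMatrix.from_frame(frame), sig, RAW)
        for s in toy_expression.sample_ids:
            assert permuted[s] == base[s]

    def test_absent_signature_rejected(self, toy_expression):
        with pytest.raises(ValueError, match="no gene"):
            ssgsea_score(toy_expression, GeneSet("sig", ("NOPE",)), RAW)

    def test_all_gene_signature_rejected(self, toy_expression):
        sig = GeneSet("sig", tuple(toy_expression.gene_ids))
        with pytest.raises(ValueError, match="every gene"):
            ssgsea_score(toy_expression, sig, RAW)

    def test_global_normalization_spans_collection(self, toy_expression):
        coll = {
            "a": GeneSet("a", ("G1", "G2")),
            "b": GeneSet("b", ("G7", "G8")),
        }
        raw = score_collection(toy_expression, coll, RAW)
        norm = score_collection(toy_expression, coll, ScoreParams(normalize=True))
        span = raw.to_numpy().max() - raw.to_numpy().min()
        np.testing.assert_allclose(norm.to_numpy(), raw.to_numpy() / span, atol=1e-12)


class TestWeightedSignature:
    def test_zero_weights_give_zero(self, toy_expression):
        sig = WeightedGeneSet("w", ("G1", "G2"), (0.0, 0.0))
        assert (weighted_signature_score(toy_expression, sig) == 0).all()

    def test_single_gene_weight_one_is_zscore(self, toy_expression):
        sig = WeightedGeneSet("w", ("G3",), (1.0,))
        scores = weighted_signature_score(toy_expression, sig)
        row = toy_expression.values[2]
        z = (row - row.mean()) / row.std()
        np.testing.assert_allclose(scores.to_numpy(), z, atol=1e-12)

    def test_hand_computed_weighted_sum(self):
        values = np.array([[1.0, 2.0, 3.0], [4.0, 6.0, 8.0], [0.0, 1.0, -1.0]])
        expr = ExpressionMatrix(["A", "B", "C"], ["s1", "s2", "s3"], values)
        sig = WeightedGeneSet("w", ("A", "B", "C"), (0.5, -1.0, 2.0))
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, keepdims=True
        )
        expected = 0.5 * z[0] - 1.0 * z[1] + 2.0 * z[2]
        scores = weighted_signature_score(expr, sig)
        np.testing.assert_allclose(scores.to_numpy(), expected, atol=1e-12)

    def test_missing_genes_listed(self, toy_expression):
        sig = WeightedGeneSet("w", ("G1", "MISSING"), (1.0, 1.0))
        with pytest.raises(ValueError, match="MISSING"):
            weighted_signature_score(toy_expression, sig)

    def test_zero_variance_gene_named(self):
        values = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        expr = ExpressionMatrix(["FLAT", "B"], ["s1", "s2", "s3"], values)
        sig = WeightedGeneSet("w", ("FLAT", "B"), (1.0, 1.0))
        with pytest.raises(ValueError, match="FLAT"):
            weighted_signature_score(expr, sig)


class TestEstimate:
    def test_combined_score_is_sum(self, toy_expression):
        stromal = GeneSet("stromal", ("G1", "G2"))
        immune = GeneSet("immune", ("G7", "G8"))
        result = estimate_scores(toy_expression, stromal, immune)
        np.testing.assert_allclose(
            result["estimate_score"],
            result["stromal_score"] + result["immune_score"],
            atol=0,
        )

    def test_purity_at_zero_score(self):
        assert math.cos(PURITY_INTERCEPT) == pytest.approx(0.8225, abs=5e-4)

    def test_identical_samples_identical_scores(self):
        values = np.array([[1.0, 1.0], [3.0, 3.0], [2.0, 2.0], [5.0, 5.0]])
        expr = ExpressionMatrix(["A", "B", "C", "D"], ["s1", "s2"], values)
        result = estimate_scores(expr, GeneSet("st", ("A",)), GeneSet("im", ("B",)))
        assert result.loc["s1"].equals(result.loc["s2"])


def _ora_oracle(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric by direct combinatorial counting."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestOra:
    def _universe(self, size: int) -> GeneSet:
        return GeneSet("universe", tuple(f"U{i}" for i in range(size)))

    def test_disjoint_term_p_one(self):
        universe = self._universe(20)
        query = GeneSet("q", universe.genes[:5])
        terms = {"t": GeneSet("t", universe.genes[10:16])}
        result = ora_enrichment(query, terms, OraParams(universe=universe))
        assert result.loc[0, "k"] == 0
        assert result.loc[0, "p"] == pytest.approx(1.0)

    def test_perfect_overlap_exact_probability(self):
        universe = self._universe(20)
        query = GeneSet("q", universe.genes[:5])
        terms = {"t": GeneSet("t", universe.genes[:5])}
        result = ora_enrichment(query, terms, OraParams(universe=universe))
        assert result.loc[0, "p"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_small_term_excluded_by_min_set(self):
        universe = self._universe(20)
        query = GeneSet("q", universe.genes[:5])
        terms = {
            "small": GeneSet("small", universe.genes[:4]),
            "ok": GeneSet("ok", universe.genes[:5]),
        }
        result = ora_enrichment(query, terms, OraParams(universe=universe, min_set=5))
        assert list(result["term"]) == ["ok"]

    def test_matches_enumeration_oracle_small_universes(self):
        """p-values agree with direct combinatorial counting for N <= 15."""
        rng = np.random.default_rng(0)
        for N in (8, 12, 15):
            universe = self._universe(N)
            for _ in range(20):
                n = int(rng.integers(1, N))
                K = int(rng.integers(1, N))
                query = GeneSet("q", tuple(rng.choice(universe.genes, n, replace=False)))
                term = GeneSet("t", tuple(rng.choice(universe.genes, K, replace=False)))
                params = OraParams(universe=universe, min_set=1)
                result = ora_enrichment(query, {"t": term}, params)
                k = len(set(query.genes) & set(term.genes))
                assert result.loc[0, "p"] == pytest.approx(
                    _ora_oracle(N, K, n, k), abs=1e-12
                )

    def test_bh_order_matches_p_order(self):
        rng = np.random.default_rng(1)
        universe = self._universe(40)
        query = GeneSet("q", tuple(rng.choice(universe.genes, 10, replace=False)))
        terms = {
            f"t{i}": GeneSet(
                f"t{i}", tuple(rng.choice(universe.genes, 8, replace=False))
            )
            for i in range(10)
        }
        result = ora_enrichment(query, terms, OraParams(universe=universe, min_set=1))
        assert (result["q"] >= result["p"] - 1e-15).all()
        assert list(result.sort_values("q", kind="stable")["term"]) == list(
            result.sort_values("p", kind="stable")["term"]
        )

    def test_empty_query_rejected(self):
        universe = self._universe(10)
        query = GeneSet("q", ("ELSEWHERE",))
        with pytest.raises(ValueError, match="universe"):
            ora_enrichment(query, {}, OraParams(universe=universe))
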