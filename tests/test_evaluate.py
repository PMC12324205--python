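"""PR curves, Mann-Whitney, rank enrichment, distribution diagnostics."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from directppi import evaluate
from directppi.pairs import pair_key


def keyed(labels_by_rank):
    """Build scores/positives/negatives from labels listed by rank."""
    scores, pos, neg = {}, set(), set()
    for rank, label in enumerate(labels_by_rank):
        key = pair_key(f"A{rank}", f"B{rank}")
        scores[key] = 1.0 - 0.1 * rank
        (pos if label else neg).add(key)
    return scores, pos, neg


class TestPRCurve:
    def test_perfect_ranking_has_unit_auprc(self):
        scores, pos, neg = keyed([1, 1, 1, 0, 0])
        assert evaluate.pr_curve(scores, pos, neg).auprc == pytest.approx(1.0)

    def test_hand_enumerated_four_pair_curve(self):
        scores, pos, neg = keyed([1, 1, 0, 1])
        res = evaluate.pr_curve(scores, pos, neg)
        assert res.recall == pytest.approx([1 / 3, 2 / 3, 2 / 3, 1.0])
        assert res.precision == pytest.approx([1.0, 1.0, 2 / 3, 3 / 4])
        assert res.auprc == pytest.approx(1 / 3 + 1 / 3 + 0 + (1 / 3) * (3 / 4))

    def test_complete_benchmark_extends_recall(self):
        scores, pos, neg = keyed([1, 0])
        pos.add(pair_key("ZZ", "YY"))  # positive the network never scored
        partial = evaluate.pr_curve(scores, pos, neg, complete_benchmark=False)
        complete = evaluate.pr_curve(scores, pos, neg, complete_benchmark=True)
        assert partial.recall.max() == pytest.approx(0.5)
        assert complete.recall.max() == pytest.approx(1.0)

    def test_recall_nondecreasing_and_auprc_bounded(self):
        rng = np.random.default_rng(3)
        labels = rng.random(40) < 0.3
        scores = {pair_key(f"A{i}", f"B{i}"): float(rng.random()) for i in range(40)}
        pos = {pair_key(f"A{i}", f"B{i}") for i in range(40) if labels[i]}
        neg = set(scores) - pos
        res = evaluate.pr_curve(scores, pos, neg)
        assert np.all(np.diff(res.recall) >= -1e-15)
        assert 0.0 <= res.auprc <= 1.0

    def test_tiny_noise_identity_on_distinct_scores(self):
        scores, pos, neg = keyed([1, 0, 1, 0, 1])
        plain = evaluate.pr_curve(scores, pos, neg)
        noisy = evaluate.pr_curve(scores, pos, neg, add_tiny_noise=True, seed=1)
        assert plain.auprc == pytest.approx(noisy.auprc, abs=1e-9)
        assert plain.recall == pytest.approx(noisy.recall)

    def test_tiny_noise_splits_ties_reproducibly(self):
        scores = {pair_key(f"A{i}", f"B{i}"): 0.5 for i in range(6)}
        pos = {pair_key(f"A{i}", f"B{i}") for i in range(3)}
        neg = set(scores) - pos
        r1 = evaluate.pr_curve(scores, pos, neg, add_tiny_noise=True, seed=2)
        r2 = evaluate.pr_curve(scores, pos, neg, add_tiny_noise=True, seed=2)
        assert r1.auprc == r2.auprc
        assert len(r1.recall) == 6  # every tie broken into its own threshold

    def test_random_scores_auprc_near_prevalence(self):
        rng = np.random.default_rng(7)
        n, prev = 300, 0.3
        pos = {pair_key(f"A{i}", f"B{i}") for i in range(int(n * prev))}
        neg = {pair_key(f"A{i}", f"B{i}") for i in range(int(n * prev), n)}
        aucs = [
            evaluate.pr_curve(
                {p: float(rng.random()) for p in pos | neg}, pos, neg
            ).auprc
            for _ in range(100)
        ]
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - prev) < 3 * se + 0.01

    def test_empty_positives_rejected(self):
        scores, pos, neg = keyed([0, 0])
        with pytest.raises(ValueError):
            evaluate.pr_curve(scores, set(), neg)


class TestFeatureRanking:
    def test_planted_feature_ranks_first(self):
        import pandas as pd

        rng = np.random.default_rng(11)
        n = 300
        pairs = [pair_key(f"A{i}", f"B{i}") for i in range(n)]
        labels = rng.random(n) < 0.4
        data = {"planted": labels + rng.normal(0, 0.3, n)}
        for j in range(9):
            data[f"noise{j}"] = rng.normal(0, 1, n)
        table = pd.DataFrame(data, index=pd.Index(pairs, name="pair_id"))
        pos = {p for p, l in zip(pairs, labels) if l}
        ranking = evaluate.feature_auprc_ranking(table, pos, set(pairs) - pos)
        assert ranking.iloc[0]["feature"] == "planted"

    def test_anticorrelated_feature_scores_below_prevalence(self):
        import pandas as pd

        rng = np.random.default_rng(12)
        n = 400
        pairs = [pair_key(f"A{i}", f"B{i}") for i in range(n)]
        labels = rng.random(n) < 0.4
        table = pd.DataFrame(
            {"anti": -(labels + rng.normal(0, 0.3, n))},
            index=pd.Index(pairs, name="pair_id"),
        )
        pos = {p for p, l in zip(pairs, labels) if l}
        ranking = evaluate.feature_auprc_ranking(table, pos, set(pairs) - pos)
        assert ranking.iloc[0]["auprc"] < np.mean(labels)

    def test_all_missing_feature_scores_at_prevalence(self):
        import pandas as pd

        pairs = [pair_key(f"A{i}", f"B{i}") for i in range(10)]
        table = pd.DataFrame(
            {"void": [np.nan] * 10}, index=pd.Index(pairs, name="pair_id")
        )
        pos = set(pairs[:4])
        ranking = evaluate.feature_auprc_ranking(table, pos, set(pairs[4:]))
        assert ranking.iloc[0]["auprc"] == pytest.approx(0.4)


class TestMannWhitney:
    def test_fully_separated_triples(self):
        u, p = evaluate.mannwhitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        _, p = evaluate.mannwhitney([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_exact_matches_scipy_enumeration_without_ties(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n1, n2 = rng.integers(2, 6, size=2)
            x = rng.permutation(20)[: n1 + n2].astype(float)
            a, b = list(x[:n1]), list(x[n1:])
            u, p = evaluate.mannwhitney(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_matches_full_permutation_oracle_with_ties(self):
        """Brute-force null over all label arrangements, ties included."""
        rng = np.random.default_rng(14)
        for _ in range(8):
            n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            pooled = rng.integers(0, 4, size=n1 + n2).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            u_obs, p_obs = evaluate.mannwhitney(list(x), list(y))

            ranks = stats.rankdata(pooled)
            center = n1 * n2 / 2
            us = [
                ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
                for idx in combinations(range(n1 + n2), n1)
            ]
            d = abs(u_obs - center)
            expected = np.mean([abs(u - center) >= d - 1e-12 for u in us])
            assert p_obs == pytest.approx(expected)

    def test_large_sample_uses_tie_corrected_normal(self):
        rng = np.random.default_rng(15)
        x = list(rng.integers(0, 10, 30).astype(float))
        y = list(rng.integers(2, 12, 25).astype(float))
        u, p = evaluate.mannwhitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert (u, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            evaluate.mannwhitney([], [1.0])


class TestAssayCountRanking:
    def test_count_is_distinct_assay_cardinality(self):
        net = {
            pair_key("A", "B"): ["y2h", "apms", "y2h"],  # duplicates collapse
            pair_key("C", "D"): ["y2h"],
        }
        scores = evaluate.rank_by_assay_count(net)
        assert scores[pair_key("A", "B")] == 2.0
        assert scores[pair_key("C", "D")] == 1.0

    def test_equal_counts_resolve_by_key(self):
        net = {pair_key("Z", "W"): ["a"], pair_key("A", "B"): ["b"]}
        scores = evaluate.rank_by_assay_count(net)
        assert list(scores.index) == sorted(scores.index)


class TestFractionConfidentAtK:
    def test_hand_counted_fraction(self):
        net = {"A B": 0.9, "C D": 0.8, "E F": 0.7}
        models = {"A B": 0.6, "C D": 0.4, "E F": 0.7}
        res = evaluate.fraction_confident_at_k(net, models, cutoff=0.5, k_grid=[2])
        assert res.fractions[0] == pytest.approx(0.5)

    def test_zero_cutoff_saturates(self):
        net = {"A B": 0.9, "C D": 0.2}
        models = {"A B": 0.1, "C D": 0.0}
        res = evaluate.fraction_confident_at_k(net, models, cutoff=0.0, k_grid=[1, 2])
        assert np.all(res.fractions == 1.0)

    def test_unmodeled_pairs_excluded_by_default(self):
        net = {"A B": 0.99, "C D": 0.5}
        models = {"C D": 0.9}
        res = evaluate.fraction_confident_at_k(net, models, k_grid=[1])
        assert res.fractions[0] == 1.0  # A B has no model, drops from ranking
        res2 = evaluate.fraction_confident_at_k(
            net, models, k_grid=[1], include_unmodeled=True
        )
        assert res2.fractions[0] == 0.0  # top pair now counts as failure

    def test_invariant_to_pairs_below_max_k(self):
        net = {"A B": 0.9, "C D": 0.8, "E F": 0.2, "G H": 0.1}
        models = {k: 0.6 for k in net}
        base = evaluate.fraction_confident_at_k(net, models, k_grid=[1, 2])
        extended = dict(net, **{"I J": 0.01})
        models["I J"] = 0.0
        more = evaluate.fraction_confident_at_k(extended, models, k_grid=[1, 2])
        assert np.array_equal(base.fractions, more.fractions)

    def test_truncation_warns(self):
        net = {"A B": 0.9}
        with pytest.warns(UserWarning, match="truncating"):
            evaluate.fraction_confident_at_k(net, {"A B": 0.6}, k_grid=[5])


class TestScoreDistribution:
    def test_beta_mixture_flagged_bimodal(self):
        rng = np.random.default_rng(16)
        scores = np.r_[rng.beta(1, 20, 5000), rng.beta(20, 1, 2000)]
        res = evaluate.score_distribution_summary(scores)
        assert res.bimodal

    def test_uniform_not_flagged(self):
        rng = np.random.default_rng(17)
        res = evaluate.score_distribution_summary(rng.random(20000))
        assert not res.bimodal

    def test_counts_sum_to_sample_size(self):
        rng = np.random.default_rng(18)
        scores = rng.random(137)
        res = evaluate.score_distribution_summary(scores)
        assert res.counts.sum() == 137
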