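"""Evaluation analytics: precision-recall, rank statistics, enrichment.

Precision-recall here follows benchmark conventions for sparse
prediction sets: with ``complete_benchmark`` enabled, benchmark
positives absent from the scored network are appended at -inf so recall
can reach 1 (the network is penalized for pairs it never scored), and
``add_tiny_noise`` breaks score ties reproducibly with additive uniform
noise on [0, 1e-8].  AUPRC integrates step-wise (precision held constant
between recall steps).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pairs import pair_key

TINY_NOISE_SCALE = 1e-8
EXACT_MW_LIMIT = 20


@dataclass(frozen=True)
class PRResult:
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    auprc: float
    n_positives: int


@dataclass(frozen=True)
class RankEnrichment:
    k_grid: np.ndarray
    fractions: np.ndarray
    cutoff: float


def pr_curve(
    scores: Mapping[str, float],
    positives: set[str],
    negatives: set[str],
    add_tiny_noise: bool = False,
    complete_benchmark: bool = False,
    seed: int = 0,
) -> PRResult:
    """Precision-recall curve of a scored network against benchmark labels.

    Only benchmark pairs participate; scored pairs outside the benchmark
    are ignored.  Recall is always counted against every benchmark
    positive, so unscored positives cap the reachable recall unless
    ``complete_benchmark`` appends the unscored benchmark pairs (both
    classes) at -inf, letting recall reach 1 at the cost of the tied
    low-score block's precision.
    """
    if not positives:
        raise ValueError("need at least one positive pair")
    if positives & negatives:
        raise ValueError("positives and negatives must be disjoint")

    items: list[tuple[float, str, int]] = []
    for label, pairs in ((1, positives), (0, negatives)):
        for pair in pairs:
            if pair in scores:
                items.append((float(scores[pair]), pair, label))
            elif complete_benchmark:
                items.append((-math.inf, pair, label))
    if not any(lab == 1 for _, _, lab in items):
        raise ValueError("no scored positives (complete_benchmark off?)")

    if add_tiny_noise:
        rng = np.random.default_rng(seed)
        items = [
            (s + rng.uniform(0.0, TINY_NOISE_SCALE) if math.isfinite(s) else s, p, l)
            for s, p, l in items
        ]

    items.sort(key=lambda t: (-t[0], t[1]))
    svals = np.array([t[0] for t in items])
    labels = np.array([t[2] for t in items])
    n_pos = len(positives)  # recall denominator: the whole benchmark

    tp = np.cumsum(labels)
    ranks = np.arange(1, len(items) + 1)
    # one curve point per distinct threshold: last index of each tie group
    last_of_group = np.r_[svals[1:] != svals[:-1], True]
    precision = (tp / ranks)[last_of_group]
    recall = (tp / n_pos)[last_of_group]
    thresholds = svals[last_of_group]

    prev_recall = np.r_[0.0, recall[:-1]]
    auprc = float(np.sum((recall - prev_recall) * precision))
    return PRResult(
        precision=precision,
        recall=recall,
        thresholds=thresholds,
        auprc=auprc,
        n_positives=n_pos,
    )


def feature_auprc_ranking(
    table: pd.DataFrame,
    positives: set[str],
    negatives: set[str],
    complete_benchmark: bool = True,
) -> pd.DataFrame:
    """Rank features by the AUPRC of sorting labeled pairs by their value.

    Missing cells leave a pair unscored for that feature; under
    ``complete_benchmark`` unscored positives still count in recall, so a
    feature with no observations scores at label prevalence.
    """
    labeled = (positives | negatives) & set(table.index)
    pos = positives & labeled
    neg = negatives & labeled
    if not pos or not neg:
        raise ValueError("need at least one labeled pair per class")
    rows = []
    for col in table.columns:
        vals = pd.to_numeric(table.loc[sorted(labeled), col], errors="coerce").dropna()
        scores = {p: float(v) for p, v in vals.items()}
        try:
            auprc = pr_curve(
                scores, pos, neg, complete_benchmark=complete_benchmark
            ).auprc
        except ValueError:
            # no scored positives and complete_benchmark off: undefined
            auprc = float("nan")
        rows.append((col, auprc, len(vals)))
    out = pd.DataFrame(rows, columns=["feature", "auprc", "n_observed"])
    return out.sort_values(
        ["auprc", "feature"], ascending=[False, True], ignore_index=True
    )


def _exact_mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact test by enumerating all label arrangements.

    Handles ties through midranks; the null U distribution is symmetric
    about n1*n2/2, so the two-sided p sums both tails at the observed
    distance from the center.
    """
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(pooled)
    center = n1 * n2 / 2.0

    def u_of(idx: tuple[int, ...]) -> float:
        return float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0)

    u_obs = u_of(tuple(range(n1)))
    d_obs = abs(u_obs - center)
    total = 0
    extreme = 0
    for idx in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(idx) - center) >= d_obs - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def mannwhitney(
    scores_pos: Sequence[float], scores_neg: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U statistic of the first sample).

    Exact enumeration over all arrangements for combined n <= 20;
    tie-corrected normal approximation beyond that.
    """
    x = np.asarray(scores_pos, dtype=float)
    y = np.asarray(scores_neg, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if x.size + y.size <= EXACT_MW_LIMIT:
        return _exact_mannwhitney(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def rank_by_assay_count(assays: Mapping[str, Iterable[str]]) -> pd.Series:
    """Score a binary network by the number of distinct supporting assays.

    Used for networks that ship without confidence values; the integer
    assay count plays the role of the score, ties resolved by pair key.
    """
    if not assays:
        raise ValueError("assay lists must be present")
    data = {
        pair_key(*pair.split(" ")): float(len(set(ids)))
        for pair, ids in assays.items()
    }
    return pd.Series(data, name="score").sort_index()


def fraction_confident_at_k(
    network_scores: Mapping[str, float],
    model_scores: Mapping[str, float],
    cutoff: float = 0.5,
    k_grid: Sequence[int] = tuple(range(500, 25001, 500)),
    include_unmodeled: bool = False,
) -> RankEnrichment:
    """Fraction of a network's top-K pairs whose structural-model score
    (e.g. pDockQ) reaches the cutoff.

    By default the ranking is restricted to pairs that have a model; with
    ``include_unmodeled`` every network pair is ranked and model-less
    pairs count as failures.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [0, 1]")
    k_grid = np.asarray(sorted(set(int(k) for k in k_grid)))
    if len(k_grid) == 0 or k_grid[0] < 1:
        raise ValueError("K grid must be strictly increasing positive counts")

    ranked = sorted(
        (
            (pair, s)
            for pair, s in network_scores.items()
            if include_unmodeled or pair in model_scores
        ),
        key=lambda t: (-t[1], t[0]),
    )
    if len(ranked) == 0:
        raise ValueError("no rankable pairs")
    hits = np.array(
        [float(model_scores.get(pair, -math.inf) >= cutoff) for pair, _ in ranked]
    )
    cum = np.cumsum(hits)
    if k_grid[-1] > len(ranked):
        warnings.warn(
            f"K grid reaches {k_grid[-1]} but only {len(ranked)} pairs are "
            "rankable; truncating",
            stacklevel=2,
        )
    ks = np.minimum(k_grid, len(ranked))
    fractions = cum[ks - 1] / ks
    return RankEnrichment(k_grid=k_grid, fractions=fractions, cutoff=cutoff)


@dataclass(frozen=True)
class ScoreDistribution:
    bin_edges: np.ndarray
    counts: np.ndarray
    bimodal: bool
    peak_bins: tuple[int, ...]


def score_distribution_summary(
    scores: Sequence[float], bins: int = 20, dip_fraction: float = 0.10
) -> ScoreDistribution:
    """Histogram plus a simple bimodality flag.

    The distribution is flagged bimodal when the two tallest local maxima
    of the (lightly smoothed) histogram are separated by a valley at
    least ``dip_fraction`` below the smaller peak.
    """
    scores = np.asarray(list(scores), dtype=float)
    counts, edges = np.histogram(scores, bins=bins)
    # 3-point moving average damps sampling noise before peak detection
    padded = np.r_[counts[0], counts, counts[-1]].astype(float)
    smooth = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0

    peaks = [
        i
        for i in range(len(smooth))
        if (i == 0 or smooth[i] > smooth[i - 1])
        and (i == len(smooth) - 1 or smooth[i] >= smooth[i + 1])
    ]
    bimodal = False
    top = sorted(peaks, key=lambda i: -smooth[i])[:2]
    if len(top) == 2:
        i, j = sorted(top)
        valley = smooth[i : j + 1].min()
        smaller = min(smooth[i], smooth[j])
        bimodal = smaller > 0 and valley <= (1.0 - dip_fraction) * smaller
    return ScoreDistribution(
        bin_edges=edges, counts=counts, bimodal=bimodal, peak_bins=tuple(sorted(top))
    )
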