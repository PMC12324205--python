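"""Co-fractionation MS elution-profile similarity features.

Proteins in direct physical contact tend to co-elute during native
biochemical separation, so similarity between their per-fraction
intensity profiles carries contact evidence.  Implemented 1-D vector
comparisons: Pearson correlation, Poisson-noise-averaged Pearson,
co-apex agreement, lag-weighted cross-correlation, and a Euclidean
distance on row-normalized profiles (a distance-type diagnostic that is
excluded from the retention filter).

Feature rows are retained only when at least one similarity-type score
exceeds 0.5 in at least one elution experiment.
"""

from __future__ import annotations

import zlib
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pairs import pair_key

SIMILARITY_METRICS = ("pearson", "poisson", "coapex", "wcc")
DISTANCE_METRICS = ("euc",)
RETENTION_CUTOFF = 0.5


def _as_profiles(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    return a, b


def pearson(profile_a: Sequence[float], profile_b: Sequence[float]) -> float:
    """Pearson r between two elution profiles.

    A zero-variance (flat) profile carries no co-elution evidence, so the
    correlation is defined as 0 in that case rather than NaN.
    """
    a, b = _as_profiles(profile_a, profile_b)
    if a.size < 3:
        raise ValueError("profiles must have length >= 3")
    va = a - a.mean()
    vb = b - b.mean()
    denom = np.sqrt((va @ va) * (vb @ vb))
    if denom == 0.0:
        return 0.0
    return float(np.clip((va @ vb) / denom, -1.0, 1.0))


def poisson_noise_pearson(
    profile_a: Sequence[float],
    profile_b: Sequence[float],
    reps: int = 10,
    seed: int = 0,
    pseudocount: float = 1.0,
    noise_scale: float = 1.0,
) -> float:
    """Mean Pearson r over Poisson-perturbed replicates of both profiles.

    Each replicate adds counts drawn from Poisson(noise_scale*profile +
    pseudocount) per fraction, damping correlations that rest on sparse
    coincidental counts.  With ``noise_scale=0, pseudocount=0`` all draws
    have rate zero and the metric reduces to plain Pearson.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    a, b = _as_profiles(profile_a, profile_b)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(reps):
        na = a + rng.poisson(noise_scale * a + pseudocount)
        nb = b + rng.poisson(noise_scale * b + pseudocount)
        vals.append(pearson(na, nb))
    return float(np.mean(vals))


def coapex(profile_a: Sequence[float], profile_b: Sequence[float]) -> int:
    """1 iff both profiles peak in the same fraction (ties -> lowest index)."""
    a, b = _as_profiles(profile_a, profile_b)
    return int(int(np.argmax(a)) == int(np.argmax(b)))


def weighted_cross_correlation(
    profile_a: Sequence[float], profile_b: Sequence[float], max_lag: int = 2
) -> float:
    """Max over lags |l| <= max_lag of pearson(a, shift(b, l)) / (1 + |l|).

    Shifted profiles are compared on their overlapping fractions, so a
    pair co-eluting with a small chromatographic offset still scores,
    discounted by the lag.  ``max_lag=0`` reduces to plain Pearson.
    """
    a, b = _as_profiles(profile_a, profile_b)
    if max_lag < 0 or max_lag >= a.size:
        raise ValueError("need 0 <= max_lag < profile length")
    best = -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            aa, bb = a[lag:] if lag else a, b[: b.size - lag] if lag else b
        else:
            aa, bb = a[:lag], b[-lag:]
        if aa.size < 3:
            continue
        best = max(best, pearson(aa, bb) / (1 + abs(lag)))
    return float(best)


def normalized_euclidean(profile_a: Sequence[float], profile_b: Sequence[float]) -> float:
    """Euclidean distance between sum-normalized profiles (distance-type)."""
    a, b = _as_profiles(profile_a, profile_b)
    sa, sb = a.sum(), b.sum()
    na = a / sa if sa > 0 else a
    nb = b / sb if sb > 0 else b
    return float(np.linalg.norm(na - nb))


def _metric_value(metric: str, a, b, reps: int, seed: int) -> float:
    if metric == "pearson":
        return pearson(a, b)
    if metric == "poisson":
        return poisson_noise_pearson(a, b, reps=reps, seed=seed)
    if metric == "coapex":
        return float(coapex(a, b))
    if metric == "wcc":
        return weighted_cross_correlation(a, b)
    if metric == "euc":
        return normalized_euclidean(a, b)
    raise ValueError(f"unknown metric {metric!r}")


def coelution_block(
    experiments: Mapping[str, pd.DataFrame],
    metrics: Sequence[str] = SIMILARITY_METRICS + DISTANCE_METRICS,
    reps: int = 10,
    seed: int = 0,
    apply_filter: bool = True,
) -> pd.DataFrame:
    """Per-experiment, per-metric similarity features for all protein pairs.

    ``experiments`` maps an experiment tag to an elution matrix (DataFrame:
    protein rows x fraction columns).  Column names are
    ``<metric>_<experiment-tag>``; ``euc`` columns get the conventional
    ``_pq_euc`` suffix instead.  With ``apply_filter`` rows are dropped
    unless some similarity-type score exceeds 0.5 somewhere.
    """
    if not experiments:
        raise ValueError("need at least one elution experiment")
    unknown = set(metrics) - set(SIMILARITY_METRICS) - set(DISTANCE_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")

    blocks = []
    for tag, elut in experiments.items():
        proteins = list(map(str, elut.index))
        mat = elut.to_numpy(dtype=float)
        rows: dict[str, list[float]] = {}
        cols = [
            f"{tag}_pq_euc" if metric == "euc" else f"{metric}_{tag}"
            for metric in metrics
        ]
        for i, j in combinations(range(len(proteins)), 2):
            key = pair_key(proteins[i], proteins[j])
            # stable across processes, unlike the builtin salted hash
            pair_seed = (zlib.crc32(key.encode()) ^ seed) % (2**31)
            rows[key] = [
                _metric_value(m, mat[i], mat[j], reps, pair_seed) for m in metrics
            ]
        block = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        block.index.name = "pair_id"
        blocks.append(block)

    merged = pd.concat(blocks, axis=1, join="outer").sort_index()
    merged.index.name = "pair_id"
    if apply_filter:
        sim_cols = [
            c
            for c in merged.columns
            if not c.endswith("_pq_euc")
        ]
        keep = (merged[sim_cols] > RETENTION_CUTOFF).any(axis=1)
        merged = merged.loc[keep]
    return merged
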