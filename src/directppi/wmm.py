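"""Weighted matrix model (WMM) co-occurrence features.

The WMM asks, for a pair of proteins observed across a compendium of
pulldown-style experiments, whether they are seen in the same set of
experiments more often than expected by chance.  For counts

* ``k`` — experiments containing both proteins,
* ``n`` — experiments containing protein A,
* ``m`` — experiments containing protein B,
* ``N`` — experiments in the dataset,

the score is the exact hypergeometric upper tail

    p = sum_{i=k}^{min(n,m)} C(n, i) C(N-n, m-i) / C(N, m)

mapped to ``-ln p`` so that strong co-occurrence gives large positive
features.  A companion ``pair_count`` feature records ``k`` itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .pairs import pair_key

#: -ln p is capped here: p below exp(-745) underflows double precision.
NEG_LN_P_CAP = 745.0


@dataclass(frozen=True)
class CoOccurrenceCounts:
    """Sufficient statistics for one pair in one dataset."""

    k: int
    n: int
    m: int
    N: int

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (0 <= self.n <= self.N and 0 <= self.m <= self.N):
            raise ValueError("need 0 <= n, m <= N")
        if not (0 <= self.k <= min(self.n, self.m)):
            raise ValueError("need 0 <= k <= min(n, m)")


def _log_comb(n: int, r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def hypergeometric_tail(c: CoOccurrenceCounts) -> float:
    """Exact upper-tail probability P(#shared >= k | n, m, N).

    Summed in log space; symmetric in (n, m); returns a value in (0, 1].
    ``k = 0`` covers every outcome and gives exactly 1.
    """
    if c.k == 0:
        return 1.0
    i = np.arange(c.k, min(c.n, c.m) + 1)
    log_terms = _log_comb(c.n, i) + _log_comb(c.N - c.n, c.m - i) - _log_comb(c.N, c.m)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def neg_ln_pval(c: CoOccurrenceCounts) -> float:
    """-ln of the hypergeometric tail, floored at 0 and capped at 745."""
    if c.k == 0:
        return 0.0
    i = np.arange(c.k, min(c.n, c.m) + 1)
    log_terms = _log_comb(c.n, i) + _log_comb(c.N - c.n, c.m - i) - _log_comb(c.N, c.m)
    log_p = min(0.0, logsumexp(log_terms))
    return float(min(NEG_LN_P_CAP, -log_p))


@dataclass(frozen=True)
class PresenceRule:
    """Rule deciding whether a protein counts as present in an experiment.

    ``score_threshold`` and ``psm_threshold`` compare a named record field
    against a threshold with comparator ``gt`` or ``ge``; ``any_detection``
    counts any record.  A bait is always present in its own experiment.
    """

    kind: str = "any_detection"  # score_threshold | psm_threshold | any_detection
    field: str = ""
    threshold: float = 0.0
    comparator: str = "ge"  # gt | ge

    def __post_init__(self) -> None:
        if self.kind not in ("score_threshold", "psm_threshold", "any_detection"):
            raise ValueError(f"unknown rule kind: {self.kind}")
        if self.comparator not in ("gt", "ge"):
            raise ValueError(f"unknown comparator: {self.comparator}")
        if self.kind != "any_detection" and not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite for thresholded rules")

    @classmethod
    def parse(cls, text: str) -> "PresenceRule":
        """Parse CLI shorthand like ``zscore:gt:4`` or ``any``."""
        parts = text.split(":")
        if parts == ["any"]:
            return cls()
        if len(parts) != 3:
            raise ValueError(f"cannot parse presence rule {text!r}")
        field, comparator, threshold = parts
        kind = "psm_threshold" if "psm" in field.lower() else "score_threshold"
        return cls(kind=kind, field=field, threshold=float(threshold), comparator=comparator)


def presence_calls(
    compendium: pd.DataFrame, rule: PresenceRule
) -> tuple[dict[str, set[str]], int]:
    """Per-experiment sets of present proteins, plus the experiment count N.

    ``compendium`` rows are (experiment_id, bait_id, prey_id, value columns).
    A protein is present iff it is the experiment's bait or any of its prey
    records satisfies the rule.
    """
    for col in ("experiment_id", "bait_id", "prey_id"):
        if col not in compendium.columns:
            raise ValueError(f"compendium lacks required column {col!r}")
    if rule.kind != "any_detection":
        if rule.field not in compendium.columns:
            raise ValueError(f"unknown presence-rule field {rule.field!r}")
        vals = compendium[rule.field].to_numpy(dtype=float)
        ok = vals > rule.threshold if rule.comparator == "gt" else vals >= rule.threshold
    else:
        ok = np.ones(len(compendium), dtype=bool)

    sets: dict[str, set[str]] = {}
    for eid, bait in zip(compendium["experiment_id"], compendium["bait_id"]):
        sets.setdefault(str(eid), set()).add(str(bait))
    for eid, prey, keep in zip(
        compendium["experiment_id"], compendium["prey_id"], ok
    ):
        if keep:
            sets.setdefault(str(eid), set()).add(str(prey))
    return sets, len(sets)


def wmm_feature_block(
    compendium: pd.DataFrame,
    rule: PresenceRule,
    dataset_tag: str,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """WMM features (``neg_ln_pval_<tag>``, ``pair_count_<tag>``) per pair.

    By default only pairs co-observed in at least one experiment are
    emitted (sparse mode); with ``all_pairs`` every pair of observed
    proteins is emitted, never-co-observed pairs scoring 0.
    """
    sets, n_exp = presence_calls(compendium, rule)
    if n_exp == 0:
        raise ValueError("empty compendium: N = 0")

    per_protein: dict[str, int] = {}
    shared: dict[str, int] = {}
    for members in sets.values():
        for p in members:
            per_protein[p] = per_protein.get(p, 0) + 1
        for a, b in combinations(sorted(members), 2):
            key = pair_key(a, b)
            shared[key] = shared.get(key, 0) + 1

    if all_pairs:
        universe = sorted(per_protein)
        keys: Iterable[str] = (
            pair_key(a, b) for i, a in enumerate(universe) for b in universe[i + 1 :]
        )
    else:
        keys = shared.keys()

    rows = {}
    for key in keys:
        a, b = key.split(" ")
        k = shared.get(key, 0)
        c = CoOccurrenceCounts(k=k, n=per_protein[a], m=per_protein[b], N=n_exp)
        rows[key] = (neg_ln_pval(c), k)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"neg_ln_pval_{dataset_tag}", f"pair_count_{dataset_tag}"]
    )
    out.index.name = "pair_id"
    return out.sort_index()


def merge_feature_blocks(blocks: list[pd.DataFrame]) -> pd.DataFrame:
    """Outer-join feature blocks on the pair key; columns must be disjoint."""
    seen: set[str] = set()
    for block in blocks:
        dup = seen.intersection(block.columns)
        if dup:
            raise ValueError(f"duplicate feature columns across blocks: {sorted(dup)}")
        seen.update(block.columns)
    if not blocks:
        return pd.DataFrame()
    merged = pd.concat(blocks, axis=1, join="outer")
    merged.index.name = "pair_id"
    return merged.sort_index()
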