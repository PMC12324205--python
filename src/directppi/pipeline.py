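"""End-to-end harness: synthetic world -> features -> classifier -> AUPRC.

The parameter-recovery experiment wires the whole pipeline together on a
synthetic world with planted contact structure: simulate a bait–prey
compendium and an elution experiment, build WMM and co-elution feature
blocks, train the classifier on the pairs of half the complexes, and
measure held-out AUPRC on the pairs of the other half.  Complexes are
protein-disjoint, so alternating them between train and test keeps the
two pair sets disjoint at the complex level.  A label-shuffled control
retrains on permuted training labels and should score near the held-out
label prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify, coelution, synthetic, wmm
from .evaluate import pr_curve
from .wmm import PresenceRule


def build_feature_table(
    world: synthetic.SyntheticWorld,
    compendium: pd.DataFrame,
    elutions: pd.DataFrame | list[pd.DataFrame],
    seed: int = 0,
) -> pd.DataFrame:
    """Standard synthetic feature block: two WMM rules + co-elution metrics.

    Several elution experiments may be supplied; coincidental co-elution
    does not replicate across experiments, so per-experiment similarity
    columns jointly separate direct from indirect pairs much better than
    any single experiment.
    """
    if isinstance(elutions, pd.DataFrame):
        elutions = [elutions]
    blocks = [
        wmm.wmm_feature_block(compendium, PresenceRule(), "wmm_any"),
        wmm.wmm_feature_block(
            compendium,
            PresenceRule(kind="psm_threshold", field="psm_count", threshold=4, comparator="ge"),
            "wmm_psm4",
        ),
        coelution.coelution_block(
            {f"elut{i+1:02d}": e for i, e in enumerate(elutions)},
            seed=seed,
            apply_filter=False,
        ),
    ]
    return wmm.merge_feature_blocks(blocks)


def world_label_sets(
    world: synthetic.SyntheticWorld, complex_indices: list[int]
) -> tuple[set[str], set[str]]:
    """(direct, indirect) intra-complex pair labels for chosen complexes."""
    pos: set[str] = set()
    neg: set[str] = set()
    for i in complex_indices:
        cpx = world.complexes[i]
        pos |= cpx.direct_pair_keys()
        neg |= cpx.indirect_pair_keys()
    return pos, neg - pos


@dataclass(frozen=True)
class RecoveryResult:
    auprc: float
    shuffled_auprc: float
    test_prevalence: float
    n_train: int
    n_test: int
    cv_accuracy: float


def parameter_recovery(
    seed: int,
    n_complexes: int = 20,
    size_range: tuple[int, int] = (5, 8),
    n_experiments: int = 300,
    rates: synthetic.CoOccurrenceRates | None = None,
    topology: str = "chain",
    n_elution_experiments: int = 3,
) -> RecoveryResult:
    """Train on half the complexes, score the other half, report AUPRC.

    The shuffled control permutes training labels with the same seed and
    re-evaluates, giving the no-signal baseline.
    """
    world = synthetic.make_world(
        n_complexes=n_complexes,
        size_range=size_range,
        topology=topology,
        rates=rates,
        seed=seed,
    )
    compendium = synthetic.simulate_compendium(world, n_experiments, seed=seed + 1)
    elutions = [
        synthetic.simulate_elution(world, seed=seed + 2 + i)
        for i in range(n_elution_experiments)
    ]
    table = build_feature_table(world, compendium, elutions, seed=seed)

    train_idx = list(range(0, n_complexes, 2))
    test_idx = list(range(1, n_complexes, 2))
    train_pos, train_neg = world_label_sets(world, train_idx)
    test_pos, test_neg = world_label_sets(world, test_idx)

    model = classify.train(table, train_pos, train_neg, seed=seed)
    test_pairs = sorted((test_pos | test_neg) & set(table.index))
    scores = classify.predict(model, table.loc[test_pairs])
    result = pr_curve(dict(scores), test_pos, test_neg, complete_benchmark=True)

    # shuffled-label control: same pairs, permuted training labels
    rng = np.random.default_rng(seed)
    labeled = sorted((train_pos | train_neg) & set(table.index))
    flags = np.array([p in train_pos for p in labeled])
    rng.shuffle(flags)
    shuf_pos = {p for p, f in zip(labeled, flags) if f}
    shuf_neg = {p for p, f in zip(labeled, flags) if not f}
    shuf_model = classify.train(table, shuf_pos, shuf_neg, seed=seed)
    shuf_scores = classify.predict(shuf_model, table.loc[test_pairs])
    shuf_result = pr_curve(dict(shuf_scores), test_pos, test_neg, complete_benchmark=True)

    prevalence = len(test_pos) / (len(test_pos) + len(test_neg))
    return RecoveryResult(
        auprc=result.auprc,
        shuffled_auprc=shuf_result.auprc,
        test_prevalence=prevalence,
        n_train=len(labeled),
        n_test=len(test_pairs),
        cv_accuracy=model.mean_cv_accuracy,
    )
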