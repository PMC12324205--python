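"""Gradient-boosted classification of direct vs indirect protein pairs.

A single LightGBM learner under stratified K-fold cross-validation turns
the pair feature table into a probability-like direct-contact score in
[0, 1].  Missing feature cells are passed straight to the learner's
native missing-value handling — absence of evidence is informative and
is not imputed.  Scores are tiered at 0.7 (confident) and 0.9 (highly
confident) for network export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier, early_stopping
from sklearn.model_selection import StratifiedKFold

from .evaluate import pr_curve
from .pairs import write_pairs_wprob

log = logging.getLogger(__name__)

DEFAULT_LEARNER_PARAMS: dict = {
    "n_estimators": 500,
    "learning_rate": 0.05,
    "num_leaves": 31,
    "deterministic": True,
    "force_row_wise": True,
    "n_jobs": 1,
    "verbosity": -1,
}

TIER_THRESHOLDS = (0.7, 0.9)


def _labels_to_series(
    table: pd.DataFrame, positives: set[str], negatives: set[str]
) -> pd.Series:
    overlap = positives & negatives
    if overlap:
        raise ValueError(f"pairs labeled both positive and negative: {sorted(overlap)[:3]}")
    labeled = sorted((positives | negatives) & set(table.index))
    if not labeled:
        raise ValueError("no labeled pairs present in the feature table")
    return pd.Series(
        [1 if p in positives else 0 for p in labeled], index=labeled, dtype=int
    )


def _single_feature_auprc(values: pd.Series, labels: pd.Series) -> float:
    """AUPRC of ranking labeled rows by one feature (missing ranked last)."""
    scores = {
        p: (float(v) if np.isfinite(v) else -np.inf)
        for p, v in values.items()
    }
    pos = {p for p in labels.index if labels[p] == 1}
    neg = set(labels.index) - pos
    return pr_curve(scores, pos, neg, complete_benchmark=True).auprc


def prune_features(
    table: pd.DataFrame,
    positives: set[str],
    negatives: set[str],
    min_obs: int = 5,
    screen: bool = False,
    screen_epsilon: float = 0.02,
) -> tuple[list[str], dict[str, str]]:
    """Split features into retained and dropped(reason) lists.

    ``no_information``: fewer than ``min_obs`` observed values, or zero
    variance, among labeled rows.  With the optional predictive
    ``screen``, features whose single-feature AUPRC does not beat label
    prevalence by ``screen_epsilon`` are dropped as ``no_signal``.
    """
    labels = _labels_to_series(table, positives, negatives)
    sub = table.loc[labels.index]
    prevalence = float(labels.mean())

    retained: list[str] = []
    dropped: dict[str, str] = {}
    for col in table.columns:
        vals = pd.to_numeric(sub[col], errors="coerce")
        observed = vals.dropna()
        if len(observed) < min_obs or observed.nunique() <= 1:
            dropped[col] = "no_information"
            continue
        if screen and _single_feature_auprc(vals, labels) <= prevalence + screen_epsilon:
            dropped[col] = "no_signal"
            continue
        retained.append(col)
    return retained, dropped


@dataclass
class TrainedModel:
    booster: LGBMClassifier
    features: list[str]
    dropped: dict[str, str]
    cv_accuracy: list[float]
    cv_auprc: list[float]
    seed: int
    learner_params: dict = field(default_factory=dict)

    @property
    def mean_cv_accuracy(self) -> float:
        return float(np.mean(self.cv_accuracy))

    @property
    def mean_cv_auprc(self) -> float:
        return float(np.mean(self.cv_auprc))


def train(
    table: pd.DataFrame,
    positives: set[str],
    negatives: set[str],
    seed: int = 0,
    folds: int = 5,
    learner_params: Mapping | None = None,
    min_obs: int = 5,
    screen: bool = False,
    early_stopping_rounds: int | None = 25,
) -> TrainedModel:
    """Cross-validated LightGBM fit on labeled rows of the feature table.

    Reports per-fold held-out accuracy and AUPRC, then refits on all
    labeled rows for deployment.  Deterministic given the seed.
    """
    labels = _labels_to_series(table, positives, negatives)
    if labels.nunique() < 2:
        raise ValueError("both classes must be present in the labels")
    features, dropped = prune_features(
        table, positives, negatives, min_obs=min_obs, screen=screen
    )
    if not features:
        raise ValueError("no informative features retained")
    params = dict(DEFAULT_LEARNER_PARAMS)
    if learner_params:
        params.update(learner_params)

    X = table.loc[labels.index, features].apply(pd.to_numeric, errors="coerce")
    y = labels.to_numpy()

    n_splits = min(folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("too few examples of the minority class for CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs: list[float] = []
    auprcs: list[float] = []
    for tr, va in skf.split(X, y):
        model = LGBMClassifier(random_state=seed, **params)
        fit_kwargs = {}
        if early_stopping_rounds:
            fit_kwargs = {
                "eval_set": [(X.iloc[va], y[va])],
                "eval_metric": "binary_error",
                "callbacks": [early_stopping(early_stopping_rounds, verbose=False)],
            }
        model.fit(X.iloc[tr], y[tr], **fit_kwargs)
        prob = model.predict_proba(X.iloc[va])[:, 1]
        accs.append(float(np.mean((prob >= 0.5) == y[va])))
        pos = {p for p, lab in zip(X.index[va], y[va]) if lab == 1}
        neg = {p for p, lab in zip(X.index[va], y[va]) if lab == 0}
        scores = dict(zip(X.index[va], map(float, prob)))
        auprcs.append(pr_curve(scores, pos, neg).auprc)

    final = LGBMClassifier(random_state=seed, **params)
    final.fit(X, y)
    return TrainedModel(
        booster=final,
        features=list(features),
        dropped=dropped,
        cv_accuracy=accs,
        cv_auprc=auprcs,
        seed=seed,
        learner_params=params,
    )


def predict(model: TrainedModel, table: pd.DataFrame) -> pd.Series:
    """Score every row of the table; one probability-like value in [0, 1].

    Columns are aligned to the training feature list (order-invariant);
    features absent from the table are treated as missing.
    """
    X = table.reindex(columns=model.features).apply(pd.to_numeric, errors="coerce")
    prob = model.booster.predict_proba(X)[:, 1]
    return pd.Series(np.clip(prob, 0.0, 1.0), index=table.index, name="score")


def tier_and_export(
    scores: pd.Series,
    out_prefix: str | Path,
    thresholds: Sequence[float] = TIER_THRESHOLDS,
) -> dict[str, Path]:
    """Write the full scored network plus one file per confidence tier.

    Tier membership is inclusive (score >= threshold), so the tiers nest.
    Files use the pairsWprob dialect, descending score, key-stable ties.
    """
    lo, hi = thresholds
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("thresholds must be ascending within [0, 1]")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "all": out_prefix.with_name(out_prefix.name + ".pairsWprob"),
        "confident": out_prefix.with_name(out_prefix.name + ".confident.pairsWprob"),
        "highly_confident": out_prefix.with_name(
            out_prefix.name + ".highly_confident.pairsWprob"
        ),
    }
    write_pairs_wprob(scores, paths["all"])
    write_pairs_wprob(scores[scores >= lo], paths["confident"])
    write_pairs_wprob(scores[scores >= hi], paths["highly_confident"])
    return paths
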