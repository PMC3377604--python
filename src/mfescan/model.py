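"""Paired SVM / random-forest classifiers with consensus MFE calling.

Both learners are trained on the same 188-D features and expose a
probability of the positive (MFE) class.  The SVM is an RBF-kernel
soft-margin classifier with Platt-calibrated probabilities, trained on
per-feature standardized inputs (distribution descriptors live on a 0-100
scale while the rest are 0-1, and margin methods are scale-sensitive); its
C and gamma are chosen by grid search with an inner cross-validation on the
training data.  The random forest votes 500 unpruned trees over raw
features, each split drawing sqrt(188) candidate features; its probability
is the fraction of trees voting positive.

A protein is called an MFE only when both models agree strongly:
SVM probability > 0.90 AND RF probability > 0.80 (strict inequalities).
Five-fold stratified cross-validation, with the scaler and both models
refitted inside every training fold, measures generalization without
leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from mfescan.ctd import GROUPINGS_VERSION, N_FEATURES, encode_batch, feature_names
from mfescan.dataset import LabeledDataset, NEGATIVE_LABEL, POSITIVE_LABEL
from mfescan.evaluation import ConfusionCounts
from mfescan.sequence_io import ProteinRecord, filter_by_length

logger = logging.getLogger(__name__)

SVM_THRESHOLD = 0.90
RF_THRESHOLD = 0.80


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for the paired learners.

    ``svm_c_grid`` / ``svm_gamma_grid`` span the standard libsvm search
    ranges (powers of two); set ``grid_search=False`` to train at the fixed
    ``svm_c`` / ``svm_gamma`` instead (much faster, used for large runs
    where the defaults are known to be adequate).
    """

    svm_c_grid: tuple[float, ...] = tuple(2.0 ** e for e in range(-2, 7))
    svm_gamma_grid: tuple[float, ...] = tuple(2.0 ** e for e in range(-7, 2))
    grid_search: bool = True
    inner_cv: int = 3
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"
    rf_trees: int = 500
    svm_threshold: float = SVM_THRESHOLD
    rf_threshold: float = RF_THRESHOLD


@dataclass
class ModelPair:
    """Fitted SVM + RF with the training-fold scaler and provenance."""

    svm_model: CalibratedClassifierCV
    rf_model: RandomForestClassifier
    scaler: StandardScaler
    config: ModelConfig
    seed: int
    groupings_version: str = GROUPINGS_VERSION

    def predict_proba(self, features: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Probability of the MFE class from each model, per row."""
        x = np.asarray(features, dtype=float)
        if x.ndim != 2 or x.shape[1] != N_FEATURES:
            raise ValueError(f"expected (n, {N_FEATURES}) feature matrix")
        svm_pos = list(self.svm_model.classes_).index(POSITIVE_LABEL)
        rf_pos = list(self.rf_model.classes_).index(POSITIVE_LABEL)
        svm_prob = self.svm_model.predict_proba(self.scaler.transform(x))[:, svm_pos]
        rf_prob = self.rf_model.predict_proba(x)[:, rf_pos]
        return svm_prob, rf_prob


@dataclass(frozen=True)
class PredictionResult:
    """Audit record for one screened protein: both probabilities + the call."""

    id: str
    svm_prob: float
    rf_prob: float
    call: bool


def _check_two_classes(labels: np.ndarray) -> None:
    classes = set(np.unique(labels))
    if classes != {POSITIVE_LABEL, NEGATIVE_LABEL}:
        raise ValueError(
            f"training requires both classes (+1 and -1); got labels {sorted(classes)}"
        )


def train_pair(
    dataset: LabeledDataset,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> ModelPair:
    """Fit the SVM/RF pair on the full dataset; deterministic per seed."""
    config = config or ModelConfig()
    _check_two_classes(dataset.labels)
    x = dataset.features.to_numpy(dtype=float)
    y = dataset.labels
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)

    if config.grid_search:
        inner = StratifiedKFold(
            n_splits=config.inner_cv, shuffle=True, random_state=seed
        )
        search = GridSearchCV(
            SVC(kernel="rbf"),
            {"C": list(config.svm_c_grid), "gamma": list(config.svm_gamma_grid)},
            cv=inner,
            n_jobs=1,
        )
        search.fit(xs, y)
        best_c = float(search.best_params_["C"])
        best_gamma = float(search.best_params_["gamma"])
        logger.info("SVM grid search: C=%g gamma=%g", best_c, best_gamma)
    else:
        best_c, best_gamma = config.svm_c, config.svm_gamma

    # Platt-style sigmoid calibration on internal CV predictions, then a
    # final SVC refit on all training rows (ensemble=False).
    svm = CalibratedClassifierCV(
        SVC(kernel="rbf", C=best_c, gamma=best_gamma),
        method="sigmoid",
        ensemble=False,
        cv=StratifiedKFold(n_splits=5, shuffle=True, random_state=seed),
    ).fit(xs, y)
    rf = RandomForestClassifier(
        n_estimators=config.rf_trees,
        max_features="sqrt",
        max_depth=None,
        random_state=seed,
        n_jobs=1,
    ).fit(x, y)
    return ModelPair(svm_model=svm, rf_model=rf, scaler=scaler, config=config, seed=seed)


@dataclass
class CVResult:
    """Per-fold and pooled confusion counts for each model.

    ``fold_assignment`` maps row id to fold index (exported for audit);
    ``fold_pairs`` keeps the per-fold fitted models so scaling statistics
    can be inspected.
    """

    fold_counts: dict[str, list[ConfusionCounts]]
    pooled: dict[str, ConfusionCounts]
    fold_assignment: pd.Series
    fold_pairs: list[ModelPair] = field(default_factory=list)


def _tally(y_true: np.ndarray, calls: np.ndarray) -> ConfusionCounts:
    pos = y_true == POSITIVE_LABEL
    return ConfusionCounts(
        tp=int(np.sum(calls & pos)),
        fp=int(np.sum(calls & ~pos)),
        tn=int(np.sum(~calls & ~pos)),
        fn=int(np.sum(~calls & pos)),
    )


def cross_validate(
    dataset: LabeledDataset,
    k: int = 5,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV; scaler and models refit inside each training fold.

    Counts are tallied per model at the 0.5 probability cut ("svm", "rf")
    and for the dual-threshold consensus rule ("consensus"); pooled counts
    sum the folds, so every row is predicted exactly once by a model that
    never saw it.
    """
    config = config or ModelConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    _check_two_classes(dataset.labels)
    y = dataset.labels
    for cls in (POSITIVE_LABEL, NEGATIVE_LABEL):
        if int(np.sum(y == cls)) < k:
            raise ValueError(f"class {cls:+d} has fewer than k={k} members")
    x = dataset.features
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_counts: dict[str, list[ConfusionCounts]] = {"svm": [], "rf": [], "consensus": []}
    assignment = pd.Series(index=pd.Index(dataset.ids, name="id"), dtype=int, name="fold")
    fold_pairs: list[ModelPair] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(x, y)):
        train = LabeledDataset(
            features=x.iloc[train_idx],
            labels=y[train_idx],
            ids=[dataset.ids[i] for i in train_idx],
        )
        pair = train_pair(train, config=config, seed=seed)
        fold_pairs.append(pair)
        svm_prob, rf_prob = pair.predict_proba(x.iloc[test_idx])
        y_test = y[test_idx]
        assignment.iloc[test_idx] = fold
        fold_counts["svm"].append(_tally(y_test, svm_prob > 0.5))
        fold_counts["rf"].append(_tally(y_test, rf_prob > 0.5))
        consensus = np.array(
            [
                consensus_call(s, r, config.svm_threshold, config.rf_threshold)
                for s, r in zip(svm_prob, rf_prob)
            ]
        )
        fold_counts["consensus"].append(_tally(y_test, consensus))
    pooled = {
        name: sum(counts[1:], counts[0]) for name, counts in fold_counts.items()
    }
    return CVResult(
        fold_counts=fold_counts,
        pooled=pooled,
        fold_assignment=assignment,
        fold_pairs=fold_pairs,
    )


def consensus_call(
    svm_prob: float,
    rf_prob: float,
    svm_threshold: float = SVM_THRESHOLD,
    rf_threshold: float = RF_THRESHOLD,
) -> bool:
    """True iff both probabilities strictly exceed their thresholds."""
    for name, p in (("svm_prob", svm_prob), ("rf_prob", rf_prob)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name}={p} outside [0, 1]")
    return (svm_prob > svm_threshold) and (rf_prob > rf_threshold)


def screen_catalog(
    records: Sequence[ProteinRecord],
    pair: ModelPair,
    min_length: int = 100,
) -> list[PredictionResult]:
    """Apply length filter, encoder, both models and the consensus rule.

    Records shorter than ``min_length + 1`` residues are excluded; records
    that fail encoding are skipped with a warning. Results carry both
    probabilities for audit.
    """
    kept = filter_by_length(list(records), min_exclusive=min_length)
    n_filtered = len(records) - len(kept)
    encodable: list[ProteinRecord] = []
    for rec in kept:
        try:
            encode_batch([rec])
        except Exception as exc:  # noqa: BLE001 - reported, not fatal
            logger.warning("skipping record %s: %s", rec.id, exc)
            continue
        encodable.append(rec)
    logger.info(
        "screen: %d records in, %d below length cutoff, %d failed encoding",
        len(records), n_filtered, len(kept) - len(encodable),
    )
    if not encodable:
        return []
    features = encode_batch(encodable)
    svm_prob, rf_prob = pair.predict_proba(features)
    return [
        PredictionResult(
            id=rec.id,
            svm_prob=float(s),
            rf_prob=float(r),
            call=consensus_call(
                float(s), float(r), pair.config.svm_threshold, pair.config.rf_threshold
            ),
        )
        for rec, s, r in zip(encodable, svm_prob, rf_prob)
    ]


def predictions_table(results: Sequence[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"id": r.id, "svm_prob": r.svm_prob, "rf_prob": r.rf_prob, "call": r.call}
            for r in results
        ],
        columns=["id", "svm_prob", "rf_prob", "call"],
    )


def save_model(pair: ModelPair, path: str | Path) -> None:
    """Persist the fitted pair with config, seed and grouping-table version."""
    joblib.dump(
        {
            "svm_model": pair.svm_model,
            "rf_model": pair.rf_model,
            "scaler": pair.scaler,
            "config": asdict(pair.config),
            "seed": pair.seed,
            "groupings_version": pair.groupings_version,
            "feature_names": feature_names(),
        },
        path,
    )


def load_model(path: str | Path) -> ModelPair:
    """Load a saved pair; refuses a grouping-table version mismatch."""
    blob = joblib.load(path)
    if blob["groupings_version"] != GROUPINGS_VERSION:
        raise ValueError(
            f"model was trained with grouping table version "
            f"{blob['groupings_version']!r} but this installation provides "
            f"{GROUPINGS_VERSION!r}; re-train rather than silently re-encode"
        )
    cfg = blob["config"]
    cfg["svm_c_grid"] = tuple(cfg["svm_c_grid"])
    cfg["svm_gamma_grid"] = tuple(cfg["svm_gamma_grid"])
    return ModelPair(
        svm_model=blob["svm_model"],
        rf_model=blob["rf_model"],
        scaler=blob["scaler"],
        config=ModelConfig(**cfg),
        seed=blob["seed"],
        groupings_version=blob["groupings_version"],
    )
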