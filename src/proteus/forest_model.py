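"""Random-forest classification of protean residues.

A forest of depth-limited decision trees is trained on the per-residue
feature vectors; the per-residue score is the fraction of trees voting
positive (hard per-tree majority vote, not probability averaging), and a
residue is called protean when that fraction reaches the probability cutoff
``p_cut`` (ties positive). Defaults follow the tuned operating point for
this problem: depth 13, 500 trees (50 for the exhaustive feature-group
search), ``p_cut`` 0.5.

Cross-validation here is cluster-grouped: the PSSM scaler is refitted on
each training split only, so test proteins can only clamp, never stretch,
the feature scale.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .dataset_folds import FoldAssignment, split
from .io_tracks import ProteinData
from .windowed_features import (
    FeatureConfig,
    PssmScaler,
    assemble_features,
    group_columns,
)


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    max_depth: int = 13
    p_cut: float = 0.5
    seed: int = 0
    feature_groups: frozenset[int] = frozenset({1, 2, 3, 4, 5, 6, 7})
    class_weight: str | None = None  # hook; off by default

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.max_depth <= 25:
            raise ValueError("max_depth must be in [1, 25]")
        if not 0.0 <= self.p_cut <= 1.0:
            raise ValueError("p_cut must be in [0, 1]")
        object.__setattr__(self, "feature_groups", frozenset(self.feature_groups))


@dataclass
class TrainedModel:
    """A fitted forest bundled with everything prediction needs."""

    forest: RandomForestClassifier
    config: ForestConfig
    columns: np.ndarray  # 0-based columns of the full 342-wide matrix
    scaler: PssmScaler | None = None
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def _data_hash(features: np.ndarray, labels: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(features).tobytes())
    h.update(np.ascontiguousarray(labels).tobytes())
    return h.hexdigest()[:16]


def train(
    features: np.ndarray,
    labels: np.ndarray,
    config: ForestConfig | None = None,
    scaler: PssmScaler | None = None,
    feature_config: FeatureConfig | None = None,
    subset_columns: bool = True,
) -> TrainedModel:
    """Fit the forest on residue feature vectors.

    ``features`` is the full 342-column matrix (rows pooled over proteins);
    columns are restricted to ``config.feature_groups`` internally when
    ``subset_columns`` is true.
    """
    cfg = config or ForestConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(np.int64).ravel()
    if features.shape[0] != labels.shape[0]:
        raise ValueError("feature rows and labels differ in length")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    cols = group_columns(cfg.feature_groups) if subset_columns else np.arange(features.shape[1])
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        random_state=cfg.seed,
        class_weight=cfg.class_weight,
        n_jobs=1,
    )
    forest.fit(features[:, cols], labels)
    meta = {
        "corpus_hash": _data_hash(features[:, cols], labels),
        "trained_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "n_examples": int(labels.shape[0]),
        "n_positive": int(labels.sum()),
        "criterion": forest.criterion,
        "max_features": forest.max_features,
        "bootstrap": forest.bootstrap,
    }
    return TrainedModel(
        forest=forest,
        config=cfg,
        columns=cols,
        scaler=scaler,
        feature_config=feature_config or FeatureConfig(),
        metadata=meta,
    )


def predict_scores(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Per-residue score: fraction of trees voting positive."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] == 342:
        X = features[:, model.columns]
    elif features.shape[1] == model.columns.shape[0]:
        X = features
    else:
        raise ValueError(
            f"feature matrix has {features.shape[1]} columns; expected 342 "
            f"or the model's {model.columns.shape[0]}-column subset"
        )
    votes = np.zeros(X.shape[0])
    for tree in model.forest.estimators_:
        votes += tree.predict(X)
    return votes / len(model.forest.estimators_)


def classify(scores: np.ndarray, p_cut: float = 0.5) -> np.ndarray:
    """Binary calls at the probability cutoff; ties classified positive."""
    scores = np.asarray(scores, dtype=float)
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("scores outside [0, 1]")
    return (scores >= p_cut).astype(np.int64)


# ---------------------------------------------------------------------------
# Corpus-level training and cross-validation


def _corpus_features(
    proteins: Sequence[ProteinData],
    scaler: PssmScaler,
    feature_config: FeatureConfig,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Pool full 342-column matrices and labels over proteins."""
    mats, labs, spans = [], [], []
    for prot in proteins:
        fm = assemble_features(
            prot.sequence,
            scaler.transform(prot.pssm),
            prot.ss,
            prot.diso,
            config=feature_config,
            protein_id=prot.id,
        )
        mats.append(fm.values)
        if prot.labels is None:
            raise ValueError(f"protein {prot.id!r} has no labels")
        labs.append(prot.labels.labels)
        spans.append((prot.id, len(prot)))
    return np.vstack(mats), np.concatenate(labs), spans


def train_corpus(
    proteins: Sequence[ProteinData],
    config: ForestConfig | None = None,
    feature_config: FeatureConfig | None = None,
) -> TrainedModel:
    """Fit the scaler and forest on a labelled corpus."""
    fc = feature_config or FeatureConfig()
    scaler = PssmScaler.fit([p.pssm for p in proteins])
    X, y, _ = _corpus_features(proteins, scaler, fc)
    return train(X, y, config, scaler=scaler, feature_config=fc)


def predict_corpus(
    model: TrainedModel, proteins: Sequence[ProteinData]
) -> dict[str, np.ndarray]:
    """Score every residue of every protein with a trained model."""
    if model.scaler is None:
        raise ValueError("model has no PSSM scaler; cannot predict from raw tracks")
    out: dict[str, np.ndarray] = {}
    for prot in proteins:
        fm = assemble_features(
            prot.sequence,
            model.scaler.transform(prot.pssm),
            prot.ss,
            prot.diso,
            config=model.feature_config,
            protein_id=prot.id,
        )
        out[prot.id] = predict_scores(model, fm.values)
    return out


def cross_validate(
    dataset: Sequence[ProteinData],
    folds: FoldAssignment,
    config: ForestConfig | None = None,
    feature_config: FeatureConfig | None = None,
    label_override: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Out-of-fold score track for every residue of every protein.

    For each rotation the PSSM scaler is refitted on the training split
    only. ``label_override`` substitutes per-protein label vectors (used for
    shuffled-label controls) without touching the dataset.
    """
    cfg = config or ForestConfig()
    fc = feature_config or FeatureConfig()
    out: dict[str, np.ndarray] = {}
    for test_fold in range(folds.k):
        train_set, test_set = split(dataset, folds, test_fold)
        scaler = PssmScaler.fit([p.pssm for p in train_set])
        X_tr, y_tr, _ = _corpus_features(train_set, scaler, fc)
        if label_override is not None:
            y_tr = np.concatenate([label_override[p.id] for p in train_set])
        model = train(X_tr, y_tr, cfg, scaler=scaler, feature_config=fc)
        for prot in test_set:
            fm = assemble_features(
                prot.sequence,
                scaler.transform(prot.pssm),
                prot.ss,
                prot.diso,
                config=fc,
                protein_id=prot.id,
            )
            out[prot.id] = predict_scores(model, fm.values)
    return out


def pooled(
    tracks: dict[str, np.ndarray], dataset: Sequence[ProteinData],
    label_override: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool score tracks and labels into aligned flat vectors (corpus order)."""
    scores, labels = [], []
    for prot in dataset:
        scores.append(tracks[prot.id])
        if label_override is not None:
            labels.append(label_override[prot.id])
        else:
            labels.append(prot.labels.labels)
    return np.concatenate(scores), np.concatenate(labels)


def group_subset_search(
    dataset: Sequence[ProteinData],
    folds: FoldAssignment,
    n_trees: int = 50,
    config: ForestConfig | None = None,
    feature_config: FeatureConfig | None = None,
) -> list[dict]:
    """Exhaustively cross-validate all 127 non-empty feature-group subsets.

    The full feature matrices are assembled once per rotation; each subset
    then reuses them by column selection. Returns one row per subset with
    its micro-averaged out-of-fold MCC and F1 at the configured cutoff, plus
    rank fields under both orderings.
    """
    from .evaluation import confusion, f1 as f1_of, mcc as mcc_of

    base = config or ForestConfig(n_trees=n_trees)
    if base.n_trees != n_trees:
        base = replace(base, n_trees=n_trees)
    fc = feature_config or FeatureConfig()

    per_fold: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    for test_fold in range(folds.k):
        train_set, test_set = split(dataset, folds, test_fold)
        scaler = PssmScaler.fit([p.pssm for p in train_set])
        X_tr, y_tr, _ = _corpus_features(train_set, scaler, fc)
        X_te, y_te, _ = _corpus_features(test_set, scaler, fc)
        per_fold.append((X_tr, y_tr, X_te, y_te))

    rows: list[dict] = []
    all_groups = (1, 2, 3, 4, 5, 6, 7)
    for r in range(1, 8):
        for subset in itertools.combinations(all_groups, r):
            cols = group_columns(set(subset))
            cfg = replace(base, feature_groups=frozenset(subset))
            calls_all, truth_all = [], []
            for X_tr, y_tr, X_te, y_te in per_fold:
                model = train(
                    X_tr[:, cols], y_tr, cfg, feature_config=fc, subset_columns=False
                )
                scores = predict_scores(model, X_te[:, cols])
                calls_all.append(classify(scores, cfg.p_cut))
                truth_all.append(y_te)
            c = confusion(np.concatenate(calls_all), np.concatenate(truth_all))
            rows.append({"groups": subset, "mcc": mcc_of(c), "f1": f1_of(c)})
    for key in ("mcc", "f1"):
        order = sorted(range(len(rows)), key=lambda i: -rows[i][key])
        for rank, i in enumerate(order, start=1):
            rows[i][f"rank_{key}"] = rank
    return rows


def feature_importance(model: TrainedModel) -> list[dict]:
    """Impurity-decrease importances averaged over trees, with group labels.

    Importances are non-negative and sum to 1 over the model's columns.
    """
    from .windowed_features import GROUP_RANGES, feature_names

    imp = model.forest.feature_importances_
    names = feature_names()
    out = []
    for col0, w in zip(model.columns, imp):
        feature_no = int(col0) + 1
        group = next(g for g, (lo, hi) in GROUP_RANGES.items() if lo <= feature_no <= hi)
        out.append(
            {
                "feature": feature_no,
                "name": names[col0],
                "group": group,
                "importance": float(w),
            }
        )
    return out
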