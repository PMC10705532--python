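"""Random-forest genotype classification with cross-validated model selection.

Hyperparameters are chosen by stratified 5-fold cross-validation over a
small grid, the winning configuration is refit on all training data, and
the fitted ensemble is applied to new feature vectors.  Every prediction is
one of the six diploid genotype classes; a prediction is *flagged* (never
withheld) when the maximum class probability falls below a confidence
threshold or the feature vector contains no counts at all.

Feature vectors are only comparable to models trained on the same k-mer
index; both sides carry the index hash and mismatches are hard errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .dataset import FeatureDataset
from .kmers import KmerFeatureVector
from .variants import ALL_GENOTYPES, GenotypeLabel

__all__ = [
    "TrainingConfig",
    "TrainedGenotyper",
    "IndexHashMismatch",
    "DEFAULT_GRID",
    "FAST_GRID",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_MODEL_FORMAT_VERSION = 1

#: Default hyperparameter grid, ordered for tie-breaking: fewer trees first,
#: then shallower (bounded before unbounded depth), then fewer features.
DEFAULT_GRID: tuple[dict, ...] = tuple(
    {"n_estimators": n, "max_depth": d, "max_features": f}
    for n in (100, 300)
    for d in (20, None)
    for f in ("sqrt", 0.3)
)

#: Reduced grid for quick, coverage-matched retraining runs.
FAST_GRID: tuple[dict, ...] = tuple(
    {"n_estimators": 100, "max_depth": d, "max_features": f}
    for d in (20, None)
    for f in ("sqrt", 0.3)
)


class IndexHashMismatch(ValueError):
    """A feature vector was built on a different k-mer index than the model."""


@dataclass(frozen=True)
class TrainingConfig:
    n_folds: int = 5
    grid: tuple[dict, ...] = DEFAULT_GRID
    seed: int = 42
    n_train_samples: int = 240
    per_sample_coverage: float = 30.0
    confidence_threshold: float = 0.5

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if not self.grid:
            raise ValueError("hyperparameter grid must not be empty")
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must be in [0, 1]")


@dataclass
class TrainedGenotyper:
    forest: RandomForestClassifier
    feature_index_hash: str
    class_labels: tuple[GenotypeLabel, ...]
    cv_report: list[dict] = field(default_factory=list)
    chosen_params: dict = field(default_factory=dict)
    confidence_threshold: float = 0.5


def _tie_break_key(params: dict) -> tuple:
    depth = params.get("max_depth")
    mf = params.get("max_features")
    mf_key = -1.0 if mf == "sqrt" else float(mf)
    return (params.get("n_estimators", 0), np.inf if depth is None else depth, mf_key)


def _as_matrix(features, labels):
    if isinstance(features, FeatureDataset):
        return features.X, list(features.labels), features.index_hash
    vectors = list(features)
    if vectors and isinstance(vectors[0], KmerFeatureVector):
        hashes = {v.index_hash for v in vectors}
        if len(hashes) > 1:
            raise IndexHashMismatch(
                f"training vectors built on multiple indexes: {sorted(hashes)}"
            )
        X = np.stack([v.counts for v in vectors]).astype(np.float32)
        return X, list(labels), hashes.pop() if hashes else ""
    X = np.asarray(features, dtype=np.float32)
    return X, list(labels), ""


def train(
    features,
    labels=None,
    config: TrainingConfig | None = None,
    index_hash: str | None = None,
) -> TrainedGenotyper:
    """Grid-search hyperparameters by stratified CV accuracy and refit.

    ``features`` may be a :class:`~svkg.dataset.FeatureDataset`, a list of
    :class:`~svkg.kmers.KmerFeatureVector`, or a plain matrix (then pass
    ``labels`` and ``index_hash``).  Deterministic for a given config seed.
    """
    config = config or TrainingConfig()
    config.validate()
    X, y_labels, inferred_hash = _as_matrix(features, labels)
    feature_hash = index_hash if index_hash is not None else inferred_hash

    label_to_idx = {g: i for i, g in enumerate(ALL_GENOTYPES)}
    y = np.array([label_to_idx[g] for g in y_labels], dtype=np.int64)
    counts = np.bincount(y, minlength=len(ALL_GENOTYPES))
    missing = [str(g) for g, c in zip(ALL_GENOTYPES, counts) if c == 0]
    if missing:
        raise ValueError(f"classes absent from training data: {missing}")
    thin = [str(g) for g, c in zip(ALL_GENOTYPES, counts) if c < config.n_folds]
    if thin:
        raise ValueError(
            f"classes with fewer than n_folds={config.n_folds} training samples: {thin}"
        )

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))

    cv_report = []
    best = None  # (mean_acc, params)
    grid = sorted(config.grid, key=_tie_break_key)
    for params in grid:
        base = RandomForestClassifier(random_state=config.seed, n_jobs=1, **params)
        fold_accs = []
        for train_idx, test_idx in folds:
            model = clone(base)
            model.fit(X[train_idx], y[train_idx])
            fold_accs.append(float(model.score(X[test_idx], y[test_idx])))
        mean_acc = float(np.mean(fold_accs))
        cv_report.append(
            {
                "params": dict(params),
                "mean_accuracy": mean_acc,
                "sd_accuracy": float(np.std(fold_accs, ddof=1)) if len(fold_accs) > 1 else 0.0,
                "fold_accuracies": fold_accs,
            }
        )
        if best is None or mean_acc > best[0]:  # ties keep the earlier (simpler) config
            best = (mean_acc, dict(params))

    forest = RandomForestClassifier(random_state=config.seed, n_jobs=1, **best[1])
    forest.fit(X, y)
    return TrainedGenotyper(
        forest=forest,
        feature_index_hash=feature_hash,
        class_labels=ALL_GENOTYPES,
        cv_report=cv_report,
        chosen_params=best[1],
        confidence_threshold=config.confidence_threshold,
    )


def predict(
    model: TrainedGenotyper, vector: KmerFeatureVector
) -> tuple[GenotypeLabel, dict[GenotypeLabel, float], str]:
    """Predict one sample: (label, class probabilities, "ok"/"uncertain").

    The label is the argmax class probability with ties broken by the fixed
    class order (WT/WT first).  The flag is "uncertain" when the maximum
    probability is below the confidence threshold or the vector is all-zero.
    """
    if vector.index_hash != model.feature_index_hash:
        raise IndexHashMismatch(
            f"feature vector index hash {vector.index_hash!r} does not match "
            f"model hash {model.feature_index_hash!r}"
        )
    X = np.asarray(vector.counts, dtype=np.float32).reshape(1, -1)
    raw = model.forest.predict_proba(X)[0]
    probs = np.zeros(len(ALL_GENOTYPES))
    probs[model.forest.classes_.astype(int)] = raw
    best_idx = int(np.argmax(probs))  # argmax takes the first max: fixed order
    label = ALL_GENOTYPES[best_idx]
    flag = "ok"
    if probs[best_idx] < model.confidence_threshold or float(np.sum(vector.counts)) == 0.0:
        flag = "uncertain"
    prob_map = {g: float(p) for g, p in zip(ALL_GENOTYPES, probs)}
    return label, prob_map, flag


def predict_matrix(model: TrainedGenotyper, dataset: FeatureDataset) -> list[GenotypeLabel]:
    """Vectorised prediction over a dataset (hash-checked)."""
    if dataset.index_hash != model.feature_index_hash:
        raise IndexHashMismatch(
            f"dataset index hash {dataset.index_hash!r} does not match "
            f"model hash {model.feature_index_hash!r}"
        )
    y = model.forest.predict(dataset.X.astype(np.float32))
    return [ALL_GENOTYPES[int(i)] for i in y]


def save_model(model: TrainedGenotyper, path) -> None:
    """Persist the ensemble (joblib) plus a JSON sidecar at ``path`` + '.json'."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "forest": model.forest,
        "feature_index_hash": model.feature_index_hash,
        "class_labels": [str(g) for g in model.class_labels],
        "cv_report": model.cv_report,
        "chosen_params": model.chosen_params,
        "confidence_threshold": model.confidence_threshold,
    }
    joblib.dump(payload, path)
    sidecar = {k: v for k, v in payload.items() if k != "forest"}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, default=str)
        fh.write("\n")


def load_model(path) -> TrainedGenotyper:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a genotyper model file")
    if payload["format_version"] != _MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload['format_version']} not supported "
            f"(expected {_MODEL_FORMAT_VERSION})"
        )
    sidecar_path = str(path) + ".json"
    try:
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        if sidecar.get("feature_index_hash") != payload["feature_index_hash"]:
            raise ValueError(
                f"index hash in sidecar {sidecar_path} disagrees with model payload"
            )
    except FileNotFoundError:
        pass  # sidecar is informational; the payload is authoritative
    return TrainedGenotyper(
        forest=payload["forest"],
        feature_index_hash=payload["feature_index_hash"],
        class_labels=tuple(GenotypeLabel.from_string(s) for s in payload["class_labels"]),
        cv_report=payload["cv_report"],
        chosen_params=payload["chosen_params"],
        confidence_threshold=payload["confidence_threshold"],
    )
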