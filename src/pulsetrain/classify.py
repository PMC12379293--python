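"""Random-forest classification of candidate events.

Two independent models mirror the two filter branches: the click model
separates ``regular_click`` / ``buzz`` / ``noise`` candidates, the
vessel model separates ``vessel`` / ``non_vessel``.  Both use the same
forest configuration (100 trees, depth 30, minimum split 7) and a
stratified, seeded 70/30 train/validation split -- stratification matters
because the class balance of labeled pulse-event data is typically
severe (buzzes are an order of magnitude rarer than background noise).

Feature importances are mean-decrease-in-impurity by default, with
permutation importance available for datasets where impurity bias is a
concern.  Models serialize as a joblib artifact plus a JSON manifest
(branch, column order, hyperparameters, seed, training-data hash);
prediction refuses a column-order mismatch.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from pulsetrain.pulse_io import SchemaError

__all__ = [
    "CLICK_CLASSES",
    "VESSEL_CLASSES",
    "RFHyperparams",
    "LabeledDataset",
    "TrainedModel",
    "split_train_validation",
    "train",
    "predict",
    "importances",
    "save_model",
    "load_model",
]

CLICK_CLASSES = ("regular_click", "buzz", "noise")
VESSEL_CLASSES = ("vessel", "non_vessel")


@dataclass(frozen=True)
class RFHyperparams:
    """Forest configuration used for both branches."""

    n_estimators: int = 100
    max_depth: int = 30
    min_samples_split: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_estimators", "max_depth", "min_samples_split"):
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value > 0):
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class LabeledDataset:
    """Feature rows with branch-appropriate labels."""

    features: pd.DataFrame
    labels: np.ndarray
    branch: Literal["click", "vessel"]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.features) != len(self.labels):
            raise ValueError(
                f"{len(self.features)} feature rows but {len(self.labels)} labels"
            )
        vocab = CLICK_CLASSES if self.branch == "click" else VESSEL_CLASSES
        unknown = set(self.labels) - set(vocab)
        if unknown:
            raise ValueError(
                f"labels {sorted(unknown)} not in the {self.branch}-branch "
                f"vocabulary {vocab}"
            )

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.features.iloc[indices].reset_index(drop=True),
            self.labels[indices],
            self.branch,
        )


@dataclass
class TrainedModel:
    """A fitted forest plus everything needed to apply it safely."""

    estimator: RandomForestClassifier
    branch: Literal["click", "vessel"]
    columns: tuple[str, ...]
    hyperparams: RFHyperparams
    training_data_hash: str = ""


def split_train_validation(
    dataset: LabeledDataset,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive, label-stratified split, reproducible per seed.

    Classes with a single member cannot be stratified; they are kept
    whole in the training side with a warning.
    """
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")

    labels = dataset.labels
    classes, counts = np.unique(labels, return_counts=True)
    singletons = set(classes[counts < 2])
    indices = np.arange(len(dataset))
    if singletons:
        warnings.warn(
            f"classes {sorted(singletons)} have fewer than 2 members and are "
            "kept whole in the training split",
            stacklevel=2,
        )
        forced = np.isin(labels, list(singletons))
        splittable = indices[~forced]
        tr, va = train_test_split(
            splittable,
            train_size=train_fraction,
            random_state=seed,
            stratify=labels[~forced],
        )
        tr = np.concatenate([tr, indices[forced]])
    else:
        tr, va = train_test_split(
            indices,
            train_size=train_fraction,
            random_state=seed,
            stratify=labels,
        )
    return dataset.subset(np.sort(tr)), dataset.subset(np.sort(va))


def _feature_columns(frame: pd.DataFrame) -> tuple[str, ...]:
    return tuple(c for c in frame.columns if c not in ("event_id", "kind"))


def _dataset_hash(X: pd.DataFrame, y: np.ndarray) -> str:
    digest = hashlib.sha256()
    digest.update(X.to_csv(index=False).encode())
    digest.update(",".join(map(str, y)).encode())
    return digest.hexdigest()[:16]


def train(dataset: LabeledDataset, hp: RFHyperparams = RFHyperparams()) -> TrainedModel:
    """Fit a forest on a labeled dataset; bit-reproducible given the seed."""
    if len(np.unique(dataset.labels)) < 2:
        raise ValueError("training requires at least 2 classes")
    columns = _feature_columns(dataset.features)
    X = dataset.features[list(columns)]
    estimator = RandomForestClassifier(
        n_estimators=hp.n_estimators,
        max_depth=hp.max_depth,
        min_samples_split=hp.min_samples_split,
        random_state=hp.seed,
    )
    estimator.fit(X.to_numpy(float), dataset.labels)
    return TrainedModel(
        estimator=estimator,
        branch=dataset.branch,
        columns=columns,
        hyperparams=hp,
        training_data_hash=_dataset_hash(X, dataset.labels),
    )


def predict(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """One branch-appropriate label per feature row."""
    given = _feature_columns(features)
    if given != model.columns:
        raise SchemaError(
            f"feature columns {given} do not match the model's training "
            f"columns {model.columns}"
        )
    if len(features) == 0:
        return np.empty(0, dtype=object)
    X = features[list(model.columns)].to_numpy(float)
    return model.estimator.predict(X).astype(object)


def importances(
    model: TrainedModel,
    method: Literal["impurity", "permutation"] = "impurity",
    X: pd.DataFrame | None = None,
    y: np.ndarray | None = None,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Feature importances, normalized to sum to 1, sorted descending.

    ``"impurity"`` is the forest's mean decrease in impurity;
    ``"permutation"`` requires evaluation data ``X``/``y``.
    """
    if not hasattr(model.estimator, "estimators_"):
        raise RuntimeError("model is not fitted")
    if method == "impurity":
        values = model.estimator.feature_importances_
    elif method == "permutation":
        if X is None or y is None:
            raise ValueError("permutation importance requires X and y")
        result = permutation_importance(
            model.estimator,
            X[list(model.columns)].to_numpy(float),
            y,
            random_state=seed,
        )
        values = np.clip(result.importances_mean, 0.0, None)
    else:
        raise ValueError(f"unknown importance method {method!r}")
    total = values.sum()
    if total > 0:
        values = values / total
    ranked = sorted(zip(model.columns, values.tolist()), key=lambda kv: -kv[1])
    return ranked


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize the ensemble next to a JSON manifest (``<path>.json``)."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    manifest = {
        "branch": model.branch,
        "columns": list(model.columns),
        "hyperparams": asdict(model.hyperparams),
        "training_data_hash": model.training_data_hash,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    manifest_path = path.with_suffix(path.suffix + ".json")
    if not manifest_path.exists():
        raise SchemaError(f"model manifest {manifest_path} is missing")
    manifest = json.loads(manifest_path.read_text())
    estimator = joblib.load(path)
    return TrainedModel(
        estimator=estimator,
        branch=manifest["branch"],
        columns=tuple(manifest["columns"]),
        hyperparams=RFHyperparams(**manifest["hyperparams"]),
        training_data_hash=manifest.get("training_data_hash", ""),
    )
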