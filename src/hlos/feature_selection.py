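"""Permutation feature importance (PFI) selection.

A random forest trained on an inner 80% split of the training data provides
the baseline validation RMSE.  Each feature's column in the validation set is
then replaced by a seeded permutation of its own observed values — an exact
draw from the feature's empirical marginal that severs its link with the
target — and the importance is the mean increase in RMSE over K repetitions.
Features with strictly positive importance contributed to accuracy and are
selected, ordered by importance.
"""
from __future__ import annotations

import dataclasses
import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ImportanceReport",
    "inner_split",
    "fit_base_model",
    "pfi_score",
    "compute_importances",
    "select_features",
    "packaged_feature_list",
]


@dataclasses.dataclass
class FeatureImportance:
    name: str
    K: int
    mean_augmented_score: float  # RMSE (days) averaged over K permutations
    importance: float            # augmented - baseline; positive = helpful

    @property
    def selected(self) -> bool:
        return self.importance > 0


@dataclasses.dataclass
class ImportanceReport:
    baseline_score: float        # RMSE (days) of the intact model on validation rows
    features: list               # [FeatureImportance, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.name, f.K, f.mean_augmented_score, f.importance, f.selected)
             for f in self.features],
            columns=["feature", "K", "mean_augmented_score", "importance", "selected"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {"baseline_score": self.baseline_score,
                   "features": [dataclasses.asdict(f) | {"selected": f.selected}
                                for f in self.features]}
        Path(path).write_text(json.dumps(payload, indent=1))


def inner_split(train: np.ndarray, seed: int = 0,
                fraction: float = 0.8) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint seeded 80/20 partition of the training indices."""
    train = np.asarray(train)
    if len(train) < 10:
        raise ValueError("need at least 10 training rows for the inner split")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    perm = rng.permutation(len(train))
    n_fit = int(round(fraction * len(train)))
    return train[np.sort(perm[:n_fit])], train[np.sort(perm[n_fit:])]


def fit_base_model(X_fit: np.ndarray, y_fit: np.ndarray, seed: int = 0,
                   n_estimators: int = 200, **kwargs) -> RandomForestRegressor:
    """Seeded random-forest base regressor for importance scoring."""
    X_fit = np.asarray(X_fit)
    if X_fit.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit the base model")
    model = RandomForestRegressor(n_estimators=n_estimators,
                                  random_state=int(seed) % (2 ** 31),
                                  n_jobs=1, **kwargs)
    model.fit(X_fit, np.asarray(y_fit))
    return model


def _rmse(y, yhat) -> float:
    return float(np.sqrt(np.mean((np.asarray(y) - np.asarray(yhat)) ** 2)))


def pfi_score(model, X_val: np.ndarray, y_val: np.ndarray, feature: int | str,
              K: int = 10, seed: int = 0, names: list | None = None,
              baseline: float | None = None) -> float:
    """Importance of one feature: mean RMSE increase over K permutations.

    ``feature`` may be a column index or a name resolved through ``names``.
    """
    X_val = np.asarray(X_val, dtype=float)
    if isinstance(feature, str):
        if names is None or feature not in names:
            raise KeyError(f"feature {feature!r} not in matrix")
        j = names.index(feature)
    else:
        j = int(feature)
        if not 0 <= j < X_val.shape[1]:
            raise KeyError(f"feature index {j} not in matrix")
    if K < 1:
        raise ValueError("K must be >= 1")
    if baseline is None:
        baseline = _rmse(y_val, model.predict(X_val))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4, j)))
    scores = []
    X_aug = X_val.copy()
    for _ in range(K):
        X_aug[:, j] = rng.permutation(X_val[:, j])
        scores.append(_rmse(y_val, model.predict(X_aug)))
    return float(np.mean(scores) - baseline)


def compute_importances(model, X_val, y_val, names: list, K: int = 10,
                        seed: int = 0) -> ImportanceReport:
    """Score every feature against one shared baseline RMSE."""
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    baseline = _rmse(y_val, model.predict(X_val))
    feats = []
    for j, name in enumerate(names):
        s = pfi_score(model, X_val, y_val, j, K=K, seed=seed, baseline=baseline)
        feats.append(FeatureImportance(name=name, K=K,
                                       mean_augmented_score=baseline + s,
                                       importance=s))
    return ImportanceReport(baseline_score=baseline, features=feats)


def select_features(report: ImportanceReport, floor: float = 0.0) -> list[str]:
    """Features with importance > floor, sorted by importance descending
    (alphabetical tie-break)."""
    if not report.features:
        raise ValueError("empty importance report")
    keep = [f for f in report.features if f.importance > floor]
    keep.sort(key=lambda f: (-f.importance, f.name))
    return [f.name for f in keep]


def packaged_feature_list() -> list[str]:
    """The 44 pre-operative features retained by PFI in the source cohort."""
    text = (importlib.resources.files("hlos.data") / "pfi_features.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]
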