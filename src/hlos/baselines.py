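"""Frequentist regression baselines behind a uniform fit/predict contract.

Eight models — SGD linear regression, Huber regression, gradient-boosted
trees (xgboost), random forest, lasso, ridge, polynomial-kernel SVR and
ordinary least squares — each with a fixed published hyperparameter set
shipped in ``data/baselines.yaml`` and validated against a per-model schema.
"""
from __future__ import annotations

import dataclasses
import importlib.resources

import numpy as np
import yaml
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import (HuberRegressor, Lasso, LinearRegression,
                                  Ridge, SGDRegressor)
from sklearn.svm import SVR
from xgboost import XGBRegressor

__all__ = ["BaselineConfig", "MODEL_IDS", "packaged_configs", "fit_predict", "run_all"]

MODEL_IDS = ("sgd_linear", "huber", "gradient_boosted_trees", "random_forest",
             "lasso", "ridge", "svr_poly", "ols")

_SCHEMAS: dict[str, set] = {
    "sgd_linear": {"learning_rate", "power_t", "alpha", "eta0", "max_iter", "tol",
                   "penalty"},
    "huber": {"epsilon", "alpha", "max_iter"},
    "gradient_boosted_trees": {"subsample", "n_estimators", "min_child_weight",
                               "max_depth", "learning_rate", "colsample_bytree",
                               "booster", "reg_alpha", "reg_lambda", "tree_method"},
    "random_forest": {"n_estimators", "min_samples_split", "min_samples_leaf",
                      "max_features", "max_depth", "bootstrap"},
    "lasso": {"alpha", "max_iter"},
    "ridge": {"alpha"},
    "svr_poly": {"kernel", "degree", "C", "epsilon", "gamma", "coef0"},
    "ols": set(),
}

_SEEDED = {"sgd_linear", "gradient_boosted_trees", "random_forest"}


@dataclasses.dataclass
class BaselineConfig:
    model_id: str
    hyperparameters: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        unknown = set(self.hyperparameters) - _SCHEMAS[self.model_id]
        if unknown:
            raise ValueError(
                f"unknown hyperparameter(s) {sorted(unknown)} for {self.model_id!r}")


def packaged_configs(seed: int = 0) -> dict[str, BaselineConfig]:
    """The published hyperparameter transcription, one config per model."""
    raw = yaml.safe_load(
        (importlib.resources.files("hlos.data") / "baselines.yaml").read_text())
    configs = {}
    for mid in MODEL_IDS:
        cfg = BaselineConfig(model_id=mid, hyperparameters=dict(raw.get(mid) or {}),
                             seed=seed)
        cfg.validate()
        configs[mid] = cfg
    return configs


def _make_estimator(config: BaselineConfig):
    hp = dict(config.hyperparameters)
    seed = int(config.seed) % (2 ** 31)
    if config.model_id == "sgd_linear":
        hp.setdefault("max_iter", 2000)
        return SGDRegressor(random_state=seed, **hp)
    if config.model_id == "huber":
        return HuberRegressor(**hp)
    if config.model_id == "gradient_boosted_trees":
        hp.setdefault("tree_method", "hist")
        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **hp)
    if config.model_id == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **hp)
    if config.model_id == "lasso":
        return Lasso(**hp)
    if config.model_id == "ridge":
        return Ridge(**hp)
    if config.model_id == "svr_poly":
        return SVR(**hp)
    return LinearRegression()


def fit_predict(config: BaselineConfig, X_train, y_train, X_test) -> np.ndarray:
    """Train the configured model and return unrounded test predictions (days)."""
    config.validate()
    model = _make_estimator(config)
    model.fit(np.asarray(X_train, dtype=float), np.asarray(y_train, dtype=float))
    return np.asarray(model.predict(np.asarray(X_test, dtype=float)), dtype=float)


def run_all(X_train, y_train, X_test, seed: int = 0,
            configs: dict | None = None) -> dict[str, np.ndarray]:
    """Run the eight baselines in a fixed order; per-model seeds derive from ``seed``."""
    if configs is None:
        configs = packaged_configs(seed=seed)
    out: dict[str, np.ndarray] = {}
    for k, mid in enumerate(MODEL_IDS):
        cfg = configs[mid]
        if mid in _SEEDED:
            cfg = dataclasses.replace(
                cfg, seed=int(np.random.SeedSequence((seed, 7, k)).generate_state(1)[0]))
        try:
            out[mid] = fit_predict(cfg, X_train, y_train, X_test)
        except Exception as err:
            raise RuntimeError(f"baseline {mid!r} failed: {err}") from err
    return out
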