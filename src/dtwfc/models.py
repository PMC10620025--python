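"""Classifier adapters and random-search spaces.

Four classifiers are compared: linear-kernel SVM, radial-kernel SVM,
L1-regularized linear SVM, and random forest. The classifiers themselves come
from scikit-learn; this module pins the fixed settings (random forest uses 500
trees and mtry = floor(sqrt(P)) candidate features per split, so it needs no
tuning) and defines the random-search sampling spaces for the tunable ones.

The search ranges are this package's own choices — log-uniform over several
decades for the misclassification penalty C and the radial kernel width — and
are echoed into every results sidecar so a run is auditable. The radial width
is parameterized as scikit-learn's ``gamma`` (inverse squared length scale);
kernlab's ``sigma`` convention coincides numerically with ``gamma`` for its
Gaussian kernel exp(-sigma * ||x - x'||^2), and both names are reported in
metadata to avoid ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC, LinearSVC

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "DegenerateFoldError",
    "default_search_space",
    "model_spec",
    "sample_params",
    "rf_mtry",
    "make_estimator",
    "fit_predict",
    "search_space_metadata",
]

MODEL_NAMES = ("svm_linear", "svm_radial", "l1_svm", "random_forest")

# Tie-breaking in the tuner prefers smaller values of this parameter.
PENALTY_PARAM = "C"


class DegenerateFoldError(ValueError):
    """A training split contains a single class; stratify the folds."""


@dataclass(frozen=True)
class ModelSpec:
    """A classifier name with its fixed settings and random-search space."""

    name: str
    fixed_params: dict = field(default_factory=dict)
    search_space: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected {MODEL_NAMES}")
        if self.name == "random_forest" and self.search_space:
            raise ValueError("random_forest has no tunable hyperparameters")


def default_search_space(name: str) -> dict:
    """Random-search distributions per model.

    SVMs draw the penalty ``C`` log-uniformly over [1e-3, 1e3]; the radial
    kernel additionally draws ``gamma`` log-uniformly over [1e-4, 1e1]. The
    random forest's space is empty: its settings are fixed a priori.
    """
    if name == "svm_linear" or name == "l1_svm":
        return {"C": stats.loguniform(1e-3, 1e3)}
    if name == "svm_radial":
        return {"C": stats.loguniform(1e-3, 1e3), "gamma": stats.loguniform(1e-4, 1e1)}
    if name == "random_forest":
        return {}
    raise ValueError(f"unknown model {name!r}; expected {MODEL_NAMES}")


def model_spec(name: str) -> ModelSpec:
    """A ModelSpec with the default search space and fixed settings."""
    fixed = {}
    if name == "random_forest":
        fixed = {"n_estimators": 500, "max_features": "floor-sqrt(P)"}
    return ModelSpec(name=name, fixed_params=fixed, search_space=default_search_space(name))


def search_space_metadata(spec: ModelSpec) -> dict:
    """JSON-serializable echo of the sampling space for results sidecars."""
    meta = {}
    for key, dist in spec.search_space.items():
        lo, hi = dist.support()
        entry = {"distribution": "log-uniform", "low": float(lo), "high": float(hi)}
        if key == "gamma":
            entry["note"] = "sklearn gamma == kernlab sigma for exp(-g*||x-x'||^2)"
        meta[key] = entry
    return meta


def sample_params(search_space: dict, n: int, seed: int) -> list[dict]:
    """Draw ``n`` candidate parameter sets, deterministically given ``seed``.

    Parameters are sampled independently, in sorted key order, from their
    declared distributions. An empty space yields ``n`` empty candidates.
    """
    if not search_space:
        return [{} for _ in range(n)]
    rng = np.random.default_rng(seed)
    keys = sorted(search_space)
    draws = {k: np.atleast_1d(search_space[k].rvs(size=n, random_state=rng)) for k in keys}
    return [{k: float(draws[k][i]) for k in keys} for i in range(n)]


def rf_mtry(n_features: int) -> int:
    """Number of candidate features per split: floor(sqrt(P))."""
    return int(math.floor(math.sqrt(n_features)))


def make_estimator(name: str, params: dict | None = None, seed: int = 0):
    """Instantiate the scikit-learn estimator behind a model name."""
    params = params or {}
    if name == "svm_linear":
        return SVC(kernel="linear", C=params.get("C", 1.0))
    if name == "svm_radial":
        return SVC(kernel="rbf", C=params.get("C", 1.0), gamma=params.get("gamma", "scale"))
    if name == "l1_svm":
        return LinearSVC(
            penalty="l1",
            dual=False,
            C=params.get("C", 1.0),
            max_iter=10_000,
            random_state=seed,
        )
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=500,
            max_features="sqrt",  # floor(sqrt(P)) candidate features per split
            random_state=seed,
            n_jobs=1,
        )
    raise ValueError(f"unknown model {name!r}; expected {MODEL_NAMES}")


def fit_predict(
    spec: ModelSpec | str,
    params: dict | None,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Fit one classifier on a training split and predict a test split.

    Deterministic given (data, params, seed). Raises
    :class:`DegenerateFoldError` when the training labels are single-class.
    """
    name = spec.name if isinstance(spec, ModelSpec) else spec
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise DegenerateFoldError("training split contains a single class")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train and test must share the feature order")
    est = make_estimator(name, params, seed)
    est.fit(X_train, y_train)
    return est.predict(X_test)
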