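"""Cross-validation protocols with leakage-safe in-fold preprocessing.

Three performance-estimation protocols are implemented:

* **Repeated nested K-fold CV** — outer folds estimate performance; for each
  outer training block an inner K-fold CV scores randomly drawn
  hyperparameter candidates and the winner is refit on the whole block.
* **Nested LOOCV** — the outer loop leaves one subject out; tuning uses a
  small inner K-fold. Metrics are computed from the pooled n predictions
  (per-fold rates are undefined for singleton held-out sets).
* **Optimistically biased CV** — plain K-fold CV is run once per candidate
  (same folds for every candidate) and the *maximum* candidate accuracy is
  reported. This reproduces the estimator whose upward bias the nested
  protocols avoid: hyperparameter selection and performance assessment reuse
  the same held-out data.

A plain repeated K-fold protocol covers classifiers with no tuning (random
forest). Every fitted preprocessing step — PCA and the DTW similarity
demeaning — lives inside a scikit-learn Pipeline that is refit on each
training block, so held-out rows never influence fitted components or
centering constants.

Randomness follows a seed ladder: a protocol's master seed derives per-repeat,
per-fold and per-candidate seeds through ``derive_seed(master, *indices)``
(a NumPy SeedSequence over the index path), so any single fold or candidate
draw is reproducible in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.utils.validation import check_is_fitted

from .connectivity import FeatureTable, SimilarityDemeaner
from .models import PENALTY_PARAM, DegenerateFoldError, ModelSpec, make_estimator, sample_params

__all__ = [
    "CVProtocol",
    "CVResult",
    "FoldSpec",
    "FoldFit",
    "RankCappedPCA",
    "derive_seed",
    "stratified_kfold",
    "fold_indices",
    "fold_safe_pca",
    "evaluate_metrics",
    "inner_tune",
    "fit_outer_fold",
    "nested_cv",
    "plain_kfold_cv",
    "optimistically_biased_cv",
    "run_cv",
]

PROTOCOL_KINDS = ("nested_kfold", "nested_loocv", "optimistically_biased", "plain_kfold")


def derive_seed(master: int, *path: int) -> int:
    """Deterministic child seed for an index path under a master seed."""
    ss = np.random.SeedSequence([int(master), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class CVProtocol:
    """Declarative description of one CV scheme.

    ``outer_k=None`` means leave-one-out (K equals the sample size).
    ``pca_components`` switches fold-safe PCA on (components are fit inside
    each training block); ``None`` disables it.
    """

    kind: str
    outer_k: int | None = 5
    inner_k: int = 5
    n_search: int = 80
    n_repeats: int = 100
    pca_components: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"kind must be one of {PROTOCOL_KINDS}")

    # Factories with the study-design defaults for each protocol.
    @staticmethod
    def nested_kfold(
        outer_k: int = 5,
        inner_k: int = 5,
        n_search: int = 80,
        n_repeats: int = 100,
        pca_components: int | None = None,
        seed: int = 0,
    ) -> "CVProtocol":
        return CVProtocol("nested_kfold", outer_k, inner_k, n_search, n_repeats, pca_components, seed)

    @staticmethod
    def nested_loocv(
        inner_k: int = 3,
        n_search: int = 40,
        pca_components: int | None = None,
        seed: int = 0,
    ) -> "CVProtocol":
        return CVProtocol("nested_loocv", None, inner_k, n_search, 1, pca_components, seed)

    @staticmethod
    def optimistically_biased(
        k: int = 10,
        n_search: int = 80,
        pca_components: int | None = None,
        seed: int = 0,
    ) -> "CVProtocol":
        return CVProtocol("optimistically_biased", k, 0, n_search, 1, pca_components, seed)

    @staticmethod
    def plain_kfold(
        k: int = 15,
        n_repeats: int = 100,
        pca_components: int | None = None,
        seed: int = 0,
    ) -> "CVProtocol":
        return CVProtocol("plain_kfold", k, 0, 0, n_repeats, pca_components, seed)


@dataclass(frozen=True)
class FoldSpec:
    """Fold assignment vector (values in 0..K-1), one entry per subject."""

    assignments: np.ndarray
    k: int
    stratified: bool
    seed: int


@dataclass
class CVResult:
    """Estimated accuracy/sensitivity/specificity with per-repeat detail."""

    accuracy: float
    sensitivity: float
    specificity: float
    per_repeat: dict
    chosen_params: list
    protocol: CVProtocol
    n_subjects: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_repeats": len(self.per_repeat["accuracy"]),
            "n_subjects": self.n_subjects,
        }


def stratified_kfold(labels, k: int, seed: int, stratified: bool = True) -> FoldSpec:
    """Shuffled (optionally class-stratified) fold assignments.

    Falls back to unstratified folds with a warning when a class has fewer
    than ``k`` members (always the case for leave-one-out).
    """
    labels = np.asarray(labels)
    n = labels.size
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= K <= n, got K={k}, n={n}")
    if stratified:
        smallest = np.bincount(labels).min()
        if smallest < k:
            warnings.warn(
                f"class with {smallest} members < K={k}; using unstratified folds",
                stacklevel=2,
            )
            stratified = False
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    assignments = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splits):
        assignments[test_idx] = fold
    return FoldSpec(assignments=assignments, k=k, stratified=stratified, seed=seed)


def fold_indices(spec: FoldSpec):
    """Yield (train_idx, test_idx) pairs in fold order."""
    for fold in range(spec.k):
        test = np.flatnonzero(spec.assignments == fold)
        train = np.flatnonzero(spec.assignments != fold)
        yield train, test


class RankCappedPCA(TransformerMixin, BaseEstimator):
    """PCA that truncates to the achievable rank instead of erroring.

    Components are fitted on training rows only (centered, unscaled).
    When the requested width exceeds the rank of the centered training block,
    the width is truncated with a warning; components whose explained
    variance is numerically zero relative to the leading one are dropped.
    """

    def __init__(self, n_components: int = 30, rank_rtol: float = 1e-9):
        self.n_components = n_components
        self.rank_rtol = rank_rtol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        n, p = X.shape
        cap = min(self.n_components, n, p)
        pca = PCA(n_components=cap, svd_solver="auto", random_state=0)
        pca.fit(X)
        ev = pca.explained_variance_
        keep = int(np.sum(ev > self.rank_rtol * max(ev[0], np.finfo(float).tiny)))
        keep = max(keep, 1)
        if keep < self.n_components:
            warnings.warn(
                f"requested {self.n_components} components, achievable rank {keep}; truncating",
                stacklevel=2,
            )
        self.mean_ = pca.mean_
        self.components_ = pca.components_[:keep]
        self.explained_variance_ = ev[:keep]
        self.n_components_ = keep
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=np.float64)
        return (X - self.mean_) @ self.components_.T


def fold_safe_pca(X_train, X_heldout, n_components: int):
    """Fit PCA on the training block only and project both blocks.

    Returns ``(train_transformed, heldout_transformed)``; the held-out rows
    are centered with the training mean and projected onto the training
    components, so perturbing them cannot change the fitted basis.
    """
    pca = RankCappedPCA(n_components=n_components).fit(X_train)
    return pca.transform(X_train), pca.transform(X_heldout)


def evaluate_metrics(y_true, y_pred, positive_label: int = 1):
    """(accuracy, sensitivity, specificity) for binary predictions.

    Sensitivity is the true-positive rate of the case class, specificity the
    true-negative rate of the control class. A class absent from ``y_true``
    makes the corresponding rate NaN; accuracy is always defined.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos = y_true == positive_label
    neg = ~pos
    accuracy = float(np.mean(y_true == y_pred))
    sensitivity = float(np.mean(y_pred[pos] == positive_label)) if pos.any() else float("nan")
    specificity = float(np.mean(y_pred[neg] != positive_label)) if neg.any() else float("nan")
    return accuracy, sensitivity, specificity


def _build_pipeline(
    spec: ModelSpec,
    params: dict,
    pca_components: int | None,
    demean: bool,
    seed: int,
) -> Pipeline:
    steps = []
    if demean:
        steps.append(("similarity", SimilarityDemeaner()))
    if pca_components is not None:
        steps.append(("pca", RankCappedPCA(n_components=pca_components)))
    steps.append(("clf", make_estimator(spec.name, params, seed)))
    return Pipeline(steps)


def _check_both_classes(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise DegenerateFoldError("training split contains a single class")


def _candidate_better(acc, params, best_acc, best_params) -> bool:
    """Selection rule: higher accuracy wins; ties prefer the smaller penalty
    parameter, then earlier draw order."""
    if best_acc is None or acc > best_acc:
        return True
    if acc == best_acc and PENALTY_PARAM in params and PENALTY_PARAM in best_params:
        return params[PENALTY_PARAM] < best_params[PENALTY_PARAM]
    return False


def inner_tune(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    inner_k: int,
    n_search: int,
    pca_components: int | None,
    seed: int,
    demean: bool = False,
) -> dict:
    """Select hyperparameters by inner stratified K-fold accuracy.

    Draws ``n_search`` candidates from the model's search space and scores
    each by pooled accuracy over the same inner folds, with fold-safe PCA and
    similarity demeaning applied inside every inner split. An empty search
    space returns empty parameters without running inner CV.
    """
    if not spec.search_space:
        return {}
    _check_both_classes(y)
    candidates = sample_params(spec.search_space, n_search, derive_seed(seed, 1))
    folds = stratified_kfold(y, inner_k, derive_seed(seed, 2))
    splits = list(fold_indices(folds))
    best_acc, best_params = None, {}
    for cand_idx, params in enumerate(candidates):
        preds = np.empty_like(y)
        for tr, te in splits:
            _check_both_classes(y[tr])
            pipe = _build_pipeline(spec, params, pca_components, demean, derive_seed(seed, 3, cand_idx))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pipe.fit(X[tr], y[tr])
                preds[te] = pipe.predict(X[te])
        acc = float(np.mean(preds == y))
        if _candidate_better(acc, params, best_acc, best_params):
            best_acc, best_params = acc, params
    return best_params


@dataclass
class FoldFit:
    """What one outer fold fitted and predicted; used for leakage audits."""

    predictions: np.ndarray
    params: dict
    demean_offset: np.ndarray | None
    pca_mean: np.ndarray | None
    pca_components: np.ndarray | None


def fit_outer_fold(
    table: FeatureTable,
    spec: ModelSpec,
    protocol: CVProtocol,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    fold_seed: int | None = None,
) -> FoldFit:
    """Run one outer fold end to end: tune on the training block, refit with
    the selected parameters, predict the held-out block. Returns the fitted
    preprocessing state so leakage freedom can be audited bitwise."""
    X, y = table.X, table.labels
    demean = table.needs_fold_demeaning()
    fold_seed = protocol.seed if fold_seed is None else fold_seed
    _check_both_classes(y[train_idx])
    params = inner_tune(
        X[train_idx],
        y[train_idx],
        spec,
        protocol.inner_k,
        protocol.n_search,
        protocol.pca_components,
        fold_seed,
        demean=demean,
    )
    pipe = _build_pipeline(spec, params, protocol.pca_components, demean, derive_seed(fold_seed, 4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(X[train_idx], y[train_idx])
        preds = pipe.predict(X[test_idx])
    named = dict(pipe.named_steps)
    return FoldFit(
        predictions=preds,
        params=params,
        demean_offset=named["similarity"].offset_.copy() if "similarity" in named else None,
        pca_mean=named["pca"].mean_.copy() if "pca" in named else None,
        pca_components=named["pca"].components_.copy() if "pca" in named else None,
    )


def _result_from_repeats(per_repeat, chosen_params, protocol, n) -> CVResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return CVResult(
            accuracy=float(np.mean(per_repeat["accuracy"])),
            sensitivity=float(np.nanmean(per_repeat["sensitivity"])),
            specificity=float(np.nanmean(per_repeat["specificity"])),
            per_repeat=per_repeat,
            chosen_params=chosen_params,
            protocol=protocol,
            n_subjects=n,
        )


def nested_cv(table: FeatureTable, spec: ModelSpec, protocol: CVProtocol) -> CVResult:
    """Repeated nested K-fold CV or nested LOOCV.

    Per repeat, outer folds are redrawn from a repeat-specific seed; metrics
    come from the pooled outer predictions of that repeat, and the reported
    estimate is the mean over repeats. All preprocessing is fitted inside
    each outer training block.
    """
    if protocol.kind not in ("nested_kfold", "nested_loocv"):
        raise ValueError(f"nested_cv cannot run protocol kind {protocol.kind!r}")
    X, y = table.X, table.labels
    n = y.size
    outer_k = n if protocol.outer_k is None else protocol.outer_k
    per_repeat = {"accuracy": [], "sensitivity": [], "specificity": []}
    chosen_params: list = []
    for rep in range(protocol.n_repeats):
        folds = stratified_kfold(y, outer_k, derive_seed(protocol.seed, rep))
        preds = np.empty_like(y)
        for f, (tr, te) in enumerate(fold_indices(folds)):
            fit = fit_outer_fold(table, spec, protocol, tr, te, derive_seed(protocol.seed, rep, f))
            preds[te] = fit.predictions
            chosen_params.append({"repeat": rep, "fold": f, **fit.params})
        acc, sens, spec_ = evaluate_metrics(y, preds)
        per_repeat["accuracy"].append(acc)
        per_repeat["sensitivity"].append(sens)
        per_repeat["specificity"].append(spec_)
    return _result_from_repeats(per_repeat, chosen_params, protocol, n)


def plain_kfold_cv(
    table: FeatureTable,
    spec: ModelSpec,
    protocol: CVProtocol,
    params: dict | None = None,
) -> CVResult:
    """Repeated K-fold CV with fixed parameters (no tuning). The protocol for
    classifiers whose settings are fixed a priori, e.g. the random forest."""
    if protocol.kind != "plain_kfold":
        raise ValueError(f"plain_kfold_cv cannot run protocol kind {protocol.kind!r}")
    X, y = table.X, table.labels
    demean = table.needs_fold_demeaning()
    params = params or {}
    per_repeat = {"accuracy": [], "sensitivity": [], "specificity": []}
    for rep in range(protocol.n_repeats):
        folds = stratified_kfold(y, protocol.outer_k, derive_seed(protocol.seed, rep))
        preds = np.empty_like(y)
        for f, (tr, te) in enumerate(fold_indices(folds)):
            _check_both_classes(y[tr])
            pipe = _build_pipeline(
                spec, params, protocol.pca_components, demean, derive_seed(protocol.seed, rep, f)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pipe.fit(X[tr], y[tr])
                preds[te] = pipe.predict(X[te])
        acc, sens, spec_ = evaluate_metrics(y, preds)
        per_repeat["accuracy"].append(acc)
        per_repeat["sensitivity"].append(sens)
        per_repeat["specificity"].append(spec_)
    return _result_from_repeats(per_repeat, [params] if params else [], protocol, y.size)


def optimistically_biased_cv(table: FeatureTable, spec: ModelSpec, protocol: CVProtocol) -> CVResult:
    """K-fold CV per candidate with shared folds; report the maximum.

    Every candidate is evaluated on the *same* fold split, isolating the
    selection effect from fold noise, and the best candidate's pooled CV
    accuracy (with its sensitivity and specificity) is returned as the
    estimate. With a single candidate this reduces to plain K-fold CV.
    """
    if protocol.kind != "optimistically_biased":
        raise ValueError(f"optimistically_biased_cv cannot run kind {protocol.kind!r}")
    X, y = table.X, table.labels
    demean = table.needs_fold_demeaning()
    candidates = sample_params(spec.search_space, protocol.n_search, derive_seed(protocol.seed, 1))
    if not candidates:
        candidates = [{}]
    folds = stratified_kfold(y, protocol.outer_k, derive_seed(protocol.seed, 0))
    splits = list(fold_indices(folds))
    best = None
    all_accs = []
    for cand_idx, params in enumerate(candidates):
        preds = np.empty_like(y)
        for tr, te in splits:
            _check_both_classes(y[tr])
            pipe = _build_pipeline(
                spec, params, protocol.pca_components, demean, derive_seed(protocol.seed, 2, cand_idx)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pipe.fit(X[tr], y[tr])
                preds[te] = pipe.predict(X[te])
        acc, sens, spec_ = evaluate_metrics(y, preds)
        all_accs.append(acc)
        if best is None or _candidate_better(acc, params, best[0], best[3]):
            best = (acc, sens, spec_, params)
    acc, sens, spec_, params = best
    per_repeat = {
        "accuracy": [acc],
        "sensitivity": [sens],
        "specificity": [spec_],
        "candidate_accuracies": all_accs,
    }
    return _result_from_repeats(per_repeat, [params], protocol, y.size)


def run_cv(table: FeatureTable, spec: ModelSpec, protocol: CVProtocol) -> CVResult:
    """Dispatch a protocol to its engine."""
    if protocol.kind in ("nested_kfold", "nested_loocv"):
        return nested_cv(table, spec, protocol)
    if protocol.kind == "plain_kfold":
        return plain_kfold_cv(table, spec, protocol)
    if protocol.kind == "optimistically_biased":
        return optimistically_biased_cv(table, spec, protocol)
    raise ValueError(f"unknown protocol kind {protocol.kind!r}")


def with_seed(protocol: CVProtocol, seed: int) -> CVProtocol:
    """Copy of a protocol with a different master seed."""
    return replace(protocol, seed=seed)
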