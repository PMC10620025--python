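"""Functional connectivity features from ROI time series.

A subject is an ROI x time matrix with a binary diagnosis label. Connectivity
between two regions is either the Pearson correlation of their series or the
banded DTW distance; DTW distances become similarity features by negating and
demeaning each region-pair column. The strict upper triangle of each subject's
symmetric R x R connectivity matrix, in row-major order, is the subject's
feature vector, so R regions give R(R-1)/2 features (105 regions -> 5460).

Demeaning of DTW similarities is a *fitted* transform: its column means must
come from training subjects only when features feed a cross-validated model.
:class:`SimilarityDemeaner` packages that step as a scikit-learn transformer
so it composes with Pipelines and is refit inside every fold; the ``global``
scope (means over the full sample, as upstream work applied it) is available
through :func:`distances_to_similarity`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dtw import DTWConfig, dtw_distance

__all__ = [
    "DegenerateSignalError",
    "SubjectRecord",
    "StudySet",
    "FCMatrix",
    "FeatureTable",
    "SimilarityDemeaner",
    "zscore_timeseries",
    "pearson_fc",
    "dtw_fc",
    "distances_to_similarity",
    "vectorize_upper",
    "build_feature_table",
    "pair_names",
    "save_study",
    "load_study",
    "save_feature_table",
    "load_feature_table",
]

MEASURES = ("pearson", "dtw_distance", "dtw_similarity")


class DegenerateSignalError(ValueError):
    """A region's time series is constant, so correlation/z-scoring is undefined."""


@dataclass
class SubjectRecord:
    """One subject's ROI x time matrix with its binary label.

    ``data`` has regions on rows and time points on columns; ``dt`` is the
    sampling interval (repetition time) in seconds. The positive class
    (label 1) is the case group.
    """

    subject_id: str
    data: np.ndarray
    label: int
    dt: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"{self.subject_id}: data must be 2-D (ROI x time)")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError(f"{self.subject_id}: need >= 2 ROIs and >= 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.subject_id}: data contains non-finite values")
        if self.label not in (0, 1):
            raise ValueError(f"{self.subject_id}: label must be 0 or 1")
        if not self.dt > 0:
            raise ValueError(f"{self.subject_id}: dt must be > 0")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class StudySet:
    """A labeled collection of subjects sharing ROI set, scan length and dt."""

    records: list[SubjectRecord]
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("StudySet needs at least one record")
        shapes = {r.data.shape for r in self.records}
        if len(shapes) != 1:
            raise ValueError(f"records have inconsistent shapes: {shapes}")
        dts = {r.dt for r in self.records}
        if len(dts) != 1:
            raise ValueError(f"records have inconsistent dt: {dts}")
        r = self.records[0].n_rois
        if self.roi_names is None:
            width = len(str(r))
            self.roi_names = [f"ROI{i + 1:0{width}d}" for i in range(r)]
        if len(self.roi_names) != r:
            raise ValueError("roi_names length must equal the ROI count")

    @property
    def n_subjects(self) -> int:
        return len(self.records)

    @property
    def n_rois(self) -> int:
        return self.records[0].n_rois

    @property
    def dt(self) -> float:
        return self.records[0].dt

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def permute_rois(self, order) -> "StudySet":
        """Reorder regions; used to check permutation equivariance."""
        order = list(order)
        return StudySet(
            records=[replace(r, data=r.data[order]) for r in self.records],
            roi_names=[self.roi_names[i] for i in order],
        )


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric region x region connectivity matrix for one subject.

    Diagonal convention: 1 for Pearson, 0 for DTW distance.
    """

    values: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")


def zscore_timeseries(record: SubjectRecord) -> SubjectRecord:
    """Standardize each region's series to mean 0, population sd 1."""
    mean = record.data.mean(axis=1, keepdims=True)
    sd = record.data.std(axis=1, keepdims=True)  # population convention
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise DegenerateSignalError(
            f"{record.subject_id}: constant series in ROI index {flat[0]}"
        )
    return replace(record, data=(record.data - mean) / sd)


def pearson_fc(record: SubjectRecord) -> FCMatrix:
    """Pearson-correlation connectivity matrix (unit diagonal)."""
    sd = record.data.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise DegenerateSignalError(
            f"{record.subject_id}: constant series in ROI index {flat[0]}"
        )
    values = np.corrcoef(record.data)
    np.fill_diagonal(values, 1.0)
    return FCMatrix(values=values, measure="pearson")


def dtw_fc(record: SubjectRecord, config: DTWConfig | None = None) -> FCMatrix:
    """Banded DTW-distance connectivity matrix (zero diagonal).

    Each unordered region pair is computed once; DTW with symmetric costs and
    a symmetric band is symmetric for equal-length series.
    """
    config = config or DTWConfig()
    r = record.n_rois
    values = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            d = dtw_distance(record.data[i], record.data[j], config, record.dt).distance
            values[i, j] = values[j, i] = d
    return FCMatrix(values=values, measure="dtw_distance")


def vectorize_upper(fc: FCMatrix | np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Strict upper triangle in row-major order: (0,1), (0,2), ..., (R-2,R-1)."""
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(values, values.T, atol=atol):
        raise ValueError("connectivity matrix is asymmetric beyond tolerance")
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def pair_names(roi_names: list[str]) -> list[str]:
    """Feature labels for the row-major strict upper triangle."""
    iu = np.triu_indices(len(roi_names), k=1)
    return [f"{roi_names[i]}__{roi_names[j]}" for i, j in zip(*iu)]


@dataclass
class FeatureTable:
    """Subjects x features design matrix with labels and provenance metadata.

    ``measure`` records what the columns hold. A table built for DTW
    similarity with fold-level demeaning keeps raw distances in ``X`` and
    ``meta['demean_scope'] == 'train_fold'``; the CV engine then inserts a
    :class:`SimilarityDemeaner` inside each fold.
    """

    X: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    subject_ids: list[str]
    measure: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        n, p = self.X.shape
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must match columns")
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("labels/subject_ids length must match rows")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def feature_order_hash(self) -> str:
        joined = "|".join(self.feature_names).encode()
        return hashlib.sha256(joined).hexdigest()[:16]

    def needs_fold_demeaning(self) -> bool:
        return (
            self.measure == "dtw_similarity"
            and self.meta.get("demean_scope") == "train_fold"
        )


class SimilarityDemeaner(TransformerMixin, BaseEstimator):
    """Turn DTW distance columns into demeaned similarity columns.

    ``fit`` learns, per feature, the mean of the *negated* training distances;
    ``transform`` negates and subtracts those training means. Held-out rows
    therefore never influence the centering constants, which makes the step
    safe inside cross-validation folds.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        self.offset_ = (-X).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "offset_")
        X = np.asarray(X, dtype=np.float64)
        return -X - self.offset_


def distances_to_similarity(
    table: FeatureTable,
    demean_scope: str = "global",
    train_means: np.ndarray | None = None,
) -> FeatureTable:
    """Convert a distance table to a similarity table (negate, then demean).

    ``global`` scope centers each column by the mean over all provided rows.
    ``train_fold`` scope requires ``train_means`` (the per-column means of the
    negated training distances, e.g. a fitted ``SimilarityDemeaner.offset_``)
    and applies them to the provided rows, which may be a held-out split.
    """
    if table.measure != "dtw_distance":
        raise ValueError("expected a table of DTW distances")
    if demean_scope == "global":
        sim = -table.X
        sim = sim - sim.mean(axis=0)
    elif demean_scope == "train_fold":
        if train_means is None:
            raise ValueError("train_fold scope on provided rows needs train_means")
        sim = -table.X - np.asarray(train_means, dtype=float)
    else:
        raise ValueError("demean_scope must be 'global' or 'train_fold'")
    meta = dict(table.meta, demean_scope=demean_scope)
    return FeatureTable(
        X=sim,
        feature_names=list(table.feature_names),
        labels=table.labels.copy(),
        subject_ids=list(table.subject_ids),
        measure="dtw_similarity",
        meta=meta,
    )


def build_feature_table(
    study: StudySet,
    measure: str = "pearson",
    config: DTWConfig | None = None,
    standardize: bool = True,
    demean_scope: str = "train_fold",
) -> FeatureTable:
    """Stack each subject's vectorized connectivity into a design matrix.

    DTW operates on z-scored series by default so that distances reflect
    signal shape rather than amplitude; Pearson is scale-invariant and
    unaffected. For ``measure='dtw_similarity'`` with ``demean_scope='global'``
    the negate-and-demean conversion is applied over the whole sample here;
    with the default ``'train_fold'`` the table keeps raw distances and is
    flagged for in-fold conversion by the CV engine.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    config = config or DTWConfig()
    rows = []
    for record in study.records:
        try:
            if measure == "pearson":
                fc = pearson_fc(record)
            else:
                rec = zscore_timeseries(record) if standardize else record
                fc = dtw_fc(rec, config)
        except (ValueError, DegenerateSignalError) as err:
            raise type(err)(f"subject {record.subject_id}: {err}") from err
        rows.append(vectorize_upper(fc))
    meta = {
        "standardize": standardize,
        "dt_seconds": study.dt,
        "dtw_window_seconds": config.window_seconds,
        "dtw_local_cost": config.local_cost,
    }
    table = FeatureTable(
        X=np.vstack(rows),
        feature_names=pair_names(study.roi_names),
        labels=study.labels,
        subject_ids=[r.subject_id for r in study.records],
        measure="dtw_distance" if measure != "pearson" else "pearson",
        meta=meta,
    )
    if measure == "dtw_similarity":
        if demean_scope == "global":
            table = distances_to_similarity(table, "global")
        elif demean_scope == "train_fold":
            table.measure = "dtw_similarity"
            table.meta["demean_scope"] = "train_fold"
        else:
            raise ValueError("demean_scope must be 'global' or 'train_fold'")
    return table


# ---------------------------------------------------------------------------
# delimited-text input/output

def save_study(study: StudySet, outdir: str | Path) -> Path:
    """Write one TSV per subject (rows = time points, columns = ROIs, header =
    ROI names) plus a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for record in study.records:
        fname = f"{record.subject_id}.tsv"
        frame = pd.DataFrame(record.data.T, columns=study.roi_names)
        frame.to_csv(outdir / fname, sep="\t", index=False, float_format="%.10g")
        rows.append(
            {
                "subject_id": record.subject_id,
                "path": fname,
                "label": record.label,
                "dt_seconds": record.dt,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_study(manifest_path: str | Path) -> StudySet:
    """Read a study from a manifest CSV; relative paths resolve against the
    manifest's directory."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "path", "label", "dt_seconds"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    records = []
    roi_names: list[str] | None = None
    for row in manifest.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest_path.parent / path
        frame = pd.read_csv(path, sep="\t")
        if roi_names is None:
            roi_names = list(frame.columns)
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                data=frame.to_numpy().T,
                label=int(row.label),
                dt=float(row.dt_seconds),
            )
        )
    return StudySet(records=records, roi_names=roi_names)


def save_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a feature table as CSV (subject_id, label, then feature columns)
    with a JSON sidecar recording measure, DTW settings and feature order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(table.X, columns=table.feature_names)
    frame.insert(0, "label", table.labels)
    frame.insert(0, "subject_id", table.subject_ids)
    frame.to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "measure": table.measure,
        "feature_order_hash": table.feature_order_hash(),
        "n_subjects": table.n_subjects,
        "n_features": table.n_features,
        **{k: v for k, v in table.meta.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def load_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    measure = meta.pop("measure", "pearson")
    for key in ("feature_order_hash", "n_subjects", "n_features"):
        meta.pop(key, None)
    feature_cols = [c for c in frame.columns if c not in ("subject_id", "label")]
    return FeatureTable(
        X=frame[feature_cols].to_numpy(dtype=float),
        feature_names=feature_cols,
        labels=frame["label"].to_numpy(dtype=int),
        subject_ids=[str(s) for s in frame["subject_id"]],
        measure=measure,
        meta=meta,
    )
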