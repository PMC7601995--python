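"""Preprocessing, feature selection and the kNN read-across regressor.

The modelling table carries one row per cytotoxicity experiment:
an id column, numeric and nominal descriptors, and the % cell viability
endpoint.  The pipeline follows the read-across recipe: drop redundant
descriptors (a column is removed when 20% or more of its values coincide
with an earlier column), z-score the remaining numeric columns *and* the
endpoint with training-set statistics, split 70/30, pick features by
correlation-based subset merit under a forward best-first search, and fit
a k-nearest-neighbours regressor whose distance is Euclidean on numeric
features with a 0/1 contribution for nominal ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "TableSchema",
    "PreprocessState",
    "KnnModel",
    "redundancy_filter",
    "fit_normalizer",
    "apply_normalizer",
    "split_train_test",
    "cfs_merit",
    "best_first_select",
    "knn_fit",
    "knn_predict",
    "ModelBundle",
    "fit_pipeline",
]

EQUALITY_TOL = 1e-12


@dataclass(frozen=True)
class TableSchema:
    """Column roles for a modelling table: id / numeric / nominal / endpoint."""

    roles: dict

    def __post_init__(self):
        bad = set(self.roles.values()) - {"id", "numeric", "nominal", "endpoint"}
        if bad:
            raise ConfigurationError(f"unknown column roles: {sorted(bad)}")
        if list(self.roles.values()).count("endpoint") != 1:
            raise ConfigurationError("schema must declare exactly one endpoint column")

    def columns(self, role: str, table: pd.DataFrame | None = None) -> list[str]:
        cols = [c for c, r in self.roles.items() if r == role]
        if table is not None:
            cols = [c for c in cols if c in table.columns]
        return cols

    @property
    def endpoint(self) -> str:
        return next(c for c, r in self.roles.items() if r == "endpoint")


def redundancy_filter(
    table: pd.DataFrame, schema: TableSchema, criterion: float = 0.2
) -> tuple[pd.DataFrame, list]:
    """Drop near-duplicate and constant descriptor columns.

    For every ordered pair of numeric descriptor columns, the later column
    is dropped when the fraction of rows on which the two agree (within
    1e-12) reaches ``criterion``.  Zero-variance columns are dropped as
    well.  Returns the filtered table and a list of ``(column, reason)``.
    """
    if not 0 < criterion <= 1:
        raise InvalidArgumentError("criterion must be in (0, 1]")
    numeric = schema.columns("numeric", table)
    dropped: list[tuple[str, str]] = []
    kept: list[str] = []
    for col in numeric:
        vals = table[col].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            dropped.append((col, "zero variance"))
            continue
        duplicate_of = None
        for ref in kept:
            ref_vals = table[ref].to_numpy(dtype=float)
            frac = float(np.mean(np.abs(vals - ref_vals) <= EQUALITY_TOL))
            if frac >= criterion:
                duplicate_of = (ref, frac)
                break
        if duplicate_of:
            dropped.append((col, f"{duplicate_of[1]:.0%} values equal to {duplicate_of[0]}"))
        else:
            kept.append(col)
    out = table.drop(columns=[c for c, _ in dropped])
    return out, dropped


@dataclass
class PreprocessState:
    """Train-fitted z-score parameters (population standard deviation)."""

    means: dict
    stds: dict
    dropped: list = field(default_factory=list)

    def to_dict(self):
        return {"means": self.means, "stds": self.stds, "dropped": self.dropped}

    @classmethod
    def from_dict(cls, d):
        return cls(means=dict(d["means"]), stds=dict(d["stds"]), dropped=list(d["dropped"]))


def fit_normalizer(train: pd.DataFrame, schema: TableSchema) -> PreprocessState:
    """Fit z-score statistics on numeric descriptors and the endpoint.

    Columns with zero spread cannot be z-scored and are recorded as
    dropped.  Population (divide-by-n) standard deviations are used; the
    convention is absorbed by the train-only fit.
    """
    if train.empty:
        raise InvalidArgumentError("training table is empty")
    cols = schema.columns("numeric", train) + [schema.endpoint]
    means, stds, dropped = {}, {}, []
    for col in cols:
        if col not in train.columns:
            continue
        vals = train[col].to_numpy(dtype=float)
        std = float(vals.std())  # ddof=0
        if std == 0:
            dropped.append((col, "zero std"))
            continue
        means[col] = float(vals.mean())
        stds[col] = std
    return PreprocessState(means, stds, dropped)


def apply_normalizer(state: PreprocessState, table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every fitted column present in ``table``; others untouched."""
    out = table.copy()
    for col, mean in state.means.items():
        if col in out.columns:
            out[col] = (out[col].to_numpy(dtype=float) - mean) / state.stds[col]
    return out


def split_train_test(
    table: pd.DataFrame, fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random row split; |train| = round(fraction * n); reproducible."""
    if len(table) < 10:
        raise InvalidArgumentError("need at least 10 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    n_train = int(round(fraction * len(table)))
    return table.iloc[perm[:n_train]], table.iloc[perm[n_train:]]


# ---------------------------------------------------------------------------
# Correlation-based feature selection


def _encode(table: pd.DataFrame, cols, schema: TableSchema) -> np.ndarray:
    """Numeric matrix for correlations: nominal columns as 0/1 codes."""
    mats = []
    for c in cols:
        if schema.roles.get(c) == "nominal":
            codes = pd.factorize(table[c], sort=True)[0].astype(float)
            mats.append(codes)
        else:
            mats.append(table[c].to_numpy(dtype=float))
    return np.column_stack(mats) if mats else np.empty((len(table), 0))


def _safe_abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    # constant columns have no defined correlation; treated as 0
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def cfs_merit(subset, train: pd.DataFrame, schema: TableSchema) -> float:
    """CFS subset merit ``k r_cf / sqrt(k + k (k-1) r_ff)``.

    ``r_cf`` is the mean absolute Pearson correlation of subset features
    with the endpoint, ``r_ff`` the mean absolute pairwise correlation
    within the subset.
    """
    subset = list(subset)
    if not subset:
        raise InvalidArgumentError("subset must be non-empty")
    X = _encode(train, subset, schema)
    y = train[schema.endpoint].to_numpy(dtype=float)
    k = len(subset)
    r_cf = float(np.mean([_safe_abs_corr(X[:, i], y) for i in range(k)]))
    if k == 1:
        return r_cf
    pair = [
        _safe_abs_corr(X[:, i], X[:, j])
        for i in range(k)
        for j in range(i + 1, k)
    ]
    r_ff = float(np.mean(pair))
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def best_first_select(
    train: pd.DataFrame,
    schema: TableSchema,
    candidates=None,
    stale_limit: int = 5,
) -> list:
    """Forward best-first search maximizing the CFS merit.

    Starts from the empty set, repeatedly expands the best open subset by
    one feature, and stops after ``stale_limit`` consecutive expansions
    that fail to improve the best merit seen.  Deterministic: ties are
    broken by column order.
    """
    if candidates is None:
        candidates = schema.columns("numeric", train) + schema.columns("nominal", train)
    candidates = [c for c in candidates if c != schema.endpoint]
    if len(candidates) < 2:
        return list(candidates)
    order = {c: i for i, c in enumerate(candidates)}
    cache: dict[frozenset, float] = {}

    def merit(subset: frozenset) -> float:
        if subset not in cache:
            cache[subset] = cfs_merit(sorted(subset, key=order.get), train, schema) if subset else 0.0
        return cache[subset]

    start = frozenset()
    open_set = {start}
    closed = set()
    best_subset, best_merit = start, 0.0
    stale = 0
    while open_set and stale < stale_limit:
        # best open node; ties -> smaller subset, then column order
        node = min(
            open_set,
            key=lambda s: (-merit(s), len(s), tuple(sorted(order[c] for c in s))),
        )
        open_set.discard(node)
        closed.add(node)
        improved = False
        for c in candidates:
            if c in node:
                continue
            child = node | {c}
            if child in closed or child in open_set:
                continue
            open_set.add(child)
            if merit(child) > best_merit + 1e-12:
                best_subset, best_merit = child, merit(child)
                improved = True
        stale = 0 if improved else stale + 1
    return sorted(best_subset, key=order.get)


# ---------------------------------------------------------------------------
# kNN read-across


@dataclass
class KnnModel:
    """Fitted mixed-distance kNN regressor.

    ``X`` holds the training rows restricted to the selected features
    (numeric columns already normalized; nominal columns as raw labels),
    ``y`` the (normalized) endpoints, ``ids`` the material identifiers.
    """

    features: list
    nominal: list
    X_numeric: np.ndarray
    X_nominal: np.ndarray
    y: np.ndarray
    ids: list
    n_neighbors: int = 3

    def __post_init__(self):
        if not 1 <= self.n_neighbors <= len(self.y):
            raise ConfigurationError(
                f"n_neighbors must be in [1, {len(self.y)}], got {self.n_neighbors}"
            )


def _split_features(features, schema: TableSchema):
    nominal = [f for f in features if schema.roles.get(f) == "nominal"]
    numeric = [f for f in features if f not in nominal]
    return numeric, nominal


def knn_fit(
    train: pd.DataFrame,
    schema: TableSchema,
    features,
    n_neighbors: int = 3,
    id_column: str | None = None,
) -> KnnModel:
    """Store the (already normalized) training rows for lazy prediction."""
    missing = [f for f in features if f not in train.columns]
    if missing:
        raise InvalidArgumentError(f"training table lacks features {missing}")
    numeric, nominal = _split_features(features, schema)
    if id_column is None:
        ids = [str(i) for i in train.index]
    else:
        ids = [str(v) for v in train[id_column]]
    return KnnModel(
        features=list(features),
        nominal=nominal,
        X_numeric=train[numeric].to_numpy(dtype=float),
        X_nominal=train[nominal].to_numpy(dtype=object),
        y=train[schema.endpoint].to_numpy(dtype=float),
        ids=ids,
        n_neighbors=n_neighbors,
    )


def _distances(model: KnnModel, row_numeric: np.ndarray, row_nominal: np.ndarray) -> np.ndarray:
    d2 = ((model.X_numeric - row_numeric) ** 2).sum(axis=1)
    if model.X_nominal.shape[1]:
        d2 = d2 + (model.X_nominal != row_nominal).sum(axis=1)
    return np.sqrt(d2)


def knn_predict(model: KnnModel, queries: pd.DataFrame, n_report: int = 4):
    """Predict each query row from its nearest training neighbours.

    The squared distance is the sum of squared differences over numeric
    (z-scored) features plus a 0/1 mismatch indicator per nominal feature.
    The prediction is the unweighted mean endpoint of the ``n_neighbors``
    nearest rows; ties are broken by training-row order.  Returns
    ``(predictions, neighbor_ids, neighbor_distances)`` where the neighbour
    arrays cover the ``n_report`` nearest rows (default 4, for reporting)
    regardless of ``n_neighbors``.
    """
    missing = [f for f in model.features if f not in queries.columns]
    if missing:
        raise InvalidArgumentError(f"query rows lack features {missing}")
    numeric = [f for f in model.features if f not in model.nominal]
    Qn = queries[numeric].to_numpy(dtype=float)
    Qc = queries[model.nominal].to_numpy(dtype=object)
    n_report = min(n_report, len(model.y))
    preds = np.empty(len(queries))
    nn_ids = []
    nn_dist = np.empty((len(queries), n_report))
    for i in range(len(queries)):
        d = _distances(model, Qn[i], Qc[i] if Qc.shape[1] else Qc[:0])
        order = np.lexsort((np.arange(len(d)), d))  # stable: distance, then row order
        preds[i] = model.y[order[: model.n_neighbors]].mean()
        nn_ids.append([model.ids[j] for j in order[:n_report]])
        nn_dist[i] = d[order[:n_report]]
    return preds, nn_ids, nn_dist


# ---------------------------------------------------------------------------
# End-to-end fit and the serializable model bundle


@dataclass
class ModelBundle:
    """Everything needed to reproduce predictions: preprocessing, features,
    training matrix, neighbour count and the applicability-domain state."""

    schema: TableSchema
    preprocess: PreprocessState
    model: KnnModel
    apd: "object" = None  # validation.ApdState
    dropped_columns: list = field(default_factory=list)
    version: int = 1

    def save(self, path) -> None:
        from .validation import ApdState

        payload = {
            "version": self.version,
            "schema": self.schema.roles,
            "preprocess": self.preprocess.to_dict(),
            "dropped_columns": self.dropped_columns,
            "model": {
                "features": self.model.features,
                "nominal": self.model.nominal,
                "X_numeric": self.model.X_numeric.tolist(),
                "X_nominal": self.model.X_nominal.tolist(),
                "y": self.model.y.tolist(),
                "ids": self.model.ids,
                "n_neighbors": self.model.n_neighbors,
            },
            "apd": None if self.apd is None else self.apd.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "ModelBundle":
        from .validation import ApdState

        d = json.loads(Path(path).read_text())
        if d.get("version") != 1:
            raise ConfigurationError(f"unsupported bundle version {d.get('version')}")
        m = d["model"]
        model = KnnModel(
            features=m["features"],
            nominal=m["nominal"],
            X_numeric=np.array(m["X_numeric"], dtype=float).reshape(len(m["y"]), -1),
            X_nominal=np.array(m["X_nominal"], dtype=object).reshape(len(m["y"]), -1),
            y=np.array(m["y"], dtype=float),
            ids=list(m["ids"]),
            n_neighbors=m["n_neighbors"],
        )
        return cls(
            schema=TableSchema(d["schema"]),
            preprocess=PreprocessState.from_dict(d["preprocess"]),
            model=model,
            apd=None if d["apd"] is None else ApdState.from_dict(d["apd"]),
            dropped_columns=d["dropped_columns"],
        )


def fit_pipeline(
    table: pd.DataFrame,
    schema: TableSchema,
    seed: int = 0,
    n_neighbors: int = 3,
    criterion: float = 0.2,
    features=None,
    id_column: str | None = None,
    split_fraction: float = 0.7,
):
    """Run the full training pipeline; returns (bundle, train, test).

    Steps: redundancy filter, 70/30 split, z-score normalization fitted on
    the training rows (applied to both), CFS + best-first feature selection
    (unless ``features`` pins them), kNN fit, and APD fit on the selected
    training matrix.  The returned train/test frames are normalized.
    """
    from .validation import apd_fit

    filtered, dropped = redundancy_filter(table, schema, criterion)
    train_raw, test_raw = split_train_test(filtered, split_fraction, seed)
    state = fit_normalizer(train_raw, schema)
    for col, _reason in state.dropped:
        if col != schema.endpoint:
            filtered = filtered.drop(columns=[col])
            dropped = dropped + [(col, "zero std in training split")]
    train = apply_normalizer(state, train_raw.drop(columns=[c for c, _ in state.dropped], errors="ignore"))
    test = apply_normalizer(state, test_raw.drop(columns=[c for c, _ in state.dropped], errors="ignore"))
    if features is None:
        features = best_first_select(train, schema)
    model = knn_fit(train, schema, features, n_neighbors, id_column)
    apd = apd_fit(model)
    bundle = ModelBundle(
        schema=schema,
        preprocess=state,
        model=model,
        apd=apd,
        dropped_columns=[list(d) for d in dropped],
    )
    return bundle, train, test
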