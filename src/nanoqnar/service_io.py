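"""Batch prediction interface with the published request/response schema.

A request tuple carries the 7 descriptors the final model needs::

    {"id": "CuO", "coreSize": 25, "hydroSize": 45, "ecEv": -5.17,
     "assay": "ATP", "exposureDose": 3.2, "des306": 3.579, "des606": -0.243}

``des306`` is the mean coordination number of surface metal atoms and
``des606`` the mean surface-normal force component of surface metal atoms.
Each response record reports the normalized inputs, the four nearest
training neighbours with their Euclidean distances, the kNN prediction on
the normalized endpoint scale (``knnprediction``, matching the published
schema) plus the denormalized ``viabilityPercent``, and the applicability
domain flag.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RequestValidationError
from .qnar_pipeline import ModelBundle, apply_normalizer, knn_predict
from .validation import apd_classify

__all__ = [
    "REQUEST_FIELDS",
    "SERVICE_FEATURES",
    "PredictionRequest",
    "PredictionRecord",
    "parse_requests",
    "predict_batch",
    "serialize_records",
]

#: Input field order as published (id first, then the 7 descriptors).
REQUEST_FIELDS = (
    "id",
    "coreSize",
    "hydroSize",
    "ecEv",
    "assay",
    "exposureDose",
    "des306",
    "des606",
)

#: The model feature columns corresponding to a request (all but id).
SERVICE_FEATURES = [f for f in REQUEST_FIELDS if f != "id"]

_NUMERIC_FIELDS = tuple(f for f in SERVICE_FEATURES if f != "assay")
_ASSAYS = ("ATP", "LDH")


@dataclass(frozen=True)
class PredictionRequest:
    id: str
    coreSize: float
    hydroSize: float
    ecEv: float
    assay: str
    exposureDose: float
    des306: float
    des606: float

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in REQUEST_FIELDS}


@dataclass(frozen=True)
class PredictionRecord:
    """One response tuple; field order follows the published schema."""

    id: str
    assay: str
    apdPrediction: str
    nn1ID: str
    nn2ID: str
    nn3ID: str
    nn4ID: str
    coreSize: float
    hydroSize: float
    ecEv: float
    exposureDose: float
    des306: float
    des606: float
    nn1Distance: float
    nn2Distance: float
    nn3Distance: float
    nn4Distance: float
    knnprediction: float
    viabilityPercent: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_tuple(raw: dict, index: int) -> tuple[PredictionRequest | None, list]:
    errors = []
    unknown = set(raw) - set(REQUEST_FIELDS)
    if unknown:
        errors.append(f"record {index}: unknown fields {sorted(unknown)}")
    values = {}
    for f in REQUEST_FIELDS:
        if f not in raw or (isinstance(raw[f], float) and np.isnan(raw[f])):
            errors.append(f"record {index}: missing field '{f}'")
            continue
        v = raw[f]
        if f == "id":
            values[f] = str(v)
        elif f == "assay":
            if str(v) not in _ASSAYS:
                errors.append(f"record {index}: bad assay label {v!r} (expected ATP or LDH)")
            else:
                values[f] = str(v)
        else:
            try:
                x = float(v)
                if not np.isfinite(x):
                    raise ValueError
                values[f] = x
            except (TypeError, ValueError):
                errors.append(f"record {index}: non-numeric value for '{f}': {v!r}")
    if errors:
        return None, errors
    return PredictionRequest(**values), []


def parse_requests(payload) -> list[PredictionRequest]:
    """Parse a batch of request tuples from JSON or CSV.

    ``payload`` may be a JSON array string, a list of dicts, a DataFrame,
    or a path to a ``.json``/``.csv`` file with the same column names.
    All records are validated; any failure raises
    :class:`RequestValidationError` naming every offending field.
    """
    records = _coerce_records(payload)
    requests, errors = [], []
    for i, raw in enumerate(records):
        req, errs = _validate_tuple(raw, i)
        errors.extend(errs)
        if req is not None:
            requests.append(req)
    if errors:
        raise RequestValidationError(errors)
    return requests


def _coerce_records(payload) -> list[dict]:
    if isinstance(payload, pd.DataFrame):
        return payload.to_dict(orient="records")
    if isinstance(payload, (list, tuple)):
        return [dict(r) for r in payload]
    if isinstance(payload, (str, Path)):
        p = Path(payload)
        text = None
        if isinstance(payload, Path) or (len(str(payload)) < 4096 and p.suffix in {".json", ".csv"} and p.exists()):
            text = p.read_text()
            if p.suffix == ".csv":
                return pd.read_csv(io.StringIO(text)).to_dict(orient="records")
        else:
            text = str(payload)
        stripped = text.lstrip()
        if stripped.startswith("[") or stripped.startswith("{"):
            data = json.loads(text)
            if isinstance(data, dict):
                data = [data]
            return [dict(r) for r in data]
        return pd.read_csv(io.StringIO(text)).to_dict(orient="records")
    raise RequestValidationError([f"unsupported payload type {type(payload).__name__}"])


def predict_batch(bundle: ModelBundle, requests) -> list[PredictionRecord]:
    """Predict a batch of validated requests with a trained service bundle.

    Composes the pipeline primitives record-wise: normalize with the
    bundle's train-fitted state, query the kNN model, and classify against
    the applicability domain.  No independent prediction logic lives here.
    """
    if isinstance(requests, (str, Path, pd.DataFrame)) or (
        requests and isinstance(requests[0], dict)
    ):
        requests = parse_requests(requests)
    missing = [f for f in bundle.model.features if f not in SERVICE_FEATURES]
    if missing:
        raise ConfigurationError(
            f"bundle features {missing} are outside the service request schema"
        )
    if not requests:
        return []
    frame = pd.DataFrame([r.to_dict() for r in requests])
    norm = apply_normalizer(bundle.preprocess, frame)
    preds, nn_ids, nn_dist = knn_predict(bundle.model, norm, n_report=4)
    k = bundle.model.n_neighbors
    flags = apd_classify(bundle.apd, nn_dist[:, : min(k, nn_dist.shape[1])])

    ep = bundle.schema.endpoint
    ep_mean = bundle.preprocess.means.get(ep)
    ep_std = bundle.preprocess.stds.get(ep)

    records = []
    for i, req in enumerate(requests):
        ids4 = (nn_ids[i] + [""] * 4)[:4]
        d4 = list(nn_dist[i]) + [float("nan")] * (4 - nn_dist.shape[1])
        records.append(
            PredictionRecord(
                id=req.id,
                assay=req.assay,
                apdPrediction=flags[i],
                nn1ID=ids4[0],
                nn2ID=ids4[1],
                nn3ID=ids4[2],
                nn4ID=ids4[3],
                coreSize=float(norm["coreSize"].iloc[i]),
                hydroSize=float(norm["hydroSize"].iloc[i]),
                ecEv=float(norm["ecEv"].iloc[i]),
                exposureDose=float(norm["exposureDose"].iloc[i]),
                des306=float(norm["des306"].iloc[i]),
                des606=float(norm["des606"].iloc[i]),
                nn1Distance=float(d4[0]),
                nn2Distance=float(d4[1]),
                nn3Distance=float(d4[2]),
                nn4Distance=float(d4[3]),
                knnprediction=float(preds[i]),
                viabilityPercent=(
                    None if ep_mean is None else float(preds[i] * ep_std + ep_mean)
                ),
            )
        )
    return records


def serialize_records(records, path=None) -> str:
    """JSON-serialize response records (full precision); optionally write."""
    text = json.dumps([r.to_dict() for r in records], indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text
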