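"""External-validation statistics, Y-randomization and applicability domain.

The Tropsha acceptability suite scores test-set predictions with the
external cross-validated coefficient

    R2_cvext = 1 - sum (y - yhat)^2 / sum (y - ybar_train)^2,

through-origin regression slopes in both directions

    k  = sum y yhat / sum yhat^2      k' = sum y yhat / sum y^2,

and through-origin determination coefficients R0^2 / R0'^2 built from the
fitted lines yhat_ro = k y (and y_ro = k' yhat).  A model is accepted when
R2_cvext > 0.5, R2_pred > 0.6, (R2_pred - R0^2)/R2_pred < 0.1 in at least
one direction, and 0.85 <= k <= 1.15 in both.

Y-randomization refits the whole pipeline on endpoint-shuffled copies of
the table; a real model must outperform the shuffled ones.  The
applicability domain (APD) threshold is <d> + Z sigma over training-set
pairwise distances (Z = 0.5); queries farther than that from their
nearest neighbours are flagged unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedStatisticError

__all__ = [
    "TropshaReport",
    "tropsha_suite",
    "y_randomization",
    "ApdState",
    "apd_fit",
    "apd_classify",
]


@dataclass(frozen=True)
class TropshaReport:
    """External validation statistics and their pass/fail flags."""

    r2_pred: float
    r2_cvext: float
    k: float
    k_prime: float
    r0_sq: float
    r0_prime_sq: float
    passes_cvext: bool
    passes_r2: bool
    passes_r0: bool
    passes_slope: bool

    @property
    def passes_all(self) -> bool:
        return self.passes_cvext and self.passes_r2 and self.passes_r0 and self.passes_slope

    def to_dict(self) -> dict:
        return {
            "r2_pred": self.r2_pred,
            "r2_cvext": self.r2_cvext,
            "k": self.k,
            "k_prime": self.k_prime,
            "r0_sq": self.r0_sq,
            "r0_prime_sq": self.r0_prime_sq,
            "passes_cvext": self.passes_cvext,
            "passes_r2": self.passes_r2,
            "passes_r0": self.passes_r0,
            "passes_slope": self.passes_slope,
            "passes_all": self.passes_all,
        }


def _through_origin_r0(y_ref: np.ndarray, y_fit: np.ndarray) -> tuple[float, float]:
    """Slope k = sum(y_ref*y_fit)/sum(y_fit^2) and the R0^2 it induces.

    R0^2 = 1 - sum (y_fit - k y_ref)^2 / sum (y_fit - mean(y_fit))^2.
    """
    denom = float((y_fit**2).sum())
    if denom == 0:
        raise UndefinedStatisticError("through-origin slope undefined: sum yhat^2 = 0")
    k = float((y_ref * y_fit).sum()) / denom
    spread = float(((y_fit - y_fit.mean()) ** 2).sum())
    if spread == 0:
        # constant fit values: no through-origin fit can explain any spread
        return k, 0.0
    r0 = 1.0 - float(((y_fit - k * y_ref) ** 2).sum()) / spread
    return k, r0


def tropsha_suite(y_true, y_pred, y_train_mean: float) -> TropshaReport:
    """Compute the full external-validation report on a test set."""
    y = np.asarray(y_true, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    if len(y) < 3:
        raise InvalidArgumentError("need at least 3 test observations")
    if y.std() == 0:
        raise UndefinedStatisticError("test endpoints are constant")

    denom = float(((y - y_train_mean) ** 2).sum())
    if denom == 0:
        raise UndefinedStatisticError("R2_cvext undefined: zero reference spread")
    r2_cvext = 1.0 - float(((y - yh) ** 2).sum()) / denom

    if yh.std() == 0:
        r2_pred = 0.0
    else:
        r2_pred = float(np.corrcoef(y, yh)[0, 1]) ** 2

    k, r0_sq = _through_origin_r0(y, yh)
    k_prime, r0_prime_sq = _through_origin_r0(yh, y)

    passes_cvext = r2_cvext > 0.5
    passes_r2 = r2_pred > 0.6
    if r2_pred == 0:
        passes_r0 = False
    else:
        passes_r0 = (
            abs(r2_pred - r0_sq) / r2_pred < 0.1
            or abs(r2_pred - r0_prime_sq) / r2_pred < 0.1
        )
    passes_slope = (0.85 <= k <= 1.15) and (0.85 <= k_prime <= 1.15)
    return TropshaReport(
        r2_pred=r2_pred,
        r2_cvext=r2_cvext,
        k=k,
        k_prime=k_prime,
        r0_sq=r0_sq,
        r0_prime_sq=r0_prime_sq,
        passes_cvext=passes_cvext,
        passes_r2=passes_r2,
        passes_r0=passes_r0,
        passes_slope=passes_slope,
    )


def y_randomization(
    table: pd.DataFrame,
    schema,
    n_rounds: int = 10,
    seed: int = 0,
    **pipeline_kwargs,
) -> dict:
    """Refit the pipeline on endpoint-shuffled tables and compare.

    Descriptors are untouched; only the endpoint column is permuted each
    round.  Returns the original report plus one report per round and the
    count of rounds whose R2_pred degraded below the original.
    """
    from .qnar_pipeline import fit_pipeline, knn_predict

    def run(tab, run_seed):
        bundle, train, test = fit_pipeline(tab, schema, seed=run_seed, **pipeline_kwargs)
        preds, _, _ = knn_predict(bundle.model, test)
        y_test = test[schema.endpoint].to_numpy(dtype=float)
        return tropsha_suite(y_test, preds, float(bundle.model.y.mean()))

    original = run(table, seed)
    rng = np.random.default_rng(seed)
    rounds = []
    for _ in range(n_rounds):
        shuffled = table.copy()
        col = schema.endpoint
        shuffled[col] = rng.permutation(shuffled[col].to_numpy())
        rounds.append(run(shuffled, seed))
    degraded = sum(r.r2_pred < original.r2_pred for r in rounds)
    return {
        "original": original,
        "rounds": rounds,
        "n_degraded": degraded,
        "mean_shuffled_r2": float(np.mean([r.r2_pred for r in rounds])),
    }


# ---------------------------------------------------------------------------
# Applicability domain


@dataclass(frozen=True)
class ApdState:
    """Reliability threshold ``APD = <d> + Z sigma`` over training distances."""

    mean_distance: float
    std_distance: float
    z: float = 0.5
    refined: bool = True

    @property
    def threshold(self) -> float:
        return self.mean_distance + self.z * self.std_distance

    def to_dict(self) -> dict:
        return {
            "mean_distance": self.mean_distance,
            "std_distance": self.std_distance,
            "z": self.z,
            "refined": self.refined,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d) -> "ApdState":
        return cls(
            mean_distance=d["mean_distance"],
            std_distance=d["std_distance"],
            z=d["z"],
            refined=d["refined"],
        )


def _training_pairwise(model) -> np.ndarray:
    d2 = (
        (model.X_numeric[:, None, :] - model.X_numeric[None, :, :]) ** 2
    ).sum(axis=-1)
    if model.X_nominal.shape[1]:
        d2 = d2 + (model.X_nominal[:, None, :] != model.X_nominal[None, :, :]).sum(axis=-1)
    d = np.sqrt(d2)
    iu = np.triu_indices(len(d), k=1)
    return d[iu]


def apd_fit(model, z: float = 0.5, refined: bool = True) -> ApdState:
    """Fit the APD threshold from training-set pairwise distances.

    With ``refined=True`` (the Enalos-style convention) the mean and
    standard deviation are taken over the pairs lying below the grand mean
    distance, falling back to the full set when that subset is empty;
    ``refined=False`` uses all pairs.  Population standard deviation.
    """
    if len(model.y) < 2:
        raise InvalidArgumentError("APD needs at least 2 training rows")
    pair = _training_pairwise(model)
    subset = pair
    if refined:
        below = pair[pair < pair.mean()]
        if below.size:
            subset = below
    return ApdState(
        mean_distance=float(subset.mean()),
        std_distance=float(subset.std()),
        z=z,
        refined=refined,
    )


def apd_classify(state: ApdState, neighbor_distances) -> list:
    """Label each query reliable/unreliable from its neighbour distances.

    A query is reliable when the mean distance to its nearest training
    neighbours (the rows used for its prediction) does not exceed the APD
    threshold.
    """
    nd = np.atleast_2d(np.asarray(neighbor_distances, dtype=float))
    labels = []
    for row in nd:
        labels.append("reliable" if row.mean() <= state.threshold else "unreliable")
    return labels
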