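"""Applicability-domain analytics.

A model's applicability domain (AD) is the descriptor-space region spanned by
its training compounds; predictions outside it are extrapolations.  Two
standard distance measures are provided:

* **leverage** — the hat-matrix diagonal for the intercept-augmented training
  design, h(x) = [1, x] (X'X)^-1 [1, x]'; the conventional warning threshold
  is h* = 3 (d + 1) / n;
* **Mahalanobis distance** — sqrt((x - c)' S^-1 (x - c)) with centroid c and
  sample covariance S (divisor n - 1) of the training rows.

Both fall back to the Moore-Penrose pseudo-inverse on singular designs, with
a ``singular`` flag carried in :class:`AdParameters`.  Williams-plot data
(standardized residual vs leverage, plus Gramatica/Insubria-style rows for
compounds without experimental values) and Euclidean nearest-neighbour
similarity round out the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Archive, Model, ValuesTable
from .errors import DimensionMismatch, InsufficientTraining, QdbError

__all__ = [
    "AdParameters",
    "AdProfile",
    "fit_ad",
    "leverage",
    "mahalanobis",
    "williams_data",
    "similar_compounds",
]


@dataclass
class AdParameters:
    """Training-set AD parameters for one model."""

    descriptor_ids: list[str]
    compound_ids: list[str]          # training compounds with complete rows
    training_matrix: np.ndarray      # (n, d)
    centroid: np.ndarray             # (d,)
    covariance: np.ndarray           # (d, d), divisor n-1
    xtx_inverse: np.ndarray          # (d+1, d+1) (pseudo-)inverse of augmented X'X
    cov_inverse: np.ndarray          # (d, d) (pseudo-)inverse of covariance
    warning_leverage: float          # 3 (d+1) / n
    training_rmse: float | None      # None when no experimental values available
    singular: bool
    rank: int                        # rank of the augmented design


@dataclass
class AdProfile:
    """Per-compound AD record for Williams/Gramatica plot data."""

    compound_id: str
    set_kind: str
    leverage: float
    mahalanobis: float
    predicted: float | str | None = None
    experimental: float | None = None
    residual: float | None = None
    std_residual: float | None = None


def _descriptor_rows(archive: Archive, model: Model) -> tuple[list[str], dict[str, np.ndarray]]:
    """Complete descriptor rows for every compound, keyed by compound id."""
    tables: list[ValuesTable] = []
    for descriptor_id in model.descriptor_ids:
        descriptor = archive.descriptors.get(descriptor_id)
        if descriptor is None or descriptor.cargos.get("values") is None:
            return model.descriptor_ids, {}
        tables.append(descriptor.values_table())
    rows: dict[str, np.ndarray] = {}
    for compound in archive.compounds:
        values = []
        for table in tables:
            if compound.id not in table or table.is_missing(compound.id):
                break
            value = table.get(compound.id)
            if isinstance(value, str):
                break
            values.append(value)
        else:
            rows[compound.id] = np.array(values, dtype=float)
    return model.descriptor_ids, rows


def _training_prediction(archive: Archive, model: Model):
    for prediction in archive.predictions_of(model):
        if prediction.set_kind == "training":
            return prediction
    return None


def fit_ad(archive: Archive, model: Model) -> AdParameters:
    """Estimate AD parameters from the model's training compounds only."""
    descriptor_ids, rows = _descriptor_rows(archive, model)
    training = _training_prediction(archive, model)
    if training is None or training.cargos.get("values") is None:
        raise InsufficientTraining(f"{model.path}: no training prediction with values")
    stored = training.values_table()
    compound_ids = [cid for cid in stored.keys() if cid in rows]
    if len(compound_ids) < 2:
        raise InsufficientTraining(
            f"{model.path}: {len(compound_ids)} complete training rows, need >= 2")
    X = np.vstack([rows[cid] for cid in compound_ids])
    n, d = X.shape
    centroid = X.mean(axis=0)
    covariance = np.cov(X, rowvar=False, ddof=1)
    covariance = np.atleast_2d(covariance)
    X_aug = np.column_stack([np.ones(n), X])
    xtx = X_aug.T @ X_aug
    rank = int(np.linalg.matrix_rank(X_aug))
    singular = rank < d + 1
    if singular:
        xtx_inverse = np.linalg.pinv(xtx)
        cov_inverse = np.linalg.pinv(covariance)
    else:
        xtx_inverse = np.linalg.inv(xtx)
        try:
            cov_inverse = np.linalg.inv(covariance)
        except np.linalg.LinAlgError:
            cov_inverse = np.linalg.pinv(covariance)
    training_rmse = _training_rmse(archive, model, stored)
    return AdParameters(
        descriptor_ids=list(descriptor_ids),
        compound_ids=compound_ids,
        training_matrix=X,
        centroid=centroid,
        covariance=covariance,
        xtx_inverse=xtx_inverse,
        cov_inverse=cov_inverse,
        warning_leverage=3.0 * (d + 1) / n,
        training_rmse=training_rmse,
        singular=singular,
        rank=rank,
    )


def _training_rmse(archive: Archive, model: Model, stored: ValuesTable) -> float | None:
    prop = archive.properties.get(model.property_id) if model.property_id else None
    if prop is None or prop.cargos.get("values") is None:
        return None
    try:
        experimental = prop.values_table()
    except QdbError:
        return None
    sq = []
    for cid, yhat in stored.items():
        if isinstance(yhat, str) or yhat is None or cid not in experimental:
            continue
        y = experimental.get(cid)
        if y is None or isinstance(y, str):
            continue
        sq.append((y - yhat) ** 2)
    if not sq:
        return None
    return float(np.sqrt(np.mean(sq)))


def _check_dim(params: AdParameters, x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != len(params.descriptor_ids):
        raise DimensionMismatch(
            f"expected {len(params.descriptor_ids)} descriptor values, got {x.shape[0]}")
    return x


def leverage(params: AdParameters, x) -> float:
    """Hat value of a query point against the training design."""
    x = _check_dim(params, x)
    v = np.concatenate([[1.0], x])
    return float(v @ params.xtx_inverse @ v)


def mahalanobis(params: AdParameters, x) -> float:
    """Mahalanobis distance of a query point from the training centroid."""
    x = _check_dim(params, x)
    delta = x - params.centroid
    d2 = float(delta @ params.cov_inverse @ delta)
    return float(np.sqrt(max(d2, 0.0)))


def williams_data(archive: Archive, model: Model,
                  params: AdParameters | None = None) -> list[AdProfile]:
    """One AD profile per compound appearing in any prediction of the model.

    Residuals use the *stored* predicted values; compounds without an
    experimental value keep leverage/Mahalanobis but no residual (the
    Gramatica/Insubria-style points).  Profiles follow compound-registry
    order; a compound in several sets takes the first set in
    training/validation/testing order.
    """
    if params is None:
        params = fit_ad(archive, model)
    _, rows = _descriptor_rows(archive, model)
    membership: dict[str, str] = {}
    predicted: dict[str, float | str] = {}
    order = {"training": 0, "validation": 1, "testing": 2}
    for prediction in sorted(archive.predictions_of(model),
                             key=lambda p: order.get(p.set_kind, 3)):
        if prediction.cargos.get("values") is None:
            continue
        for cid, value in prediction.values_table().items():
            if cid not in membership:
                membership[cid] = prediction.set_kind or "external"
                if value is not None:
                    predicted[cid] = value
    experimental: dict[str, float] = {}
    prop = archive.properties.get(model.property_id) if model.property_id else None
    if prop is not None and prop.cargos.get("values") is not None:
        for cid, value in prop.values_table().items():
            if value is not None and not isinstance(value, str):
                experimental[cid] = value
    profiles: list[AdProfile] = []
    for compound in archive.compounds:
        cid = compound.id
        if cid not in membership or cid not in rows:
            continue
        profile = AdProfile(
            compound_id=cid,
            set_kind=membership[cid],
            leverage=leverage(params, rows[cid]),
            mahalanobis=mahalanobis(params, rows[cid]),
            predicted=predicted.get(cid),
        )
        yhat = predicted.get(cid)
        if cid in experimental and yhat is not None and not isinstance(yhat, str):
            profile.experimental = experimental[cid]
            profile.residual = experimental[cid] - yhat
            if params.training_rmse:
                profile.std_residual = profile.residual / params.training_rmse
        profiles.append(profile)
    return profiles


def similar_compounds(archive: Archive, model: Model, x, k: int = 5,
                      scaled: bool = False) -> list[tuple[str, float, float | str | None,
                                                          float | str | None]]:
    """k nearest dataset compounds by Euclidean distance in descriptor space.

    Distances use raw descriptor values by default; ``scaled=True`` z-scores
    each descriptor by the dataset mean and standard deviation first.  Ties
    break by compound-registry order.  Returns
    ``(compound_id, distance, experimental, predicted)`` tuples.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _, rows = _descriptor_rows(archive, model)
    if not rows:
        raise InsufficientTraining(f"{model.path}: no complete descriptor rows")
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != len(model.descriptor_ids):
        raise DimensionMismatch(
            f"expected {len(model.descriptor_ids)} descriptor values, got {x.shape[0]}")
    ordered_ids = [c.id for c in archive.compounds if c.id in rows]
    matrix = np.vstack([rows[cid] for cid in ordered_ids])
    query = x
    if scaled:
        mean = matrix.mean(axis=0)
        sd = matrix.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        matrix = (matrix - mean) / sd
        query = (x - mean) / sd
    distances = np.sqrt(((matrix - query) ** 2).sum(axis=1))
    experimental: dict[str, float | str] = {}
    prop = archive.properties.get(model.property_id) if model.property_id else None
    if prop is not None and prop.cargos.get("values") is not None:
        experimental = {cid: v for cid, v in prop.values_table().items() if v is not None}
    predicted: dict[str, float | str] = {}
    order = {"training": 0, "validation": 1, "testing": 2}
    for prediction in sorted(archive.predictions_of(model),
                             key=lambda p: order.get(p.set_kind, 3)):
        if prediction.cargos.get("values") is None:
            continue
        for cid, value in prediction.values_table().items():
            if value is not None and cid not in predicted:
                predicted[cid] = value
    # stable sort on distance preserves registry order among ties
    ranking = sorted(range(len(ordered_ids)), key=lambda i: distances[i])
    result = []
    for i in ranking[: min(k, len(ordered_ids))]:
        cid = ordered_ids[i]
        result.append((cid, float(distances[i]), experimental.get(cid), predicted.get(cid)))
    return result
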