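"""Prediction summary statistics: regression errors and confusion matrices.

Statistics are computed over the key intersection of an experimental and a
predicted values table, after dropping missing entries on either side.  For
external (validation/testing) sets R^2 may legitimately be negative and is
reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValuesTable
from .errors import NoOverlap, ZeroVariance

__all__ = ["RegressionStats", "ConfusionMatrix", "regression_stats", "confusion", "residuals"]


@dataclass(frozen=True)
class RegressionStats:
    n: int
    r2: float
    rmse: float
    mae: float


@dataclass
class ConfusionMatrix:
    """Square count table, rows = actual label, columns = predicted label."""

    labels: list[str]
    counts: np.ndarray  # shape (k, k), ints

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def count(self, actual: str, predicted: str) -> int:
        return int(self.counts[self.labels.index(actual), self.labels.index(predicted)])

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "counts": self.counts.tolist(),
            "total": self.total,
            "accuracy": self.accuracy,
        }


def _paired(experimental: ValuesTable, predicted: ValuesTable):
    pairs = []
    for key, y in experimental.items():
        if y is None or key not in predicted:
            continue
        yhat = predicted.get(key)
        if yhat is None:
            continue
        pairs.append((key, y, yhat))
    if not pairs:
        raise NoOverlap("no common non-missing compounds")
    return pairs


def regression_stats(experimental: ValuesTable, predicted: ValuesTable) -> RegressionStats:
    """n, R^2, RMSE and MAE over the common non-missing keys.

    R^2 = 1 - SS_res/SS_tot with SS_tot about the experimental mean; a
    zero-variance experimental vector makes R^2 undefined and raises
    :class:`ZeroVariance` rather than reporting 0.
    """
    pairs = _paired(experimental, predicted)
    y = np.array([p[1] for p in pairs], dtype=float)
    yhat = np.array([p[2] for p in pairs], dtype=float)
    residual = y - yhat
    ss_res = float(np.sum(residual**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ZeroVariance("all experimental values identical; r2 undefined")
    n = len(pairs)
    return RegressionStats(
        n=n,
        r2=1.0 - ss_res / ss_tot,
        rmse=float(np.sqrt(ss_res / n)),
        mae=float(np.mean(np.abs(residual))),
    )


def confusion(experimental: ValuesTable, predicted: ValuesTable) -> ConfusionMatrix:
    """Confusion matrix over the sorted union of observed labels."""
    pairs = _paired(experimental, predicted)
    as_label = lambda v: v if isinstance(v, str) else repr(v)
    actual = [as_label(p[1]) for p in pairs]
    pred = [as_label(p[2]) for p in pairs]
    labels = sorted(set(actual) | set(pred))
    index = {label: i for i, label in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, p in zip(actual, pred):
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def residuals(experimental: ValuesTable, predicted: ValuesTable) -> ValuesTable:
    """Per-compound residual (experimental - predicted) over common keys."""
    pairs = _paired(experimental, predicted)
    table = ValuesTable()
    for key, y, yhat in pairs:
        table.set(key, float(y) - float(yhat))
    return table
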