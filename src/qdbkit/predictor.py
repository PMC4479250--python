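"""End-to-end prediction workflow.

Three entry points mirror the three ways a query reaches a deposited model:

* :func:`predict_structure` — SMILES or InChI in; a pluggable descriptor
  calculator turns the structure into descriptor values, the equation is
  evaluated, and the result is annotated with applicability-domain (AD)
  distances and the nearest dataset compounds (3-step pipeline: prepare
  structure, calculate descriptors, evaluate model);
* :func:`predict_manual` — descriptor values entered directly;
* :func:`predict_stored` — repeat a prediction from the raw descriptor data
  stored in the archive for one of its own compounds.

:func:`predict_batch` applies any mix of these record-wise; one bad record
never aborts the batch.

Descriptor calculators are plugins keyed by an application string
("name/version").  The built-in :class:`TableCalculator` ("mock/1.0") is
table-driven and exists so the whole pipeline is exercisable without a
chemistry engine; a real engine (e.g. an RDKit-backed calculator) registers
through the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol

from . import ad as _ad
from .core import Archive, Model, resolve_strong
from .equations import evaluate, parse_equation
from .errors import (
    DescriptorNotComputable,
    DescriptorValueMissing,
    EquationParseError,
    MissingBinding,
    QdbError,
)

__all__ = [
    "DescriptorCalculator",
    "TableCalculator",
    "PredictionResult",
    "predict_structure",
    "predict_manual",
    "predict_stored",
    "predict_batch",
]


class DescriptorCalculator(Protocol):
    """Contract for descriptor-calculator plugins.

    ``application`` identifies the engine as "name/version".  ``calculate``
    returns values for the descriptor ids it can compute; ids it cannot
    compute are *absent* from the result — declining is explicit, never a
    silent zero.
    """

    application: str

    def calculate(self, structure: str, descriptor_ids: list[str]
                  ) -> Mapping[str, float]: ...


class TableCalculator:
    """Table-driven calculator: maps known structure strings to fixed rows."""

    application = "mock/1.0"

    def __init__(self, table: Mapping[str, Mapping[str, float]] | None = None,
                 default: Mapping[str, float] | None = None):
        self.table = {k: dict(v) for k, v in (table or {}).items()}
        self.default = dict(default) if default else None

    def calculate(self, structure: str, descriptor_ids: list[str]) -> dict[str, float]:
        row = self.table.get(structure, self.default)
        if row is None:
            return {}
        return {d: row[d] for d in descriptor_ids if d in row}


@dataclass
class PredictionResult:
    model_id: str
    value: float | str
    descriptor_values: dict[str, float]
    provenance: dict[str, str]                 # per descriptor: computed|manual|stored
    leverage: float | None = None
    mahalanobis: float | None = None
    inside_domain: bool | None = None          # leverage <= 3(d+1)/n, when AD exists
    neighbours: list[tuple] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "value": self.value,
            "descriptors": self.descriptor_values,
            "provenance": self.provenance,
            "ad": {
                "leverage": self.leverage,
                "mahalanobis": self.mahalanobis,
                "inside_domain": self.inside_domain,
            },
            "neighbours": [
                {"compound": c, "distance": d, "experimental": e, "predicted": p}
                for c, d, e, p in self.neighbours
            ],
        }


def _finish(archive: Archive, model: Model, bindings: dict[str, float],
            provenance: dict[str, str], k: int) -> PredictionResult:
    payload = model.cargos.get("equation")
    if payload is None:
        raise EquationParseError(f"{model.path}: no equation cargo")
    spec = parse_equation(payload)
    value = evaluate(spec, bindings)
    x = [bindings[d] for d in model.descriptor_ids]
    result = PredictionResult(
        model_id=model.id,
        value=value,
        descriptor_values=dict(bindings),
        provenance=provenance,
    )
    try:
        params = _ad.fit_ad(archive, model)
    except QdbError:
        params = None
    if params is not None:
        result.leverage = _ad.leverage(params, x)
        result.mahalanobis = _ad.mahalanobis(params, x)
        result.inside_domain = result.leverage <= params.warning_leverage
    try:
        result.neighbours = _ad.similar_compounds(archive, model, x, k=k)
    except QdbError:
        result.neighbours = []
    return result


def _resolve_model(archive: Archive, model: Model | str) -> Model:
    if isinstance(model, str):
        return resolve_strong(archive, "models", model)  # type: ignore[return-value]
    return model


def predict_structure(archive: Archive, model: Model | str, structure: str,
                      calculator: DescriptorCalculator, k: int = 5) -> PredictionResult:
    """Predict from a SMILES or InChI string via a descriptor calculator."""
    model = _resolve_model(archive, model)
    structure = structure.strip()  # step 1: prepare the structure representation
    computed = calculator.calculate(structure, list(model.descriptor_ids))  # step 2
    missing = [d for d in model.descriptor_ids if d not in computed]
    if missing:
        raise DescriptorNotComputable(missing)
    bindings = {d: float(computed[d]) for d in model.descriptor_ids}
    provenance = {d: "computed" for d in model.descriptor_ids}
    return _finish(archive, model, bindings, provenance, k)  # step 3


def predict_manual(archive: Archive, model: Model | str,
                   values: Mapping[str, float], k: int = 5) -> PredictionResult:
    """Predict from manually entered descriptor values."""
    model = _resolve_model(archive, model)
    missing = sorted(set(model.descriptor_ids) - set(values))
    if missing:
        raise MissingBinding(missing)
    bindings = {d: float(values[d]) for d in model.descriptor_ids}
    provenance = {d: "manual" for d in model.descriptor_ids}
    return _finish(archive, model, bindings, provenance, k)


def predict_stored(archive: Archive, model: Model | str, compound_id: str,
                   k: int = 5) -> PredictionResult:
    """Repeat a prediction from the descriptor values stored in the archive."""
    model = _resolve_model(archive, model)
    resolve_strong(archive, "compounds", compound_id, referrer=model.path)
    bindings: dict[str, float] = {}
    for descriptor_id in model.descriptor_ids:
        descriptor = archive.descriptors.get(descriptor_id)
        if descriptor is None or descriptor.cargos.get("values") is None:
            raise DescriptorValueMissing(
                f"descriptor {descriptor_id!r} has no stored values")
        table = descriptor.values_table()
        if compound_id not in table or table.is_missing(compound_id):
            raise DescriptorValueMissing(
                f"compound {compound_id!r} has no value for descriptor "
                f"{descriptor_id!r}")
        value = table.get(compound_id)
        if isinstance(value, str):
            raise DescriptorValueMissing(
                f"descriptor {descriptor_id!r} value for {compound_id!r} is not numeric")
        bindings[descriptor_id] = value
    provenance = {d: "stored" for d in model.descriptor_ids}
    return _finish(archive, model, bindings, provenance, k)


def predict_batch(archive: Archive, model: Model | str, inputs: list[dict],
                  calculator: DescriptorCalculator | None = None,
                  k: int = 5) -> list[dict]:
    """Record-wise prediction over a batch of heterogeneous inputs.

    Each input record is a dict with exactly one of the keys ``structure``,
    ``values`` or ``compound``.  The output list matches the input order;
    each entry is ``{"ok": True, "result": PredictionResult}`` or
    ``{"ok": False, "error": message}``.
    """
    model = _resolve_model(archive, model)
    results: list[dict] = []
    for record in inputs:
        try:
            modes = [key for key in ("structure", "values", "compound") if key in record]
            if len(modes) != 1:
                raise QdbError(
                    f"record must have exactly one of structure/values/compound, "
                    f"got {modes or 'none'}")
            mode = modes[0]
            if mode == "structure":
                if calculator is None:
                    raise QdbError("no descriptor calculator configured")
                result = predict_structure(archive, model, record["structure"],
                                           calculator, k=k)
            elif mode == "values":
                result = predict_manual(archive, model, record["values"], k=k)
            else:
                result = predict_stored(archive, model, record["compound"], k=k)
            results.append({"ok": True, "result": result})
        except QdbError as exc:
            results.append({"ok": False, "error": str(exc)})
    return results
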