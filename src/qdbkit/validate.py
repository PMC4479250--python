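"""Three-level validation of QDB archives.

* **basic** ("sanity testing") — structural well-formedness: required
  attributes, declared cargos present and parseable, CAS check digit and
  InChI syntax for compounds, equation presence for models, strong and weak
  reference resolution.
* **intermediate** ("reusability testing") — unique identifiability: every
  compound carries an InChI, every property both endpoint attributes plus a
  UCUM unit cargo, every descriptor its application attribute.
* **advanced** ("reproducibility testing") — every model is re-evaluated on
  its stored descriptor data and the recomputed predictions are compared with
  the stored ones.

Each level runs every lower level as well; all problems become findings
(ERROR or WARNING), never exceptions, and the report outcome is *failed* iff
an ERROR is present, *warnings* iff only warnings, else *clean*.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation

from .core import SET_KINDS, Archive, Container, Model, ValuesTable
from .equations import parse_equation, regenerate_predictions
from .errors import CargoParseError, EquationParseError

__all__ = [
    "Finding",
    "ValidationReport",
    "validate",
    "check_basic",
    "check_intermediate",
    "check_advanced",
    "validate_cas",
    "validate_inchi_syntax",
    "stored_value_tolerance",
]

LEVELS = ("basic", "intermediate", "advanced")

_CAS_SHAPE_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")

# Layered InChI grammar: version prefix, non-empty formula layer, then zero or
# more letter-prefixed layers.  Purely syntactic; no chemistry semantics.
_INCHI_RE = re.compile(r"^InChI=1S?/[A-Za-z0-9.]+(/[A-Za-z][^/]*)*$")


def validate_cas(text: str) -> bool:
    """Check a CAS Registry Number: NN...N-NN-N shape plus check digit.

    The check digit is the weighted sum of the preceding digits (weight =
    position counted from the right, starting at 1) modulo 10.
    """
    match = _CAS_SHAPE_RE.match(text)
    if match is None:
        return False
    digits = match.group(1) + match.group(2)
    check = int(match.group(3))
    total = sum(int(d) * w for w, d in enumerate(reversed(digits), start=1))
    return total % 10 == check


def validate_inchi_syntax(text: str) -> bool:
    """True iff *text* matches the layered InChI grammar (syntax only)."""
    return _INCHI_RE.match(text) is not None


def stored_value_tolerance(stored_text: str) -> float:
    """Comparison tolerance for a stored decimal value.

    Stored values carry finite printed precision, so a recomputed value is
    accepted within half a unit in the last decimal place of the stored text,
    with an absolute floor of 1e-8.
    """
    try:
        exponent = Decimal(stored_text).as_tuple().exponent
    except (InvalidOperation, ValueError):
        return 1e-8
    if not isinstance(exponent, int):
        return 1e-8
    return max(0.5 * 10.0 ** exponent, 1e-8)


@dataclass(frozen=True)
class Finding:
    severity: str   # ERROR | WARNING
    level: str      # basic | intermediate | advanced
    check_id: str
    path: str
    message: str

    def to_dict(self) -> dict:
        return {
            "severity": self.severity,
            "level": self.level,
            "check_id": self.check_id,
            "path": self.path,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    target_level: str
    findings: list[Finding]

    @property
    def outcome(self) -> str:
        if any(f.severity == "ERROR" for f in self.findings):
            return "failed"
        if self.findings:
            return "warnings"
        return "clean"

    def to_json(self) -> str:
        return json.dumps(
            {
                "level": self.target_level,
                "outcome": self.outcome,
                "findings": [f.to_dict() for f in self.findings],
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"validation level: {self.target_level}", f"outcome: {self.outcome}"]
        for f in self.findings:
            lines.append(f"{f.severity} [{f.level}/{f.check_id}] {f.path}: {f.message}")
        return "\n".join(lines)


def _sort_findings(archive: Archive, findings: list[Finding]) -> list[Finding]:
    registry_rank = {kind: i for i, kind in enumerate(Archive.REGISTRY_ORDER)}

    def key(f: Finding):
        registry, _, container_id = f.path.partition("/")
        return (registry_rank.get(registry, -1), container_id, f.check_id, f.message)

    return sorted(findings, key=key)


def _values_cargo_table(container: Container) -> ValuesTable | None:
    payload = container.cargos.get("values")
    if payload is None:
        return None
    try:
        return ValuesTable.from_tsv(payload)
    except CargoParseError:
        return None


# ---------------------------------------------------------------------------
# basic level


def check_basic(archive: Archive) -> list[Finding]:
    findings: list[Finding] = []

    def err(check_id, container, message):
        findings.append(Finding("ERROR", "basic", check_id, container.path, message))

    def warn(check_id, container, message):
        findings.append(Finding("WARNING", "basic", check_id, container.path, message))

    for registry in archive.registries():
        for container in registry:
            if container.name is None:
                warn("name-missing", container, "optional attribute 'name' is missing")
            if container.description is None:
                warn("description-missing", container,
                     "optional attribute 'description' is missing")
            if not container.labels:
                warn("labels-missing", container, "optional attribute 'labels' is empty")
            for cargo_name, payload in container.cargos.items():
                if payload is None:
                    err("cargo-missing", container,
                        f"declared cargo {cargo_name!r} has no data entry")

    for compound in archive.compounds:
        if compound.cas is not None:
            if not _CAS_SHAPE_RE.match(compound.cas):
                findings.append(Finding("ERROR", "basic", "cas-format", compound.path,
                                        f"CAS number {compound.cas!r} is malformed"))
            elif not validate_cas(compound.cas):
                findings.append(Finding("ERROR", "basic", "cas-checksum", compound.path,
                                        f"CAS number {compound.cas!r} fails its check digit"))
        if compound.inchi is not None and not validate_inchi_syntax(compound.inchi):
            findings.append(Finding("ERROR", "basic", "inchi-syntax", compound.path,
                                    f"InChI {compound.inchi!r} violates the layer grammar"))

    for registry_kind in ("properties", "descriptors", "predictions"):
        for container in archive.registry(registry_kind):
            if "values" not in container.cargos:
                findings.append(Finding("ERROR", "basic", "values-cargo-missing",
                                        container.path, "no 'values' cargo declared"))
                continue
            payload = container.cargos["values"]
            if payload is None:
                continue  # already reported as cargo-missing
            try:
                table = ValuesTable.from_tsv(payload)
            except CargoParseError as exc:
                findings.append(Finding("ERROR", "basic", "cargo-unparseable",
                                        container.path, f"values cargo: {exc}"))
                continue
            for key in table.keys():
                if key not in archive.compounds:
                    findings.append(Finding(
                        "ERROR", "basic", "weak-ref-unresolved", container.path,
                        f"values key {key!r} does not resolve to a compound"))
            if registry_kind == "descriptors":
                for key, value in table.items():
                    if isinstance(value, str):
                        findings.append(Finding(
                            "ERROR", "basic", "descriptor-value-nonnumeric",
                            container.path,
                            f"value for {key!r} is not a number or N/A: {value!r}"))

    for model in archive.models:
        if model.property_id is None:
            findings.append(Finding("ERROR", "basic", "property-ref-missing", model.path,
                                    "required attribute 'property-ref' is missing"))
        elif model.property_id not in archive.properties:
            findings.append(Finding("ERROR", "basic", "strong-ref-unresolved", model.path,
                                    f"property reference {model.property_id!r} "
                                    "does not resolve"))
        for descriptor_id in model.descriptor_ids:
            if descriptor_id not in archive.descriptors:
                findings.append(Finding("ERROR", "basic", "strong-ref-unresolved",
                                        model.path,
                                        f"descriptor reference {descriptor_id!r} "
                                        "does not resolve"))
        if "equation" not in model.cargos:
            findings.append(Finding("ERROR", "basic", "equation-missing", model.path,
                                    "no mathematical representation ('equation' cargo)"))
        elif model.cargos["equation"] is not None:
            try:
                spec = parse_equation(model.cargos["equation"])
            except EquationParseError as exc:
                findings.append(Finding("ERROR", "basic", "equation-unparseable",
                                        model.path, str(exc)))
            else:
                unknown = sorted(spec.identifiers - set(model.descriptor_ids))
                if unknown:
                    findings.append(Finding(
                        "ERROR", "basic", "equation-identifier-unknown", model.path,
                        f"equation uses non-descriptor identifiers: {', '.join(unknown)}"))

    for prediction in archive.predictions:
        if prediction.model_id is None:
            findings.append(Finding("ERROR", "basic", "model-ref-missing", prediction.path,
                                    "required attribute 'model-ref' is missing"))
        elif prediction.model_id not in archive.models:
            findings.append(Finding("ERROR", "basic", "strong-ref-unresolved",
                                    prediction.path,
                                    f"model reference {prediction.model_id!r} "
                                    "does not resolve"))
        if prediction.set_kind not in SET_KINDS:
            findings.append(Finding("ERROR", "basic", "set-kind-invalid", prediction.path,
                                    f"set kind {prediction.set_kind!r} is not one of "
                                    f"{'/'.join(SET_KINDS)}"))

    return _sort_findings(archive, findings)


# ---------------------------------------------------------------------------
# intermediate level


def check_intermediate(archive: Archive) -> list[Finding]:
    findings: list[Finding] = []
    seen_inchi: dict[str, str] = {}
    for compound in archive.compounds:
        if compound.inchi is None:
            findings.append(Finding("ERROR", "intermediate", "compound-inchi-missing",
                                    compound.path, "compound has no InChI attribute"))
        else:
            if compound.inchi in seen_inchi:
                findings.append(Finding(
                    "WARNING", "intermediate", "inchi-duplicate", compound.path,
                    f"InChI identical to compound {seen_inchi[compound.inchi]!r}"))
            else:
                seen_inchi[compound.inchi] = compound.id
    for prop in archive.properties:
        if prop.endpoint_category is None or prop.endpoint_name is None:
            findings.append(Finding("ERROR", "intermediate", "property-endpoint-missing",
                                    prop.path,
                                    "property lacks endpoint category and/or name"))
        if prop.cargos.get("ucum") is None:
            findings.append(Finding("ERROR", "intermediate", "property-ucum-missing",
                                    prop.path, "property has no UCUM unit cargo"))
    for descriptor in archive.descriptors:
        if descriptor.application is None:
            findings.append(Finding("ERROR", "intermediate",
                                    "descriptor-application-missing", descriptor.path,
                                    "descriptor has no application attribute"))
    return _sort_findings(archive, findings)


# ---------------------------------------------------------------------------
# advanced level


def _model_evaluable(archive: Archive, model: Model) -> bool:
    if model.cargos.get("equation") is None:
        return False
    try:
        spec = parse_equation(model.cargos["equation"])
    except EquationParseError:
        return False
    if not spec.identifiers <= set(model.descriptor_ids):
        return False
    for descriptor_id in model.descriptor_ids:
        descriptor = archive.descriptors.get(descriptor_id)
        if descriptor is None or _values_cargo_table(descriptor) is None:
            return False
    return True


def check_advanced(archive: Archive, tolerance_spec=stored_value_tolerance) -> list[Finding]:
    """Re-evaluate every model's predictions against the stored values.

    ``tolerance_spec`` maps the stored value text to the numeric tolerance
    used for the comparison (default: half a unit in the last printed
    decimal place, floored at 1e-8).  Categorical predictions are compared by
    exact label equality.
    """
    findings: list[Finding] = []
    for model in archive.models:
        if not _model_evaluable(archive, model):
            findings.append(Finding("WARNING", "advanced", "model-skipped", model.path,
                                    "model not re-evaluated: failed basic checks"))
            continue
        recomputed_tables = regenerate_predictions(archive, model)
        for prediction in archive.predictions_of(model):
            stored = _values_cargo_table(prediction)
            recomputed = recomputed_tables.get(prediction.id)
            if stored is None or recomputed is None:
                continue
            for cid in stored.keys():
                stored_value = stored.get(cid)
                if stored_value is None:
                    continue
                new_value = recomputed.get(cid) if cid in recomputed else None
                if new_value is None:
                    findings.append(Finding(
                        "ERROR", "advanced", "descriptor-value-missing", prediction.path,
                        f"compound {cid!r}: descriptor data missing or not evaluable"))
                    continue
                if isinstance(stored_value, float) and isinstance(new_value, float):
                    tolerance = tolerance_spec(stored.raw(cid))
                    if abs(stored_value - new_value) > tolerance * (1 + 1e-9):
                        findings.append(Finding(
                            "ERROR", "advanced", "prediction-mismatch", prediction.path,
                            f"compound {cid!r}: stored {stored.raw(cid)}, "
                            f"recomputed {new_value!r}"))
                elif stored_value != new_value:
                    findings.append(Finding(
                        "ERROR", "advanced", "prediction-mismatch", prediction.path,
                        f"compound {cid!r}: stored {stored_value!r}, "
                        f"recomputed {new_value!r}"))
    return _sort_findings(archive, findings)


def validate(archive: Archive, level: str = "basic",
             tolerance_spec=stored_value_tolerance) -> ValidationReport:
    """Run all checks of *level* and every lower level."""
    if level not in LEVELS:
        raise ValueError(f"unknown validation level {level!r}")
    findings = list(check_basic(archive))
    if level in ("intermediate", "advanced"):
        findings.extend(check_intermediate(archive))
    if level == "advanced":
        findings.extend(check_advanced(archive, tolerance_spec))
    return ValidationReport(target_level=level, findings=findings)
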