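"""Object model for QSAR DataBank (QDB) archives.

A QDB archive is a set of five container registries — compounds, properties,
descriptors, models and predictions — plus archive-level metadata and an
optional bibliography record.  Each container is an identified record that
carries free-text attributes and named byte payloads ("cargos"); tabular
per-compound data lives in a ``values`` cargo, modelled here as
:class:`ValuesTable`.

Two relationship semantics connect containers:

* **strong** — an attribute-level reference (a model's ``property_id``, a
  prediction's ``model_id``) that must resolve to an existing container;
* **weak** — the compound-id keys inside a values cargo, whose resolution
  status is reported by the validator rather than enforced here.
"""

from __future__ import annotations

import copy
import re
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .errors import CargoParseError, DuplicateId, QdbError, UnresolvedReference

__all__ = [
    "TOKEN_RE",
    "MISSING",
    "ValuesTable",
    "BibliographyRecord",
    "Container",
    "Compound",
    "Property",
    "Descriptor",
    "Model",
    "Prediction",
    "Registry",
    "Archive",
    "SET_KINDS",
    "resolve_strong",
    "weak_targets",
    "format_number",
]

# Container ids must be filesystem- and URL-safe tokens.
TOKEN_RE = re.compile(r"^[a-z0-9][a-z0-9-]*$")

#: Literal marker for a missing value in cargo text.
MISSING = "N/A"

SET_KINDS = ("training", "validation", "testing")


def format_number(value: float) -> str:
    """Render a float as shortest round-trip decimal text."""
    if value != value or value in (float("inf"), float("-inf")):
        raise ValueError(f"non-finite value {value!r} cannot be stored")
    return repr(float(value))


class ValuesTable:
    """Ordered mapping compound-id -> value.

    Values are stored as their exact cargo text so that archives round-trip
    byte-identically; a value is either decimal text, a categorical label, or
    the missing marker ``N/A``.  :meth:`get` returns ``float`` for decimal
    text, ``str`` for labels and ``None`` for missing entries.
    """

    def __init__(self, data: Mapping[str, object] | None = None):
        self._data: OrderedDict[str, str] = OrderedDict()
        if data is not None:
            for key, value in data.items():
                self.set(key, value)

    def set(self, compound_id: str, value: object) -> None:
        if not TOKEN_RE.match(compound_id):
            raise ValueError(f"invalid compound id {compound_id!r}")
        if value is None:
            text = MISSING
        elif isinstance(value, str):
            text = value
        elif isinstance(value, (int, float)):
            text = format_number(float(value))
        else:
            raise TypeError(f"unsupported value type {type(value).__name__}")
        self._data[compound_id] = text

    def raw(self, compound_id: str) -> str:
        return self._data[compound_id]

    def get(self, compound_id: str):
        text = self._data[compound_id]
        return self._coerce(text)

    @staticmethod
    def _coerce(text: str):
        if text == MISSING:
            return None
        try:
            return float(text)
        except ValueError:
            return text

    def is_missing(self, compound_id: str) -> bool:
        return self._data[compound_id] == MISSING

    def keys(self):
        return self._data.keys()

    def items(self):
        """Iterate (compound-id, coerced value) pairs in insertion order."""
        for key, text in self._data.items():
            yield key, self._coerce(text)

    def items_raw(self):
        return self._data.items()

    def numeric_items(self):
        """Iterate (id, float) pairs, skipping missing; labels raise."""
        for key, value in self.items():
            if value is None:
                continue
            if isinstance(value, str):
                raise QdbError(f"non-numeric value {value!r} for {key!r}")
            yield key, value

    def is_numeric(self) -> bool:
        return all(not isinstance(v, str) for _, v in self.items())

    def delete(self, compound_id: str) -> None:
        del self._data[compound_id]

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._data

    def __len__(self) -> int:
        return len(self._data)

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ValuesTable):
            return NotImplemented
        return list(self._data.items()) == list(other._data.items())

    def __repr__(self) -> str:
        return f"ValuesTable({dict(self._data)!r})"

    @classmethod
    def from_tsv(cls, payload: bytes) -> "ValuesTable":
        """Parse a two-column TSV cargo (``id\\tvalue``, optional header)."""
        try:
            text = payload.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise CargoParseError(f"values cargo is not UTF-8: {exc}") from exc
        table = cls()
        lines = text.split("\n")
        if lines and lines[-1] == "":
            lines.pop()
        for lineno, line in enumerate(lines, start=1):
            fields = line.split("\t")
            if len(fields) != 2:
                raise CargoParseError(
                    f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            key, value = fields
            if lineno == 1 and (key, value) == ("id", "value"):
                continue
            if key in table._data:
                raise CargoParseError(f"line {lineno}: duplicate compound id {key!r}")
            if not TOKEN_RE.match(key):
                raise CargoParseError(f"line {lineno}: invalid compound id {key!r}")
            table._data[key] = value
        return table

    def to_tsv(self) -> bytes:
        lines = [f"{key}\t{text}" for key, text in self._data.items()]
        return ("\n".join(lines) + "\n" if lines else "").encode("utf-8")


class BibliographyRecord:
    """A single BibTeX-style bibliography entry (entry type + key/value fields).

    Field keys are case-insensitive and stored lowercased.
    """

    def __init__(self, entry_type: str, fields: Mapping[str, str] | None = None,
                 key: str = "ref1"):
        self.entry_type = entry_type
        self.key = key
        self.fields: OrderedDict[str, str] = OrderedDict()
        for name, value in (fields or {}).items():
            lname = name.lower()
            if lname in self.fields:
                raise ValueError(f"duplicate bibliography field {name!r}")
            self.fields[lname] = value

    def __eq__(self, other) -> bool:
        if not isinstance(other, BibliographyRecord):
            return NotImplemented
        return (self.entry_type, self.key, dict(self.fields)) == (
            other.entry_type, other.key, dict(other.fields))

    def __repr__(self) -> str:
        return f"BibliographyRecord({self.entry_type!r}, {dict(self.fields)!r})"

    def to_bibtex(self) -> str:
        body = ",\n".join(f"  {k} = {{{v}}}" for k, v in self.fields.items())
        return f"@{self.entry_type}{{{self.key},\n{body}\n}}\n"

    @classmethod
    def from_bibtex(cls, text: str) -> "BibliographyRecord":
        match = re.match(r"\s*@(\w+)\s*\{\s*([^,\s]+)\s*,(.*)\}\s*$", text, re.S)
        if match is None:
            raise CargoParseError("unparseable bibliography entry")
        entry_type, key, body = match.groups()
        fields = OrderedDict()
        for fmatch in re.finditer(r"(\w+)\s*=\s*\{([^{}]*)\}", body):
            fields[fmatch.group(1).lower()] = fmatch.group(2)
        return cls(entry_type.lower(), fields, key=key)


@dataclass(eq=True)
class Container:
    """Abstract base for the five container kinds.

    ``cargos`` maps cargo name to its byte payload; a ``None`` payload means
    the cargo is *declared* but its data entry is absent — readable archives
    may contain such declarations, and the validator reports them.
    """

    id: str
    name: str | None = None
    description: str | None = None
    labels: list[str] = field(default_factory=list)
    cargos: dict[str, bytes | None] = field(default_factory=dict)

    #: registry name for this container kind; set by subclasses
    KIND = "container"

    def __post_init__(self):
        if not TOKEN_RE.match(self.id):
            raise ValueError(f"invalid container id {self.id!r}")

    @property
    def path(self) -> str:
        return f"{self.KIND}/{self.id}"

    def set_values(self, table: ValuesTable) -> None:
        self.cargos["values"] = table.to_tsv()

    def values_table(self) -> ValuesTable:
        payload = self.cargos.get("values")
        if payload is None:
            raise CargoParseError(f"{self.path}: no values cargo payload")
        return ValuesTable.from_tsv(payload)


@dataclass(eq=True)
class Compound(Container):
    cas: str | None = None
    inchi: str | None = None

    KIND = "compounds"


@dataclass(eq=True)
class Property(Container):
    endpoint_category: str | None = None
    endpoint_name: str | None = None

    KIND = "properties"


@dataclass(eq=True)
class Descriptor(Container):
    application: str | None = None

    KIND = "descriptors"


@dataclass(eq=True)
class Model(Container):
    property_id: str | None = None
    descriptor_ids: list[str] = field(default_factory=list)

    KIND = "models"


@dataclass(eq=True)
class Prediction(Container):
    model_id: str | None = None
    set_kind: str | None = None
    application: str | None = None

    KIND = "predictions"


class Registry:
    """Insertion-ordered collection of containers with unique ids."""

    def __init__(self, kind: str):
        self.kind = kind
        self._items: OrderedDict[str, Container] = OrderedDict()

    def add(self, container: Container) -> Container:
        if container.id in self._items:
            raise DuplicateId(f"{self.kind}: duplicate id {container.id!r}")
        self._items[container.id] = container
        return container

    def get(self, container_id: str) -> Container | None:
        return self._items.get(container_id)

    def ids(self):
        return list(self._items.keys())

    def index(self, container_id: str) -> int:
        return list(self._items.keys()).index(container_id)

    def __getitem__(self, container_id: str) -> Container:
        return self._items[container_id]

    def __contains__(self, container_id: str) -> bool:
        return container_id in self._items

    def __iter__(self):
        return iter(self._items.values())

    def __len__(self) -> int:
        return len(self._items)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Registry):
            return NotImplemented
        return self.kind == other.kind and list(self._items.items()) == list(
            other._items.items())

    def __repr__(self) -> str:
        return f"Registry({self.kind!r}, n={len(self)})"


class Archive:
    """Root QDB archive object: five registries plus archive metadata."""

    REGISTRY_ORDER = ("compounds", "properties", "descriptors", "models", "predictions")

    def __init__(self, name: str | None = None, description: str | None = None):
        self.name = name
        self.description = description
        self.compounds = Registry("compounds")
        self.properties = Registry("properties")
        self.descriptors = Registry("descriptors")
        self.models = Registry("models")
        self.predictions = Registry("predictions")
        self.bibliography: BibliographyRecord | None = None

    def registry(self, kind: str) -> Registry:
        if kind not in self.REGISTRY_ORDER:
            raise KeyError(f"unknown registry {kind!r}")
        return getattr(self, kind)

    def registries(self):
        for kind in self.REGISTRY_ORDER:
            yield self.registry(kind)

    def copy(self) -> "Archive":
        return copy.deepcopy(self)

    def predictions_of(self, model: Model) -> list[Prediction]:
        return [p for p in self.predictions if p.model_id == model.id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Archive):
            return NotImplemented
        return (
            self.name == other.name
            and self.description == other.description
            and all(self.registry(k) == other.registry(k) for k in self.REGISTRY_ORDER)
            and self.bibliography == other.bibliography
        )

    def __repr__(self) -> str:
        sizes = ", ".join(f"{k}={len(self.registry(k))}" for k in self.REGISTRY_ORDER)
        return f"Archive({self.name!r}, {sizes})"


def resolve_strong(archive: Archive, kind: str, container_id: str,
                   referrer: str | None = None) -> Container:
    """Resolve a strong reference or raise :class:`UnresolvedReference`."""
    registry = archive.registry(kind)
    container = registry.get(container_id)
    if container is None:
        raise UnresolvedReference(kind, container_id, referrer)
    return container


def weak_targets(table: ValuesTable, archive: Archive) -> list[tuple[str, bool]]:
    """Resolution status of every compound-id key in a values table.

    Weak references are data, not constraints: unresolved keys are reported,
    not raised, and it is the validator's job to judge them.
    """
    return [(key, key in archive.compounds) for key in table.keys()]
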