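"""Reading and writing QDB archives.

On disk an archive is a ZIP container (or an unpacked directory with the same
layout) holding:

* ``archive.xml`` — archive-level name/description;
* one registry XML per container kind, e.g. ``compounds/compounds.xml``;
* cargo payloads at ``<registry>/<container-id>/<cargo-name>``;
* optionally ``bibliography.bib`` at the root.

The reader is deliberately lenient — a declared cargo whose data entry is
absent loads with a ``None`` payload, and it is the validator that reports it.
Writing is byte-deterministic: fixed entry order, fixed epoch timestamps and
stored (uncompressed) entries, so identical archives produce identical ZIPs.
"""

from __future__ import annotations

import io as _stdio
import json
import os
import xml.etree.ElementTree as ET
import zipfile
from pathlib import Path

import numpy as np

from . import ad as _ad
from .core import (
    Archive,
    BibliographyRecord,
    Compound,
    Container,
    Descriptor,
    Model,
    Prediction,
    Property,
    Registry,
    ValuesTable,
)
from .errors import CargoParseError, FormatError, InsufficientTraining, MissingRegistry, QdbError

__all__ = ["read_archive", "write_archive", "parse_values", "normalize_internal"]

_REGISTRY_CLASSES = {
    "compounds": Compound,
    "properties": Property,
    "descriptors": Descriptor,
    "models": Model,
    "predictions": Prediction,
}

# Fixed DOS timestamp for reproducible ZIP bytes.
_EPOCH = (1980, 1, 1, 0, 0, 0)


def parse_values(payload: bytes) -> ValuesTable:
    """Parse a two-column TSV values cargo into a :class:`ValuesTable`."""
    return ValuesTable.from_tsv(payload)


# ---------------------------------------------------------------------------
# XML serialization


def _set_text_child(parent: ET.Element, tag: str, text: str | None) -> None:
    if text is not None:
        child = ET.SubElement(parent, tag)
        child.text = text


def _container_to_xml(container: Container) -> ET.Element:
    elem = ET.Element("container", {"id": container.id})
    _set_text_child(elem, "name", container.name)
    _set_text_child(elem, "description", container.description)
    if container.labels:
        labels = ET.SubElement(elem, "labels")
        for label in container.labels:
            _set_text_child(labels, "label", label)
    if isinstance(container, Compound):
        _set_text_child(elem, "cas", container.cas)
        _set_text_child(elem, "inchi", container.inchi)
    elif isinstance(container, Property):
        if container.endpoint_category is not None or container.endpoint_name is not None:
            attrs = {}
            if container.endpoint_category is not None:
                attrs["category"] = container.endpoint_category
            if container.endpoint_name is not None:
                attrs["name"] = container.endpoint_name
            ET.SubElement(elem, "endpoint", attrs)
    elif isinstance(container, Descriptor):
        _set_text_child(elem, "application", container.application)
    elif isinstance(container, Model):
        _set_text_child(elem, "property-ref", container.property_id)
        for descriptor_id in container.descriptor_ids:
            _set_text_child(elem, "descriptor-ref", descriptor_id)
    elif isinstance(container, Prediction):
        _set_text_child(elem, "model-ref", container.model_id)
        _set_text_child(elem, "set-kind", container.set_kind)
        _set_text_child(elem, "application", container.application)
    for cargo_name in container.cargos:
        ET.SubElement(elem, "cargo", {"name": cargo_name})
    return elem


def _container_from_xml(kind: str, elem: ET.Element) -> Container:
    cls = _REGISTRY_CLASSES[kind]
    container_id = elem.get("id")
    if not container_id:
        raise FormatError(f"{kind}: container element without id")
    kwargs = {"id": container_id}
    name = elem.find("name")
    if name is not None:
        kwargs["name"] = name.text or ""
    description = elem.find("description")
    if description is not None:
        kwargs["description"] = description.text or ""
    labels = elem.find("labels")
    if labels is not None:
        kwargs["labels"] = [lab.text or "" for lab in labels.findall("label")]
    if cls is Compound:
        for tag, attr in (("cas", "cas"), ("inchi", "inchi")):
            child = elem.find(tag)
            if child is not None:
                kwargs[attr] = child.text or ""
    elif cls is Property:
        endpoint = elem.find("endpoint")
        if endpoint is not None:
            kwargs["endpoint_category"] = endpoint.get("category")
            kwargs["endpoint_name"] = endpoint.get("name")
    elif cls is Descriptor:
        app = elem.find("application")
        if app is not None:
            kwargs["application"] = app.text or ""
    elif cls is Model:
        pref = elem.find("property-ref")
        if pref is not None:
            kwargs["property_id"] = pref.text or ""
        kwargs["descriptor_ids"] = [d.text or "" for d in elem.findall("descriptor-ref")]
    elif cls is Prediction:
        mref = elem.find("model-ref")
        if mref is not None:
            kwargs["model_id"] = mref.text or ""
        set_kind = elem.find("set-kind")
        if set_kind is not None:
            kwargs["set_kind"] = set_kind.text or ""
        app = elem.find("application")
        if app is not None:
            kwargs["application"] = app.text or ""
    try:
        container = cls(**kwargs)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc
    for cargo in elem.findall("cargo"):
        cargo_name = cargo.get("name")
        if not cargo_name:
            raise FormatError(f"{kind}/{container_id}: cargo element without name")
        if cargo_name in container.cargos:
            raise FormatError(f"{kind}/{container_id}: duplicate cargo {cargo_name!r}")
        container.cargos[cargo_name] = None  # payload attached later
    return container


def _xml_bytes(root: ET.Element) -> bytes:
    ET.indent(root)
    return b'<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(root, encoding="utf-8",
                                                                     xml_declaration=False) + b"\n"


# ---------------------------------------------------------------------------
# Entry-map layer: both ZIP and directory inputs are reduced to a path->bytes map


def _collect_entries(source) -> dict[str, bytes]:
    if isinstance(source, (str, os.PathLike)) and Path(source).is_dir():
        root = Path(source)
        return {
            str(p.relative_to(root)).replace(os.sep, "/"): p.read_bytes()
            for p in sorted(root.rglob("*"))
            if p.is_file()
        }
    try:
        with zipfile.ZipFile(source) as zf:
            return {info.filename: zf.read(info) for info in zf.infolist()
                    if not info.is_dir()}
    except zipfile.BadZipFile as exc:
        raise FormatError(f"not a ZIP container: {exc}") from exc


def read_archive(source) -> Archive:
    """Load an archive from a ``.qdb`` ZIP, a readable stream, or a directory."""
    entries = _collect_entries(source)
    if "archive.xml" not in entries:
        raise MissingRegistry("archive.xml not found")
    try:
        root = ET.fromstring(entries["archive.xml"])
    except ET.ParseError as exc:
        raise FormatError(f"archive.xml: {exc}") from exc
    name = root.find("name")
    description = root.find("description")
    archive = Archive(
        name=name.text if name is not None else None,
        description=description.text if description is not None else None,
    )
    for kind in Archive.REGISTRY_ORDER:
        registry_path = f"{kind}/{kind}.xml"
        if registry_path not in entries:
            continue
        try:
            registry_root = ET.fromstring(entries[registry_path])
        except ET.ParseError as exc:
            raise FormatError(f"{registry_path}: {exc}") from exc
        registry: Registry = archive.registry(kind)
        for elem in registry_root.findall("container"):
            container = _container_from_xml(kind, elem)
            for cargo_name in container.cargos:
                entry = f"{kind}/{container.id}/{cargo_name}"
                if entry in entries:
                    container.cargos[cargo_name] = entries[entry]
            registry.add(container)
    if "bibliography.bib" in entries:
        try:
            archive.bibliography = BibliographyRecord.from_bibtex(
                entries["bibliography.bib"].decode("utf-8"))
        except (CargoParseError, UnicodeDecodeError) as exc:
            raise FormatError(f"bibliography.bib: {exc}") from exc
    return archive


def _archive_entries(archive: Archive) -> list[tuple[str, bytes]]:
    root = ET.Element("archive")
    _set_text_child(root, "name", archive.name)
    _set_text_child(root, "description", archive.description)
    entries: list[tuple[str, bytes]] = [("archive.xml", _xml_bytes(root))]
    cargo_entries: list[tuple[str, bytes]] = []
    for kind in Archive.REGISTRY_ORDER:
        registry = archive.registry(kind)
        registry_root = ET.Element(kind)
        for container in registry:
            registry_root.append(_container_to_xml(container))
            for cargo_name, payload in container.cargos.items():
                if payload is not None:
                    cargo_entries.append((f"{kind}/{container.id}/{cargo_name}", payload))
        entries.append((f"{kind}/{kind}.xml", _xml_bytes(registry_root)))
    cargo_entries.sort(key=lambda item: item[0])
    entries.extend(cargo_entries)
    if archive.bibliography is not None:
        entries.append(("bibliography.bib", archive.bibliography.to_bibtex().encode("utf-8")))
    return entries


def write_archive(archive: Archive, target) -> None:
    """Write an archive as a deterministic ZIP (path or writable stream)."""
    buffer = _stdio.BytesIO()
    with zipfile.ZipFile(buffer, "w", compression=zipfile.ZIP_STORED) as zf:
        for entry_name, payload in _archive_entries(archive):
            info = zipfile.ZipInfo(entry_name, date_time=_EPOCH)
            info.external_attr = 0o644 << 16
            zf.writestr(info, payload)
    data = buffer.getvalue()
    if isinstance(target, (str, os.PathLike)):
        Path(target).write_bytes(data)
    else:
        target.write(data)


# ---------------------------------------------------------------------------
# Internal (repository-optimized) variant


def normalize_internal(archive: Archive) -> Archive:
    """Produce the normalized "internal" variant of an archive.

    The original is left untouched; the returned copy has every values cargo
    re-serialized canonically (keys in compound-registry order, value text
    verbatim) and, for each model whose applicability-domain parameters can be
    estimated, a ``derived`` cargo holding those precomputed parameters as
    JSON.  Evaluation problems never abort normalization — affected models
    simply get no derived cargo.
    """
    internal = archive.copy()
    compound_order = {cid: i for i, cid in enumerate(internal.compounds.ids())}
    for registry in internal.registries():
        for container in registry:
            payload = container.cargos.get("values")
            if payload is None:
                continue
            try:
                table = ValuesTable.from_tsv(payload)
            except CargoParseError:
                continue
            canonical = ValuesTable()
            ordered = sorted(
                table.items_raw(),
                key=lambda kv: compound_order.get(kv[0], len(compound_order)),
            )
            for key, text in ordered:
                canonical._data[key] = text
            container.cargos["values"] = canonical.to_tsv()
    for model in internal.models:
        try:
            params = _ad.fit_ad(internal, model)
        except (QdbError, InsufficientTraining):
            model.cargos.pop("derived", None)
            continue
        derived = {
            "descriptor_ids": list(params.descriptor_ids),
            "training_compounds": list(params.compound_ids),
            "training_matrix_shape": [int(params.training_matrix.shape[0]),
                                      int(params.training_matrix.shape[1])],
            "centroid": [float(v) for v in params.centroid],
            "covariance": np.asarray(params.covariance).tolist(),
            "xtx_inverse": np.asarray(params.xtx_inverse).tolist(),
            "warning_leverage": float(params.warning_leverage),
            "training_rmse": None if params.training_rmse is None
            else float(params.training_rmse),
            "singular": bool(params.singular),
        }
        model.cargos["derived"] = (
            json.dumps(derived, sort_keys=True, separators=(",", ":")) + "\n"
        ).encode("utf-8")
    return internal
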