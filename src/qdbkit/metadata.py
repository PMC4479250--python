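"""Harvesting archive-level metadata.

Mirrors the repository's metadata-extraction step: the record is populated
purely from what the archive already contains (registries, equation headers,
application attributes, the optional bibliography entry), so submitters never
re-type what the archive can answer itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Archive, BibliographyRecord
from .equations import parse_equation
from .errors import EquationParseError

__all__ = ["MetadataRecord", "harvest_metadata"]


@dataclass
class MetadataRecord:
    endpoint: str | None
    model_types: list[str]
    software: list[str]
    n_compounds: int
    n_properties: int
    n_descriptors: int
    n_models: int
    n_predictions: int
    bibliography: BibliographyRecord | None = None

    def to_dict(self) -> dict:
        record = {
            "endpoint": self.endpoint,
            "model_types": self.model_types,
            "software": self.software,
            "counts": {
                "compounds": self.n_compounds,
                "properties": self.n_properties,
                "descriptors": self.n_descriptors,
                "models": self.n_models,
                "predictions": self.n_predictions,
            },
        }
        if self.bibliography is not None:
            record["bibliography"] = {
                "entry_type": self.bibliography.entry_type,
                **dict(self.bibliography.fields),
            }
        return record


def harvest_metadata(archive: Archive) -> MetadataRecord:
    """Populate a :class:`MetadataRecord` from archive content alone."""
    endpoint = None
    for prop in archive.properties:
        if prop.endpoint_name is not None:
            endpoint = prop.endpoint_name
            break
        if endpoint is None and prop.name is not None:
            endpoint = prop.name
    model_types: list[str] = []
    for model in archive.models:
        payload = model.cargos.get("equation")
        if payload is None:
            continue
        try:
            spec = parse_equation(payload)
        except EquationParseError:
            continue
        if spec.model_type not in model_types:
            model_types.append(spec.model_type)
    software: set[str] = set()
    for descriptor in archive.descriptors:
        if descriptor.application is not None:
            software.add(descriptor.application)
    for prediction in archive.predictions:
        if prediction.application is not None:
            software.add(prediction.application)
    return MetadataRecord(
        endpoint=endpoint,
        model_types=model_types,
        software=sorted(software),
        n_compounds=len(archive.compounds),
        n_properties=len(archive.properties),
        n_descriptors=len(archive.descriptors),
        n_models=len(archive.models),
        n_predictions=len(archive.predictions),
        bibliography=archive.bibliography,
    )
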