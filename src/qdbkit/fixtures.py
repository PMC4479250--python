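"""Deterministic synthetic QDB archives.

The generator builds archives with a known ground truth — descriptor values
drawn from stated normal distributions, an experimental property that is a
linear function of the descriptors plus Gaussian noise, and a model whose
equation cargo encodes the exact generating coefficients.  Stored predictions
are computed by that same equation from the stored descriptor values, so a
defect-free archive is reproducible by construction and passes advanced
validation cleanly.  Named defects can then be injected to break exactly one
validation level at a time.

Randomness comes from a self-contained splitmix64 generator with Box-Muller
normal variates, so a given seed yields byte-identical archives on every
platform and in any reimplementation that follows the same recipe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import (
    Archive,
    BibliographyRecord,
    Compound,
    Descriptor,
    Model,
    Prediction,
    Property,
    ValuesTable,
    format_number,
)
from .equations import evaluate, parse_equation
from .errors import SpecError

__all__ = ["SplitMix64", "FixtureSpec", "DEFECT_LEVEL", "generate",
           "parameter_recovery_check"]

_MASK = (1 << 64) - 1


class SplitMix64:
    """64-bit splitmix PRNG with Box-Muller normals (portable, seedable)."""

    def __init__(self, seed: int):
        self.state = seed & _MASK
        self._spare: float | None = None

    def next_u64(self) -> int:
        self.state = (self.state + 0x9E3779B97F4A7C15) & _MASK
        z = self.state
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
        return (z ^ (z >> 31)) & _MASK

    def uniform(self) -> float:
        """Uniform in [0, 1) with 53 random bits."""
        return (self.next_u64() >> 11) * (2.0 ** -53)

    def randint(self, n: int) -> int:
        """Uniform integer in [0, n) (via the 53-bit uniform; n is tiny here)."""
        return int(self.uniform() * n)

    def normal(self, mean: float = 0.0, sd: float = 1.0) -> float:
        if self._spare is not None:
            z = self._spare
            self._spare = None
        else:
            u1 = ((self.next_u64() >> 11) + 1) * (2.0 ** -53)  # (0, 1]
            u2 = self.uniform()
            r = math.sqrt(-2.0 * math.log(u1))
            z = r * math.cos(2.0 * math.pi * u2)
            self._spare = r * math.sin(2.0 * math.pi * u2)
        return mean + sd * z

    def shuffle(self, items: list) -> list:
        for i in range(len(items) - 1, 0, -1):
            j = self.randint(i + 1)
            items[i], items[j] = items[j], items[i]
        return items


# Genuine simple-molecule InChIs; beyond the pool, unique formula-only
# n-alkane InChIs keep every compound's identifier distinct and syntax-valid.
_INCHI_POOL = [
    ("water", "InChI=1S/H2O/h1H2"),
    ("methane", "InChI=1S/CH4/h1H4"),
    ("ammonia", "InChI=1S/H3N/h1H3"),
    ("methanol", "InChI=1S/CH4O/c1-2/h2H,1H3"),
    ("ethanol", "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3"),
    ("ethane", "InChI=1S/C2H6/c1-2/h1-2H3"),
    ("benzene", "InChI=1S/C6H6/c1-2-4-6-5-3-1/h1-6H"),
    ("formaldehyde", "InChI=1S/CH2O/c1-2/h1H2"),
]

DEFECT_LEVEL = {
    "bad-cas": "basic",
    "orphan-cargo": "basic",
    "dangling-weak-ref": "basic",
    "drop-inchi": "intermediate",
    "drop-application": "intermediate",
    "drop-ucum": "intermediate",
    "drop-endpoint": "intermediate",
    "tamper-prediction": "advanced",
    "drop-name": None,  # warning only; no level fails
}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic archive."""

    n_compounds: int = 32
    descriptor_defs: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("logp", 1.5, 1.0), ("mw", 150.0, 40.0)])
    coefficients: list[float] = field(default_factory=lambda: [0.8, 0.55, -0.01])
    noise_sd: float = 0.25
    split: tuple[float, float, float] = (0.7, 0.15, 0.15)
    model_type: str = "regression"
    cut_points: list[float] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    seed: int = 42
    defects: list[str] = field(default_factory=list)

    def check(self) -> None:
        if self.n_compounds < 4:
            raise SpecError("n_compounds must be >= 4")
        if not self.descriptor_defs:
            raise SpecError("at least one descriptor required")
        if len(self.coefficients) != len(self.descriptor_defs) + 1:
            raise SpecError("coefficients must be intercept + one weight per descriptor")
        if any(f < 0 or f > 1 for f in self.split) or abs(sum(self.split) - 1) > 1e-9:
            raise SpecError("split fractions must lie in [0,1] and sum to 1")
        if self.model_type not in ("regression", "classification"):
            raise SpecError(f"unknown model type {self.model_type!r}")
        if self.model_type == "classification":
            if not self.cut_points or len(self.labels) != len(self.cut_points) + 1:
                raise SpecError("classification needs cut points and len(cuts)+1 labels")
        unknown = set(self.defects) - set(DEFECT_LEVEL)
        if unknown:
            raise SpecError(f"unknown defect tokens: {sorted(unknown)}")


def _make_cas(rng: SplitMix64) -> str:
    body = "".join(str(rng.randint(10)) for _ in range(7))
    segment1, segment2 = body[:5], body[5:7]
    digits = segment1 + segment2
    check = sum(int(d) * w for w, d in enumerate(reversed(digits), start=1)) % 10
    return f"{segment1}-{segment2}-{check}"


def _inchi_for(index: int) -> tuple[str, str]:
    if index < len(_INCHI_POOL):
        return _INCHI_POOL[index]
    carbons = index + 2
    return (f"alkane-C{carbons}", f"InChI=1S/C{carbons}H{2 * carbons + 2}")


def _split_counts(spec: FixtureSpec) -> tuple[int, int, int]:
    n = spec.n_compounds
    n_train = max(2, round(spec.split[0] * n))
    n_valid = round(spec.split[1] * n)
    n_valid = min(n_valid, n - n_train)
    n_test = n - n_train - n_valid
    return n_train, n_valid, n_test


def _equation_text(spec: FixtureSpec) -> str:
    terms = [format_number(spec.coefficients[0])]
    for (descriptor_id, _, _), weight in zip(spec.descriptor_defs, spec.coefficients[1:]):
        terms.append(f"{format_number(weight)}*{descriptor_id}")
    expression = " + ".join(terms)
    if spec.model_type == "classification":
        cuts = ",".join(format_number(c) for c in spec.cut_points)
        labels = ",".join(spec.labels)
        header = f"type=classification; cuts={cuts}; labels={labels}"
    else:
        header = "type=regression"
    return f"{header}\n{expression}\n"


def generate(spec: FixtureSpec) -> Archive:
    """Build one synthetic archive from a :class:`FixtureSpec`."""
    spec.check()
    rng = SplitMix64(spec.seed)
    archive = Archive(
        name=f"synthetic-qdb-{spec.seed}",
        description="Synthetic QSAR archive with a known linear ground truth.",
    )
    archive.bibliography = BibliographyRecord("article", {
        "author": "Synthetic, A. and Fixture, B.",
        "title": f"A synthetic linear structure-activity dataset (seed {spec.seed})",
        "journal": "Journal of Synthetic Benchmarks",
        "year": "2016",
        "doi": f"10.0000/synthetic.{spec.seed}",
    })

    compound_ids = []
    for i in range(spec.n_compounds):
        molecule, inchi = _inchi_for(i)
        compound = Compound(
            id=f"c{i + 1}",
            name=f"Compound {i + 1} ({molecule})",
            description=f"Synthetic dataset member #{i + 1}",
            labels=["synthetic"],
            cas=_make_cas(rng),
            inchi=inchi,
        )
        compound.cargos["smiles"] = f"C{'C' * (i % 5)}\n".encode("utf-8")
        archive.compounds.add(compound)
        compound_ids.append(compound.id)

    # Descriptor values: independent normals, stored as shortest-repr text;
    # everything downstream (property, predictions) uses the *stored* values.
    descriptor_values: dict[str, dict[str, float]] = {}
    for descriptor_id, mean, sd in spec.descriptor_defs:
        table = ValuesTable()
        for cid in compound_ids:
            table.set(cid, rng.normal(mean, sd))
        descriptor = Descriptor(
            id=descriptor_id,
            name=f"Descriptor {descriptor_id}",
            description=f"Synthetic normal descriptor ({mean}, {sd})",
            labels=["synthetic"],
            application="mock/1.0",
        )
        descriptor.set_values(table)
        archive.descriptors.add(descriptor)
        descriptor_values[descriptor_id] = {cid: table.get(cid) for cid in compound_ids}

    latent = {}
    for cid in compound_ids:
        y = spec.coefficients[0]
        for (descriptor_id, _, _), weight in zip(spec.descriptor_defs,
                                                 spec.coefficients[1:]):
            y += weight * descriptor_values[descriptor_id][cid]
        latent[cid] = y

    prop = Property(
        id="activity",
        name="Toxic potency",
        description="Synthetic endpoint generated from the descriptors",
        labels=["synthetic"],
        endpoint_category="TOX",
        endpoint_name="pIGC50",
    )
    prop.cargos["ucum"] = b"-lg(mol/L)\n"
    experimental = ValuesTable()
    for cid in compound_ids:
        noisy = latent[cid] + rng.normal(0.0, spec.noise_sd)
        if spec.model_type == "classification":
            label = spec.labels[-1]
            for cut, lab in zip(spec.cut_points, spec.labels):
                if noisy <= cut:
                    label = lab
                    break
            experimental.set(cid, label)
        else:
            experimental.set(cid, noisy)
    prop.set_values(experimental)
    archive.properties.add(prop)

    model = Model(
        id="model1",
        name="Synthetic linear model",
        description="Linear model over the synthetic descriptors",
        labels=["synthetic"],
        property_id="activity",
        descriptor_ids=[d for d, _, _ in spec.descriptor_defs],
    )
    model.cargos["equation"] = _equation_text(spec).encode("utf-8")
    archive.models.add(model)

    equation_spec = parse_equation(model.cargos["equation"])
    n_train, n_valid, n_test = _split_counts(spec)
    shuffled = rng.shuffle(list(compound_ids))
    assignments = {
        "training": sorted(shuffled[:n_train], key=compound_ids.index),
        "validation": sorted(shuffled[n_train:n_train + n_valid], key=compound_ids.index),
        "testing": sorted(shuffled[n_train + n_valid:], key=compound_ids.index),
    }
    for set_kind in ("training", "validation", "testing"):
        members = assignments[set_kind]
        if not members:
            continue
        table = ValuesTable()
        for cid in members:
            bindings = {d: descriptor_values[d][cid] for d in model.descriptor_ids}
            table.set(cid, evaluate(equation_spec, bindings))
        prediction = Prediction(
            id=set_kind,
            name=f"{set_kind.capitalize()} set",
            description=f"Model predictions for the {set_kind} set",
            labels=["synthetic"],
            model_id=model.id,
            set_kind=set_kind,
            application="qdbkit/0.1",
        )
        prediction.set_values(table)
        archive.predictions.add(prediction)

    for defect in spec.defects:
        _apply_defect(archive, defect)
    return archive


def _apply_defect(archive: Archive, defect: str) -> None:
    first_compound = next(iter(archive.compounds))
    if defect == "drop-name":
        first_compound.name = None
    elif defect == "drop-inchi":
        first_compound.inchi = None
    elif defect == "bad-cas":
        cas = first_compound.cas
        head, check = cas[:-1], int(cas[-1])
        first_compound.cas = head + str((check + 1) % 10)
    elif defect == "orphan-cargo":
        first_compound.cargos["extra"] = None  # declared, no data entry
    elif defect == "dangling-weak-ref":
        prediction = archive.predictions["training"]
        table = prediction.values_table()
        table.set("zz-missing", 1.0)
        prediction.set_values(table)
    elif defect == "drop-application":
        next(iter(archive.descriptors)).application = None
    elif defect == "drop-ucum":
        archive.properties["activity"].cargos.pop("ucum", None)
    elif defect == "drop-endpoint":
        archive.properties["activity"].endpoint_name = None
    elif defect == "tamper-prediction":
        prediction = archive.predictions["training"]
        table = prediction.values_table()
        first = next(iter(table.keys()))
        value = table.get(first)
        if isinstance(value, str):
            table.set(first, value + "-flipped")
        else:
            table.set(first, value + 1.0)
        prediction.set_values(table)
    else:
        raise SpecError(f"unknown defect token {defect!r}")


def parameter_recovery_check(spec: FixtureSpec, fitted_coefficients) -> dict:
    """Compare externally fitted OLS coefficients with the generating truth.

    ``fitted_coefficients`` is intercept-first, matching
    ``FixtureSpec.coefficients``.  The report flags saturated designs
    (training size <= number of coefficients) where recovery is exact
    interpolation rather than estimation.
    """
    spec.check()
    if spec.model_type != "regression":
        raise SpecError("parameter recovery applies to regression fixtures only")
    fitted = [float(c) for c in fitted_coefficients]
    if len(fitted) != len(spec.coefficients):
        raise SpecError(
            f"expected {len(spec.coefficients)} coefficients, got {len(fitted)}")
    n_train, _, _ = _split_counts(spec)
    d = len(spec.descriptor_defs)
    errors = [abs(f - t) for f, t in zip(fitted, spec.coefficients)]
    return {
        "true_coefficients": list(spec.coefficients),
        "fitted_coefficients": fitted,
        "abs_errors": errors,
        "max_abs_error": max(errors),
        "n_training": n_train,
        "n_descriptors": d,
        "saturated": n_train <= d + 1,
    }
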