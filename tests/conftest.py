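import numpy as np
import pytest

from qdbkit import (
    Archive,
    Compound,
    Descriptor,
    FixtureSpec,
    Model,
    Prediction,
    Property,
    ValuesTable,
    generate,
)


@pytest.fixture
def archive():
    """Defect-free regression fixture archive."""
    return generate(FixtureSpec(seed=7))


@pytest.fixture
def classification_archive():
    return generate(FixtureSpec(
        seed=11,
        model_type="classification",
        cut_points=[1.0],
        labels=["inactive", "active"],
    ))


def random_spec(rng: np.random.Generator, defects=()) -> FixtureSpec:
    """Small random fixture recipe used by round-trip/monotonicity suites."""
    n_descriptors = int(rng.integers(1, 4))
    descriptor_defs = [
        (f"d{i + 1}", float(rng.normal(0, 2)), float(rng.uniform(0.5, 2)))
        for i in range(n_descriptors)
    ]
    return FixtureSpec(
        n_compounds=int(rng.integers(8, 24)),
        descriptor_defs=descriptor_defs,
        coefficients=[float(rng.normal(0, 1)) for _ in range(n_descriptors + 1)],
        noise_sd=float(rng.uniform(0, 0.5)),
        seed=int(rng.integers(0, 2**31)),
        defects=list(defects),
    )


def archive_from_matrix(X: np.ndarray, y: np.ndarray | None = None,
                        weights: np.ndarray | None = None) -> Archive:
    """Minimal archive around a given training design matrix.

    All compounds form the training set; the model equation is linear with
    the given weights (default: all-ones with zero intercept) and stored
    predictions are computed from it.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    weights = np.ones(d) if weights is None else np.asarray(weights, dtype=float)
    archive = Archive(name="toy")
    compound_ids = [f"c{i + 1}" for i in range(n)]
    for cid in compound_ids:
        archive.compounds.add(Compound(id=cid, name=cid, inchi="InChI=1S/H2O/h1H2"))
    descriptor_ids = [f"x{j + 1}" for j in range(d)]
    for j, did in enumerate(descriptor_ids):
        descriptor = Descriptor(id=did, name=did, application="mock/1.0")
        descriptor.set_values(ValuesTable({cid: X[i, j]
                                           for i, cid in enumerate(compound_ids)}))
        archive.descriptors.add(descriptor)
    prop = Property(id="y", name="y", endpoint_category="TOX", endpoint_name="y")
    prop.cargos["ucum"] = b"1\n"
    yhat = X @ weights
    y = yhat if y is None else np.asarray(y, dtype=float)
    prop.set_values(ValuesTable({cid: float(y[i]) for i, cid in enumerate(compound_ids)}))
    archive.properties.add(prop)
    expression = " + ".join(f"{float(w)!r}*{did}"
                            for w, did in zip(weights, descriptor_ids))
    model = Model(id="m", name="m", property_id="y", descriptor_ids=descriptor_ids)
    model.cargos["equation"] = f"type=regression\n{expression}\n".encode()
    archive.models.add(model)
    prediction = Prediction(id="training", name="training", model_id="m",
                            set_kind="training", application="qdbkit/0.1")
    prediction.set_values(ValuesTable({cid: float(yhat[i])
                                       for i, cid in enumerate(compound_ids)}))
    archive.predictions.add(prediction)
    return archive
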