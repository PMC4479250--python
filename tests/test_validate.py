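import string

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qdbkit import FixtureSpec, generate, validate, validate_cas, validate_inchi_syntax
from qdbkit.fixtures import DEFECT_LEVEL
from qdbkit.validate import Finding, ValidationReport, stored_value_tolerance

from conftest import random_spec


# --- independent oracles -----------------------------------------------------


def cas_oracle(text: str) -> bool:
    """Brute-force CAS check: explicit shape walk plus digit-weight sum."""
    parts = text.split("-")
    if len(parts) != 3:
        return False
    a, b, c = parts
    if not (a.isdigit() and b.isdigit() and c.isdigit()):
        return False
    if not (2 <= len(a) <= 7 and len(b) == 2 and len(c) == 1):
        return False
    digits = list(a + b)
    total = 0
    position = 1
    while digits:
        total += position * int(digits.pop())
        position += 1
    return total % 10 == int(c)


def inchi_oracle(text: str) -> bool:
    """Layer-by-layer InChI grammar walk, written without regular expressions."""
    for prefix in ("InChI=1S/", "InChI=1/"):
        if text.startswith(prefix):
            rest = text[len(prefix):]
            break
    else:
        return False
    layers = rest.split("/")
    formula = layers[0]
    if not formula or any(ch not in string.ascii_letters + string.digits + "."
                          for ch in formula):
        return False
    for layer in layers[1:]:
        if not layer or layer[0] not in string.ascii_letters:
            return False
        if "/" in layer:
            return False
    return True


# --- identifier checks -------------------------------------------------------


def test_cas_known_examples():
    assert validate_cas("7732-18-5")      # water
    assert not validate_cas("7732-18-4")  # wrong check digit
    assert not validate_cas("7732185")


def test_cas_agrees_with_brute_force_oracle():
    rng = np.random.default_rng(0)
    candidates = []
    for _ in range(1000):
        shape = rng.integers(0, 4)
        if shape == 0:  # well-formed, random check digit
            a = "".join(str(d) for d in rng.integers(0, 10, rng.integers(2, 8)))
            candidates.append(f"{a}-{rng.integers(10, 100)}-{rng.integers(0, 10)}")
        elif shape == 1:  # random junk
            length = rng.integers(1, 14)
            alphabet = list(string.digits + "-ab ")
            candidates.append("".join(rng.choice(alphabet) for _ in range(length)))
        elif shape == 2:  # wrong segment widths
            candidates.append(f"{rng.integers(0, 10)}-{rng.integers(0, 1000)}-"
                              f"{rng.integers(0, 10)}")
        else:  # valid by construction
            digits = "".join(str(d) for d in rng.integers(0, 10, 7))
            check = sum(w * int(d) for w, d in enumerate(reversed(digits), 1)) % 10
            candidates.append(f"{digits[:5]}-{digits[5:]}-{check}")
    for candidate in candidates:
        assert validate_cas(candidate) == cas_oracle(candidate), candidate


INCHI_CASES = [
    ("InChI=1S/H2O/h1H2", True),
    ("InChI=1/CH4/h1H4", True),
    ("InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3", True),
    ("InChI=1S/C6H6", True),           # formula-only
    ("water", False),
    ("InChI=1S/", False),              # empty formula layer
    ("InChI=2S/H2O", False),           # wrong version
    ("InChI=1S/H2O//h1H2", False),     # empty layer
    ("InChI=1S/H2O/1h", False),        # layer without letter prefix
]


@pytest.mark.parametrize("text,expected", INCHI_CASES)
def test_inchi_syntax_examples(text, expected):
    assert validate_inchi_syntax(text) is expected
    assert inchi_oracle(text) is expected


def test_inchi_agrees_with_grammar_oracle_on_fuzz_set():
    rng = np.random.default_rng(1)
    alphabet = list("CHNO123hc/=ISi.+-?")
    for _ in range(500):
        prefix = ["InChI=1S/", "InChI=1/", "InChI=", ""][rng.integers(0, 4)]
        body = "".join(rng.choice(alphabet) for _ in range(rng.integers(0, 15)))
        text = prefix + body
        assert validate_inchi_syntax(text) == inchi_oracle(text), text


# --- level behaviour ---------------------------------------------------------


def test_clean_fixture_all_levels(archive):
    for level in ("basic", "intermediate", "advanced"):
        report = validate(archive, level)
        assert report.outcome == "clean", report.to_text()


def test_missing_optional_name_is_warning_only(archive):
    archive.compounds["c1"].name = None
    report = validate(archive, "basic")
    assert report.outcome == "warnings"
    assert {f.check_id for f in report.findings} == {"name-missing"}


def test_model_referencing_absent_property_fails(archive):
    archive.models["model1"].property_id = "nope"
    report = validate(archive, "basic")
    assert report.outcome == "failed"
    assert any(f.check_id == "strong-ref-unresolved" for f in report.findings)


def test_dangling_weak_ref_detected(archive):
    table = archive.predictions["training"].values_table()
    table.set("zz-unknown", 1.0)
    archive.predictions["training"].set_values(table)
    findings = validate(archive, "basic").findings
    assert [f.check_id for f in findings] == ["weak-ref-unresolved"]


@pytest.mark.parametrize("defect,target", sorted(DEFECT_LEVEL.items()))
def test_each_defect_flips_exactly_its_level(defect, target):
    """The lowest failing level of a singly-defective archive is the target level."""
    archive = generate(FixtureSpec(seed=13, defects=[defect]))
    outcomes = {level: validate(archive, level).outcome
                for level in ("basic", "intermediate", "advanced")}
    if target is None:
        assert set(outcomes.values()) == {"warnings"}
        return
    failing = [level for level, outcome in outcomes.items() if outcome == "failed"]
    assert failing and failing[0] == target
    order = ["basic", "intermediate", "advanced"]
    assert failing == order[order.index(target):]  # monotone above the target


@pytest.mark.parametrize("seed", [21, 22, 23, 24])
def test_findings_monotone_across_levels(seed):
    rng = np.random.default_rng(seed)
    defect_pool = list(DEFECT_LEVEL)
    defects = list(rng.choice(defect_pool, size=rng.integers(0, 3), replace=False))
    archive = generate(random_spec(rng, defects=defects))
    basic = set(validate(archive, "basic").findings)
    intermediate = set(validate(archive, "intermediate").findings)
    advanced = set(validate(archive, "advanced").findings)
    assert basic <= intermediate <= advanced


# --- advanced reproducibility ------------------------------------------------


def test_perturbed_prediction_yields_exactly_one_mismatch(archive):
    prediction = archive.predictions["validation"]
    table = prediction.values_table()
    key = next(iter(table.keys()))
    table.set(key, table.get(key) + 1.0)
    prediction.set_values(table)
    findings = validate(archive, "advanced").findings
    mismatches = [f for f in findings if f.check_id == "prediction-mismatch"]
    assert len(mismatches) == 1
    assert mismatches[0].path == "predictions/validation"
    assert f"'{key}'" in mismatches[0].message


def test_flipped_classification_label_is_one_mismatch(classification_archive):
    prediction = classification_archive.predictions["training"]
    table = prediction.values_table()
    key = next(iter(table.keys()))
    flipped = "active" if table.get(key) == "inactive" else "inactive"
    table.set(key, flipped)
    prediction.set_values(table)
    findings = validate(classification_archive, "advanced").findings
    assert [f.check_id for f in findings] == ["prediction-mismatch"]


def test_tolerance_is_half_ulp_of_printed_text():
    assert stored_value_tolerance("2.35") == pytest.approx(0.005)
    assert stored_value_tolerance("2.3") == pytest.approx(0.05)
    assert stored_value_tolerance("3") == pytest.approx(0.5)
    # full-precision repr hits the absolute floor
    assert stored_value_tolerance("2.0591061097772581") == pytest.approx(1e-8)


def test_within_tolerance_difference_not_flagged(archive):
    """A stored value printed at two decimals tolerates half-ULP rounding."""
    prediction = archive.predictions["training"]
    table = prediction.values_table()
    key = next(iter(table.keys()))
    table.set(key, f"{table.get(key):.2f}")
    prediction.set_values(table)
    findings = validate(archive, "advanced").findings
    assert not [f for f in findings if f.check_id == "prediction-mismatch"]


# --- report outcome invariant ------------------------------------------------


finding_strategy = st.builds(
    Finding,
    severity=st.sampled_from(["ERROR", "WARNING"]),
    level=st.sampled_from(["basic", "intermediate", "advanced"]),
    check_id=st.sampled_from(["a", "b"]),
    path=st.just("compounds/c1"),
    message=st.just("m"),
)


@settings(max_examples=200, derandomize=True)
@given(st.lists(finding_strategy, max_size=8))
def test_outcome_derivation_invariant(findings):
    report = ValidationReport(target_level="basic", findings=findings)
    if any(f.severity == "ERROR" for f in findings):
        assert report.outcome == "failed"
    elif findings:
        assert report.outcome == "warnings"
    else:
        assert report.outcome == "clean"
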