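"""Parsing and evaluation of the mathematical representation of models.

A model's ``equation`` cargo is UTF-8 text whose first line is a header —
``type=regression`` or ``type=classification; cuts=<c1,...>; labels=<l1,...>``
— followed by an arithmetic expression over descriptor ids with the operators
``+ - * / ^``, parentheses and the unary functions ``ln``, ``log10``, ``exp``,
``sqrt``, ``abs``.  Classification is thresholded regression: the expression
yields a score and the ordered cut points select one of ``len(cuts)+1``
labels (score <= cut_i picks ``labels[i]``, otherwise the last label).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping

from .core import Archive, Model, ValuesTable
from .errors import (
    CargoParseError,
    EquationParseError,
    MathDomainError,
    MissingBinding,
    QdbError,
)

__all__ = ["EquationSpec", "parse_equation", "evaluate", "regenerate_predictions"]

_FUNCTIONS = {
    "ln": math.log,
    "log10": math.log10,
    "exp": math.exp,
    "sqrt": math.sqrt,
    "abs": abs,
}

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<number>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)"
    r"|(?P<ident>[A-Za-z_][A-Za-z0-9_-]*)"
    r"|(?P<op>[-+*/^()]))"
)


@dataclass
class EquationSpec:
    """Parsed equation: model type, expression AST and classification spec."""

    model_type: str  # "regression" | "classification"
    expression: str
    cut_points: list[float] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    ast: tuple = None  # type: ignore[assignment]
    identifiers: frozenset[str] = frozenset()


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            remainder = text[pos:].strip()
            if not remainder:
                break
            raise EquationParseError(f"unknown token at {remainder[:10]!r}")
        pos = match.end()
        for group in ("number", "ident", "op"):
            value = match.group(group)
            if value is not None:
                tokens.append((group, value))
                break
    return tokens


class _Parser:
    """Recursive-descent parser for the equation expression grammar.

    expr   := term (('+' | '-') term)*
    term   := factor (('*' | '/') factor)*
    factor := ('+' | '-') factor | power
    power  := atom ('^' factor)?            # right-associative
    atom   := number | ident | func '(' expr ')' | '(' expr ')'
    """

    def __init__(self, tokens):
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def take(self):
        token = self.peek()
        self.pos += 1
        return token

    def expect_op(self, op):
        kind, value = self.take()
        if kind != "op" or value != op:
            raise EquationParseError(f"expected {op!r}, got {value!r}")

    def parse(self):
        node = self.expr()
        if self.pos != len(self.tokens):
            raise EquationParseError(f"unexpected trailing token {self.peek()[1]!r}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() == ("op", "+") or self.peek() == ("op", "-"):
            _, op = self.take()
            node = (op, node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() == ("op", "*") or self.peek() == ("op", "/"):
            _, op = self.take()
            node = (op, node, self.factor())
        return node

    def factor(self):
        if self.peek() in (("op", "-"), ("op", "+")):
            _, op = self.take()
            child = self.factor()
            return child if op == "+" else ("neg", child)
        return self.power()

    def power(self):
        node = self.atom()
        if self.peek() == ("op", "^"):
            self.take()
            node = ("^", node, self.factor())
        return node

    def atom(self):
        kind, value = self.take()
        if kind == "number":
            return ("num", float(value))
        if kind == "ident":
            if value in _FUNCTIONS:
                self.expect_op("(")
                inner = self.expr()
                self.expect_op(")")
                return ("call", value, inner)
            return ("var", value)
        if (kind, value) == ("op", "("):
            inner = self.expr()
            self.expect_op(")")
            return inner
        raise EquationParseError(f"unexpected token {value!r}")


def _collect_identifiers(node, acc: set):
    tag = node[0]
    if tag == "var":
        acc.add(node[1])
    elif tag == "neg":
        _collect_identifiers(node[1], acc)
    elif tag == "call":
        _collect_identifiers(node[2], acc)
    elif tag in ("+", "-", "*", "/", "^"):
        _collect_identifiers(node[1], acc)
        _collect_identifiers(node[2], acc)


def parse_equation(payload: bytes | str) -> EquationSpec:
    """Parse an ``equation`` cargo into an :class:`EquationSpec`."""
    text = payload.decode("utf-8") if isinstance(payload, bytes) else payload
    lines = text.strip().split("\n", 1)
    if len(lines) != 2:
        raise EquationParseError("equation cargo needs a header line and an expression line")
    header, expression = lines[0].strip(), lines[1].strip()
    parts = [p.strip() for p in header.split(";")]
    header_fields = {}
    for part in parts:
        if "=" not in part:
            raise EquationParseError(f"malformed header field {part!r}")
        key, _, value = part.partition("=")
        header_fields[key.strip()] = value.strip()
    model_type = header_fields.get("type")
    if model_type not in ("regression", "classification"):
        raise EquationParseError(f"unknown model type {model_type!r}")
    cut_points: list[float] = []
    labels: list[str] = []
    if model_type == "classification":
        if "cuts" not in header_fields or "labels" not in header_fields:
            raise EquationParseError("classification header needs cuts= and labels=")
        try:
            cut_points = [float(c) for c in header_fields["cuts"].split(",")]
        except ValueError as exc:
            raise EquationParseError(f"bad cut point: {exc}") from exc
        labels = [lab.strip() for lab in header_fields["labels"].split(",")]
        if not cut_points:
            raise EquationParseError("classification needs at least one cut point")
        if any(b <= a for a, b in zip(cut_points, cut_points[1:])):
            raise EquationParseError("cut points must be strictly increasing")
        if len(labels) != len(cut_points) + 1:
            raise EquationParseError(
                f"need {len(cut_points) + 1} labels for {len(cut_points)} cuts, "
                f"got {len(labels)}")
    ast = _Parser(_tokenize(expression)).parse()
    identifiers: set[str] = set()
    _collect_identifiers(ast, identifiers)
    return EquationSpec(
        model_type=model_type,
        expression=expression,
        cut_points=cut_points,
        labels=labels,
        ast=ast,
        identifiers=frozenset(identifiers),
    )


def _eval_node(node, bindings: Mapping[str, float]) -> float:
    tag = node[0]
    if tag == "num":
        return node[1]
    if tag == "var":
        return bindings[node[1]]
    if tag == "neg":
        return -_eval_node(node[1], bindings)
    if tag == "call":
        func_name, arg_node = node[1], node[2]
        arg = _eval_node(arg_node, bindings)
        if func_name in ("ln", "log10", "sqrt") and arg <= 0 and func_name != "sqrt":
            raise MathDomainError(f"{func_name} of non-positive value {arg}")
        if func_name == "sqrt" and arg < 0:
            raise MathDomainError(f"sqrt of negative value {arg}")
        try:
            return _FUNCTIONS[func_name](arg)
        except (ValueError, OverflowError) as exc:
            raise MathDomainError(f"{func_name}({arg}): {exc}") from exc
    left = _eval_node(node[1], bindings)
    right = _eval_node(node[2], bindings)
    if tag == "+":
        return left + right
    if tag == "-":
        return left - right
    if tag == "*":
        return left * right
    if tag == "/":
        if right == 0:
            raise MathDomainError("division by zero")
        return left / right
    if tag == "^":
        try:
            result = left ** right
        except (ValueError, OverflowError, ZeroDivisionError) as exc:
            raise MathDomainError(f"{left} ^ {right}: {exc}") from exc
        if isinstance(result, complex):
            raise MathDomainError(f"{left} ^ {right} is complex")
        return result
    raise AssertionError(f"unknown node {tag!r}")


def evaluate(spec: EquationSpec, bindings: Mapping[str, float]):
    """Evaluate an equation under descriptor bindings.

    Returns a float for regression, a label for classification.
    """
    missing = sorted(spec.identifiers - set(bindings))
    if missing:
        raise MissingBinding(missing)
    value = _eval_node(spec.ast, bindings)
    if not math.isfinite(value):
        raise MathDomainError(f"non-finite result {value}")
    if spec.model_type == "regression":
        return value
    for cut, label in zip(spec.cut_points, spec.labels):
        if value <= cut:
            return label
    return spec.labels[-1]


def regenerate_predictions(archive: Archive, model: Model) -> dict[str, ValuesTable]:
    """Re-evaluate every prediction of a model from stored descriptor data.

    Returns one recomputed table per prediction container, over the same
    compound keys in the same order.  Per-compound problems (a missing
    descriptor value, a math-domain error) leave that key marked missing
    rather than aborting.
    """
    payload = model.cargos.get("equation")
    if payload is None:
        raise EquationParseError(f"{model.path}: no equation cargo")
    spec = parse_equation(payload)
    descriptor_tables: dict[str, ValuesTable] = {}
    for descriptor_id in model.descriptor_ids:
        descriptor = archive.descriptors.get(descriptor_id)
        if descriptor is None or descriptor.cargos.get("values") is None:
            descriptor_tables[descriptor_id] = ValuesTable()
        else:
            descriptor_tables[descriptor_id] = descriptor.values_table()
    result: dict[str, ValuesTable] = {}
    for prediction in archive.predictions_of(model):
        if prediction.cargos.get("values") is None:
            continue
        try:
            stored = prediction.values_table()
        except CargoParseError:
            continue
        recomputed = ValuesTable()
        for compound_id in stored.keys():
            bindings = {}
            complete = True
            for descriptor_id, table in descriptor_tables.items():
                if compound_id not in table or table.is_missing(compound_id):
                    complete = False
                    break
                value = table.get(compound_id)
                if isinstance(value, str):
                    complete = False
                    break
                bindings[descriptor_id] = value
            if not complete:
                recomputed.set(compound_id, None)
                continue
            try:
                recomputed.set(compound_id, evaluate(spec, bindings))
            except QdbError:
                recomputed.set(compound_id, None)
        result[prediction.id] = recomputed
    return result
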