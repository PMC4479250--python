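"""Exception hierarchy shared by all qdbkit modules."""


class QdbError(Exception):
    """Base class for all qdbkit errors."""


class FormatError(QdbError):
    """Malformed ZIP container or registry XML."""


class MissingRegistry(FormatError):
    """The archive lacks the root ``archive.xml`` registry."""


class DuplicateId(QdbError):
    """Two containers in the same registry share an id."""


class CargoParseError(QdbError):
    """A system cargo payload could not be parsed."""


class IoError(QdbError):
    pass


class UnresolvedReference(QdbError):
    """A strong reference names a container that does not exist."""

    def __init__(self, kind: str, ref_id: str, referrer: str | None = None):
        self.kind = kind
        self.ref_id = ref_id
        self.referrer = referrer
        where = f" (referenced from {referrer})" if referrer else ""
        super().__init__(f"unresolved {kind} reference {ref_id!r}{where}")


class EquationParseError(QdbError):
    pass


class MissingBinding(QdbError):
    """Equation evaluation is missing one or more descriptor values."""

    def __init__(self, identifiers):
        self.identifiers = list(identifiers)
        super().__init__(f"missing bindings for: {', '.join(self.identifiers)}")


class MathDomainError(QdbError):
    """Evaluation hit a math-domain problem (log of non-positive, 1/0, overflow)."""


class NoOverlap(QdbError):
    """Experimental and predicted tables share no scorable compound."""


class ZeroVariance(QdbError):
    """All experimental values are identical; R^2 is undefined."""


class DimensionMismatch(QdbError):
    pass


class InsufficientTraining(QdbError):
    """Fewer than two complete descriptor rows in the training set."""


class CalculatorUnavailable(QdbError):
    pass


class DescriptorNotComputable(QdbError):
    """The calculator declined one or more descriptor ids."""

    def __init__(self, identifiers):
        self.identifiers = list(identifiers)
        super().__init__(f"cannot compute descriptors: {', '.join(self.identifiers)}")


class DescriptorValueMissing(QdbError):
    pass


class SpecError(QdbError):
    """Invalid fixture specification."""
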