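"""Exception hierarchy shared across the package."""


class MelmpError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MelmpError):
    """A file does not conform to its declared layout (names the offending line/record)."""


class InvalidSymbolError(MelmpError):
    """A sequence contains a symbol outside its declared alphabet."""


class DegenerateInputError(MelmpError):
    """An input is structurally valid but carries no usable information."""


class StructuralError(MelmpError):
    """An ontology violates its structural invariants (cycle, missing root, ...)."""
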