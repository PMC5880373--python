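"""Exception hierarchy shared across the package."""


class HybdiagError(Exception):
    """Base class for all package-specific errors."""


class InvalidSymbolError(HybdiagError):
    """A character is not a valid IUPAC nucleotide symbol in this context."""


class AlignmentShapeError(HybdiagError):
    """Sequences in an alignment do not share the same length."""


class TraceError(HybdiagError):
    """A trace matrix is malformed (e.g. an all-zero intensity column)."""


class ParameterError(HybdiagError):
    """A numeric parameter is outside its documented domain."""
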