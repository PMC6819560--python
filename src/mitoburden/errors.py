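"""Exception hierarchy shared across the package."""


class MitoError(Exception):
    """Base class for all mitoburden errors."""


class CoordinateError(MitoError):
    """A genomic position falls outside 1..16,569 or outside a feature."""


class SequenceError(MitoError):
    """Invalid nucleotide content (non-ACGT codon, bad reference)."""


class ParseError(MitoError):
    """A variant label or file token could not be parsed."""


class FormatError(MitoError):
    """A file is structurally invalid for its declared format."""


class ValidationError(MitoError):
    """A value violates a domain constraint (e.g. MAF outside [0,1])."""


class DegenerateTableError(MitoError):
    """A contingency table has a zero marginal and the test is undefined."""


class ConfigError(MitoError):
    """A pipeline configuration references missing files or bad settings."""
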