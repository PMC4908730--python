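"""Exception hierarchy used across the package."""


class ProinflamError(Exception):
    """Base class for all package-specific errors."""


class FastaParseError(ProinflamError):
    """Raised when a FASTA file is syntactically malformed.

    ``line`` is the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(ProinflamError, ValueError):
    """Raised when a sequence or dataset violates a precondition."""


class AlphabetError(ValidationError):
    """A sequence contains a character outside the 20 standard residues."""

    def __init__(self, record: str, char: str):
        self.record = record
        self.char = char
        super().__init__(
            f"non-standard residue {char!r} in {record!r}; "
            "allowed alphabet is the 20 standard amino acids"
        )


class LengthError(ValidationError):
    """A peptide falls outside the permitted length range."""

    def __init__(self, record: str, length: int, min_len: int, max_len: int):
        self.record = record
        self.length = length
        super().__init__(
            f"{record!r} has length {length}, outside the allowed "
            f"range {min_len}-{max_len}"
        )


class ConfigError(ProinflamError):
    """Invalid configuration: scheme, scale table, motif syntax, parameters."""


class ModelFormatError(ProinflamError):
    """A model file is unreadable or has an incompatible version."""
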