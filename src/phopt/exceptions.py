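"""Exception hierarchy shared across the package."""


class PhoptError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PhoptError):
    """A file could not be parsed (malformed FASTA entry, bad mutation name, ...)."""


class SchemaError(PhoptError):
    """A tabular input is missing required columns."""


class ValidationError(PhoptError):
    """A value violates a domain constraint (bad position, wild-type mismatch, ...)."""


class ContractError(PhoptError):
    """A precondition of an operation was violated by the caller."""


class CapabilityError(PhoptError):
    """An optional backend (e.g. the protein-language-model embedder) is unavailable."""


class TrainingError(PhoptError):
    """Optimization failed (non-finite loss); message names the epoch and batch."""
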