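"""Exception hierarchy.

Every component raises a subclass of :class:`RxnForgeError` so that the
trainer can attach the owning config path before re-raising.
"""


class RxnForgeError(Exception):
    """Base class for all framework errors."""


class ParseError(RxnForgeError):
    """A SMILES string or data file could not be parsed."""


class MappingError(RxnForgeError):
    """Atom-map labels are missing, duplicated, or not conserved."""


class ConfigError(RxnForgeError):
    """An invalid or inconsistent configuration value."""


class DatasetError(RxnForgeError):
    """A tabular dataset is missing columns, rows, or target values."""


class TokenizationError(RxnForgeError):
    """A SMILES string does not follow the token grammar."""


class GeometryError(RxnForgeError):
    """Mismatched or malformed 3D geometry input."""


class InputError(RxnForgeError):
    """A model received a structurally invalid input batch."""


class GenerationError(RxnForgeError):
    """The synthetic-reaction generator could not satisfy its spec."""
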