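"""Exception and warning types shared across the package."""


class SymptomNetError(Exception):
    """Base class for all package-specific errors."""


class InvalidNetworkError(SymptomNetError):
    """Network parameters violate an invariant (asymmetry, nonzero diagonal...)."""


class EnumerationRefusedError(SymptomNetError):
    """Exact enumeration requested for a state space that is too large."""


class InvalidSpecError(SymptomNetError):
    """A specification object (contrast spec, latent-Gaussian spec...) is inconsistent."""


class InvalidResponseError(SymptomNetError):
    """A Likert response falls outside the admissible category range."""


class MissingItemError(SymptomNetError):
    """A required item code is absent from a dataset or network."""


class IncompatibleDatasetsError(SymptomNetError):
    """Two datasets that must share an item set do not."""


class UndefinedCorrelationError(SymptomNetError):
    """Correlation undefined because an item has zero variance."""


class InvalidPValueError(SymptomNetError):
    """A p-value lies outside (0, 1]."""


class ConfigError(SymptomNetError):
    """A run configuration references missing paths or inconsistent settings."""


class DegenerateNodeWarning(UserWarning):
    """A node's response column is constant; it is isolated in the fit."""
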