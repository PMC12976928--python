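"""Exception hierarchy for tcrcontact."""


class TcrContactError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TcrContactError):
    """A required column, option, or parameter is missing or invalid."""


class EmptyDatasetError(TcrContactError):
    """Reading or filtering produced zero usable records."""


class TruncationError(TcrContactError):
    """A sequence exceeds the store's maximum length; silent truncation is refused."""


class StoreLookupError(TcrContactError, KeyError):
    """A sequence was requested that the embedding store does not hold."""


class InfeasibleSplitError(TcrContactError):
    """No epitope satisfies the requested minimum edit-distance threshold."""


class UndefinedMetricError(TcrContactError):
    """A metric is undefined for the given inputs (e.g. single-class labels)."""


class NonFiniteLossError(TcrContactError):
    """Training produced a NaN/Inf loss; carries a diagnostic batch dump."""

    def __init__(self, message, batch_dump=None):
        super().__init__(message)
        self.batch_dump = batch_dump


class StructureSelectionError(TcrContactError):
    """A chain or residue range could not be resolved in a structure."""
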