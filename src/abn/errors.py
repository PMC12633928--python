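"""Exception types shared across the package."""


class AbnError(Exception):
    """Base class for all package-specific errors."""


class HierarchyIntegrityError(AbnError):
    """The structure tree violates an invariant (duplicate IDs, bad paths...)."""


class MissingParentError(HierarchyIntegrityError):
    """A node references a parent that is not present in the tree."""


class RegionLookupError(AbnError, KeyError):
    """A region ID or acronym does not resolve in the hierarchy."""


class ValidationError(AbnError, ValueError):
    """Invalid input data (non-finite coordinates, malformed tables...)."""


class ScopePartitionError(AbnError):
    """A scope set is not a partition: one member is an ancestor of another."""


class EmptyBrainError(AbnError):
    """A brain contributes zero neurons to the requested scope."""


class NoLayerError(AbnError):
    """The requested parent region has no laminar (cortical layer) children."""


class InsufficientDataError(AbnError):
    """Too few observations for the requested statistic."""


class AlignmentError(AbnError):
    """Region sets of two inputs cannot be reconciled."""


class DegenerateNetworkError(AbnError):
    """A network has no weight (m = 0) or is otherwise unusable."""
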