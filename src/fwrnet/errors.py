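"""Exception hierarchy for fwrnet.

All package errors derive from :class:`FwrnetError` so callers can catch
one base class; each subclass maps to a distinct failure mode of the
pipeline (bad window geometry, degenerate partitions, disconnected
networks, cohort validation, ...).
"""


class FwrnetError(Exception):
    """Base class for all fwrnet errors."""


class InvalidWindowError(FwrnetError):
    """Window is not square with an odd side of at least 3."""


class EmptyFeatureSetError(FwrnetError):
    """Image too small for the requested window: no valid centers."""


class InvalidInputError(FwrnetError):
    """Non-finite or otherwise malformed numeric input."""


class InsufficientDataError(FwrnetError):
    """Fewer data points than clusters requested."""


class InvalidPartitionError(FwrnetError):
    """Membership matrix is not row-stochastic (rows must sum to 1)."""


class InvalidRelationError(FwrnetError):
    """Fuzzy relation matrix lacks symmetry, unit diagonal, or [0,1] range."""


class InvalidAdjacencyError(FwrnetError):
    """Adjacency matrix is not symmetric/binary/zero-diagonal as required."""


class InvalidWeightError(FwrnetError):
    """Edge weights outside the admissible range (negative weights)."""


class InvalidTransformError(FwrnetError):
    """Weight-to-length transform produced a non-positive edge length."""


class DisconnectedNetworkError(FwrnetError):
    """Network splits into several components, so mean path length is undefined.

    Carries the number of connected components found.
    """

    def __init__(self, n_components: int, message: str | None = None):
        self.n_components = n_components
        super().__init__(
            message
            or f"network is disconnected: {n_components} connected components"
        )


class CohortValidationError(FwrnetError):
    """A cohort table row violates the schema (IHC score range, negative months)."""


class EmptySpecimenError(FwrnetError):
    """No kept tiles for a specimen: nothing to average."""


class UnpairedPatientError(FwrnetError):
    """Patient lacks a biopsy/tumor specimen pair."""


class DegenerateRatioError(FwrnetError):
    """Biopsy metric is zero, tumor/biopsy ratio undefined."""


class GroupTooSmallError(FwrnetError):
    """Subgroup has fewer than 3 patients; association is not computed."""


class UndefinedCorrelationError(FwrnetError):
    """Correlation undefined because one variable is constant."""


class EmptyDenominatorError(FwrnetError):
    """No patients fall in the requested ratio range."""
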