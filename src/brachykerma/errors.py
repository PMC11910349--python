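"""Exception hierarchy for brachykerma."""


class BrachyKermaError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BrachyKermaError, ValueError):
    """An argument violates a documented precondition."""


class InvalidMixtureError(InvalidInputError):
    """Mixture mass fractions do not form a valid partition."""


class ValidationError(BrachyKermaError, ValueError):
    """A domain object violates one of its invariants."""


class PlanParseError(BrachyKermaError, ValueError):
    """A dwell-plan file could not be parsed."""


class OutOfRangeError(BrachyKermaError, ValueError):
    """Energy outside the tabulated grid (no extrapolation)."""


class SimulationError(BrachyKermaError, RuntimeError):
    """The transport kernel produced a non-finite state."""


class EmptyStructureError(BrachyKermaError, ValueError):
    """A structure mask contains no voxels."""


class InsufficientVolumeError(BrachyKermaError, ValueError):
    """Structure smaller than the requested absolute-volume metric."""


class UndefinedMetricError(BrachyKermaError, ZeroDivisionError):
    """Metric undefined for this input (e.g. DHI with V100 = 0)."""


class EmptySelectionError(BrachyKermaError, ValueError):
    """No voxels fall inside the requested dose band."""


class DegenerateTestError(BrachyKermaError, ValueError):
    """Statistical test undefined (e.g. all paired differences zero)."""


class EmptyCohortError(BrachyKermaError, ValueError):
    """Summary requested for an empty collection of values."""


class DegenerateCaseError(BrachyKermaError, ValueError):
    """Synthetic case generation produced an unusable geometry."""
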