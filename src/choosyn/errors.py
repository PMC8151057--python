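"""Exception hierarchy for the synergy-selection pipeline."""


class ChoosynError(Exception):
    """Base class for all package-specific errors."""


class OrderExceedsMusclesError(ChoosynError):
    """Requested number of synergies exceeds the number of muscles."""


class GenerationFailureError(ChoosynError):
    """Ground-truth generator could not satisfy its constraints."""


class IncompatibleSetsError(ChoosynError):
    """Ground-truth sets cannot be combined (mismatched order or muscles)."""


class EmptyInputError(ChoosynError):
    """An operation received an empty collection."""


class NoCompleteCycleError(ChoosynError):
    """Fewer than two gait events: no complete cycle to segment."""


class EventOrderError(ChoosynError):
    """Gait events are not strictly increasing."""


class FilterDesignError(ChoosynError):
    """Requested filter cutoff is at or above the Nyquist frequency."""


class InsufficientCyclesError(ChoosynError):
    """Fewer than 10 gait cycles: no complete subgroup can be formed."""


class IncompleteStackError(ChoosynError):
    """Synergy stack does not cover the full range of candidate orders."""


class ClusteringDomainError(ChoosynError):
    """Zero-norm vector passed to a cosine-based computation."""


class UndefinedVafError(ChoosynError):
    """VAF is undefined (reference matrix is all zero)."""


class NoSelectionError(ChoosynError):
    """A selection criterion found no qualifying number of synergies."""


class DegenerateElbowError(ChoosynError):
    """VAF curve is exactly linear: no elbow exists."""


class UndefinedMetricError(ChoosynError):
    """Benchmark metric undefined (no valid trials after exclusions)."""
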