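"""Exception hierarchy for himme.

All himme-specific errors derive from :class:`HimmeError` so callers can catch
the whole family; most also derive from ``ValueError`` because they signal
invalid inputs or degenerate data rather than programming errors.
"""


class HimmeError(Exception):
    """Base class for all himme errors."""


class AmbiguousBaseError(HimmeError, ValueError):
    """A k-mer contained a character outside {A, C, G, T} where none is allowed."""


class InvalidProbabilityError(HimmeError, ValueError):
    """A probability parameter fell outside its admissible range."""


class InvalidDistributionError(HimmeError, ValueError):
    """A probability vector does not sum to one (or has negative entries)."""


class EmptyTrainingError(HimmeError, ValueError):
    """No countable k-mer transition exists in the training input."""


class UntrainedStateError(HimmeError, ValueError):
    """With pseudocount 0, some transition rows received no counts and are undefined."""


class UndefinedScoreError(HimmeError, ValueError):
    """A score was requested for a sequence with no scoreable k-mer (m == 0)."""


class DegenerateBenchmarkError(HimmeError, ValueError):
    """A reference score distribution has zero spread and cannot define z-scores."""


class ZeroVarianceError(HimmeError, ValueError):
    """All corrected scores are identical; the assembly coefficient is undefined."""


class InsufficientDataError(HimmeError, ValueError):
    """Fewer data points than the statistic requires."""


class ModelMismatchError(HimmeError, ValueError):
    """Transition and emission models (or matrix files) disagree on k or alphabet."""


class MatrixFormatError(HimmeError, ValueError):
    """A model matrix file is malformed or internally inconsistent."""
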