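"""Exception hierarchy shared across the pipeline stages."""


class RoilogitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RoilogitError, ValueError):
    """A specification or argument failed an invariant check."""


class GridMismatchError(RoilogitError, ValueError):
    """Statistical map and atlas do not share a voxel grid."""


class LabelingError(RoilogitError, ValueError):
    """Atlas label volume contains labels missing from the region table."""


class SizingError(RoilogitError, ValueError):
    """Toy atlas grid cannot accommodate the requested regions."""


class JoinError(RoilogitError, ValueError):
    """Subject metadata cannot be joined one-to-one with maps/rows."""


class SampleSizeError(RoilogitError, ValueError):
    """Too few subjects for the requested statistic."""


class DegenerateOutcomeError(RoilogitError, ValueError):
    """Outcome column contains a single class."""


class FoldError(RoilogitError, ValueError):
    """Cross-validation fold structure is infeasible."""


class LeakageError(RoilogitError, ValueError):
    """Evaluation rows overlap the rows used to train the model."""
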