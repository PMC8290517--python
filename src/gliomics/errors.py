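"""Domain-specific exceptions raised across the pipeline."""


class GliomicsError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(GliomicsError):
    """A cohort specification violates its invariants (e.g. non-positive counts)."""


class InfeasibleGeometryError(GliomicsError):
    """A requested tumor geometry cannot fit inside the image grid."""


class InvalidInputError(GliomicsError):
    """An input volume or table is structurally unusable (empty, misaligned...)."""


class DegenerateIntensityError(GliomicsError):
    """Intensity normalization is impossible (zero variance over the support)."""


class InvalidRoiError(GliomicsError):
    """A region of interest is empty or otherwise unusable for feature extraction."""


class MissingInputError(GliomicsError):
    """A required channel or column is absent; the message names it."""


class DegenerateLabelsError(GliomicsError):
    """The label vector is constant; no classifier or selector can be fit."""


class SchemaMismatchError(GliomicsError):
    """Feature names at prediction time do not match the trained model."""


class StratificationError(GliomicsError):
    """A class has fewer members than the requested number of folds."""


class InvalidSubgroupError(GliomicsError):
    """A subgroup restriction leaves fewer than two classes."""


class UndefinedMetricError(GliomicsError):
    """A performance metric is undefined on the given inputs (e.g. one-class AUC)."""


class UnstableCiError(GliomicsError):
    """The bootstrap metric was undefined on too many resamples for a stable CI."""
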