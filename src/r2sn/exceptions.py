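"""Exception hierarchy for the r2sn pipeline."""


class R2SNError(Exception):
    """Base class for all r2sn errors."""


class ParameterError(R2SNError, ValueError):
    """An operation received an invalid parameter or specification."""


class EmptyRegionError(R2SNError):
    """A parcellation region contains no voxels."""


class MissingRegionError(R2SNError):
    """An atlas region is absent from a label volume."""


class DegenerateFeatureError(R2SNError):
    """A feature column is constant and cannot be min-max normalized."""


class DegenerateRegionError(R2SNError):
    """A region's retained-feature vector has zero variance."""


class EmptySelectionError(R2SNError):
    """The consistent-edge intersection is empty; the pipeline cannot proceed."""


class DegenerateInputError(R2SNError):
    """Input is degenerate for the requested statistic (e.g. all-zero matrix)."""
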