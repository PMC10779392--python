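"""Exception hierarchy shared across the pipeline."""


class PipelineError(Exception):
    """Base class for all mbmri errors."""


class DimensionError(PipelineError):
    """An image or array has the wrong dimensionality or mismatched grids."""


class FormatError(PipelineError):
    """A file violates its on-disk format contract (e.g. non-positive voxel dims)."""


class ValidationError(PipelineError):
    """A table or config row fails validation (duplicate ids, unknown tokens...)."""


class ParameterError(PipelineError):
    """An analysis parameter is infeasible (e.g. passband above Nyquist)."""


class GenerationError(PipelineError):
    """Synthetic-cohort generation could not satisfy its contract."""


class DegenerateDataError(PipelineError):
    """Input data are degenerate for the requested statistic (constant series,
    zero-variance sample, all-zero difference vector)."""
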