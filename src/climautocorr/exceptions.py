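"""Exception hierarchy used across the package."""


class ClimAutocorrError(Exception):
    """Base class for package errors."""


class FormatError(ClimAutocorrError):
    """A file or dataset does not conform to the expected layout
    (missing coordinates, unrecognized units, unknown calendar tag)."""


class EstimationError(ClimAutocorrError):
    """A statistical fit could not be carried out (too few data,
    non-convergence after multi-start, no feasible model)."""


class DegenerateFitError(EstimationError):
    """The fit succeeded numerically but the result carries no usable
    structure (e.g. a flat variogram: partial sill ~ 0, range undefined)."""
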