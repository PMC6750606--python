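"""Exception and warning types shared across the package."""


class DomainError(ValueError):
    """An input lies outside the physical or mathematical domain of an operation."""


class InsufficientDataError(ValueError):
    """Too few usable observations remain to carry out the computation."""


class DegenerateDataError(RuntimeError):
    """Data are structurally degenerate (zero spread, all-zero differences, ...)."""


class IngestError(ValueError):
    """A cohort table could not be mapped onto the required column dictionary."""


class NonPhysicalValueWarning(RuntimeWarning):
    """A computed quantity lies outside its physical range and is flagged, not clipped."""
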