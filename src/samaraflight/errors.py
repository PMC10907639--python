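"""Exception types raised across the pipeline."""


class SamaraError(ValueError):
    """Base class for domain errors in samaraflight."""


class DomainError(SamaraError):
    """An input falls outside the physically meaningful domain."""


class SchemaError(SamaraError):
    """A table or record does not match the expected CSV schema."""


class SegmentationError(SamaraError):
    """No usable silhouette could be extracted from an image."""


class SingularFitError(SamaraError):
    """A regression problem is degenerate (no spread in the regressor)."""


class MissingBaselineError(SamaraError):
    """A perturbation series lacks its unaltered (level-0) record."""


class NoEquilibriumError(SamaraError):
    """The vertical force balance has no solution (projected area vanishes)."""
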