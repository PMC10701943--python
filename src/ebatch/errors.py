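"""Exception and warning types shared across the package."""


class EbatchError(Exception):
    """Base class for all validation and estimation errors."""


class ShapeMismatchError(EbatchError):
    """Sample or gene identifiers disagree between inputs."""


class SingleBatchError(EbatchError):
    """Fewer than two distinct batches were supplied."""


class SingleSampleBatchError(EbatchError):
    """A batch contains too few samples for the requested model."""


class ConfoundedDesignError(EbatchError):
    """A covariate is collinear with the batch indicators."""


class EBDegenerateError(EbatchError):
    """Across-gene variance of the scale estimates is zero; the
    inverse-gamma hyperprior cannot be moment-matched."""


class ParseError(EbatchError):
    """A matrix, batch or covariate file could not be parsed."""


class DegenerateGeneWarning(UserWarning):
    """Genes constant across all samples bypass correction."""


class ConvergenceWarning(UserWarning):
    """An iterative solver hit its iteration cap."""


class NumericalUnderflowWarning(UserWarning):
    """All donor weights underflowed for a gene in the non-parametric
    posterior; the gene's own estimates are kept."""


class PoissonFallbackWarning(UserWarning):
    """A batch's profile likelihood was maximized at zero dispersion."""


class IRLSDivergenceWarning(UserWarning):
    """Per-gene IRLS diverged; method-of-moments coefficients used."""
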