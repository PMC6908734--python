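"""Exception and warning types shared across the package."""


class PathsigError(Exception):
    """Base class for all package-specific errors."""


class MalformedPathwayError(PathsigError):
    """A pathway file references nodes that were never declared, or is otherwise unparseable."""


class EmptyRoleError(PathsigError):
    """A pathway has no receptor (in-degree 0) or no effector (out-degree 0) node."""


class EmptyMappingError(PathsigError):
    """No probe in the probe matrix maps to any gene."""


class DegenerateMatrixError(PathsigError):
    """Quantile normalization requested on a matrix with a constant column."""


class DomainError(PathsigError):
    """A numeric argument lies outside its documented domain (e.g. a signal outside [0, 1])."""


class NoTargetResolvedError(PathsigError):
    """None of the perturbation target genes match the expression matrix index."""


class DesignError(PathsigError):
    """A case/control design is invalid (wrong labels, missing samples, groups too small)."""


class GenerationError(PathsigError):
    """A synthetic fixture could not satisfy its constraints within the retry budget."""


class NonConvergenceWarning(UserWarning):
    """Fixed-point propagation on a cyclic circuit hit max_iter before reaching tol."""


class DegenerateScaleWarning(UserWarning):
    """A rescaling or normalization step met a constant input and applied its documented fallback."""
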