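"""Exception hierarchy for the rdschain package."""


class RDSError(Exception):
    """Base class for all rdschain errors."""


class SchemaError(RDSError):
    """A required column or variable is missing or unresolvable."""


class CategoryError(RDSError, ValueError):
    """A cell value cannot be mapped onto a known category level."""


class IntegrityError(RDSError):
    """Referential integrity of the participant table / coupon graph is broken
    (duplicate ids, dangling recruiter links, unreachable nodes)."""


class ConfigError(RDSError):
    """A simulation or pipeline configuration is invalid."""


class SimulationError(RDSError):
    """Recruitment simulation failed (e.g. pool exhaustion far from target)."""


class EstimationError(RDSError):
    """An estimator cannot be computed on the given data."""


class DiagnosticError(RDSError):
    """A Markov-chain diagnostic is undefined (reducible chain, no convergence)."""


class ConvergenceError(RDSError):
    """Iterative model fitting failed to converge (e.g. separation)."""


class DesignError(RDSError):
    """The regression design matrix is rank deficient or degenerate."""
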