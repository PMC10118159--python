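"""Exception types shared across the package."""


class IwsDesignError(Exception):
    """Base class for all package-specific errors."""


class NonEstimableContrastError(IwsDesignError):
    """A requested contrast (or mean) has no information in the design.

    Raised when an allocation leaves a condition uninformed, so the
    corresponding GLS contrast variance is infinite.  Distinct from a
    numerical failure: the quantity is well-defined but unbounded.
    """


class InfeasibleDesignError(IwsDesignError):
    """No feasible allocation attains a finite criterion value."""


class ConfigError(IwsDesignError):
    """A study configuration file is malformed or inconsistent."""
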