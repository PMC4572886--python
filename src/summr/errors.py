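"""Exception hierarchy shared across the package."""


class SummrError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SummrError, ValueError):
    """A record or table violates a declared invariant."""


class HarmonizationError(SummrError):
    """Instrument and outcome tables cannot be allele-aligned."""


class EstimationError(SummrError):
    """An estimator received degenerate input (e.g. zero instruments)."""


class SimulationError(SummrError):
    """The simulator could not satisfy the requested design."""


class ConfigError(SummrError):
    """One or more problems found while validating a run configuration.

    Collects every problem instead of failing on the first, so a user can
    fix a config file in one pass.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))
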