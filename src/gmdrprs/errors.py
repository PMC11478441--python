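"""Exception hierarchy used across the pipeline."""


class GmdrPrsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(GmdrPrsError, ValueError):
    """A numeric parameter is outside its admissible range."""


class ConfigError(GmdrPrsError, ValueError):
    """A configuration file or dictionary is malformed."""


class ConvergenceError(GmdrPrsError, RuntimeError):
    """A model fit did not converge (e.g. quasi-complete separation)."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedStatisticError(GmdrPrsError, ValueError):
    """The requested statistic is undefined for this input
    (monomorphic SNP for LD, single-class evaluation set for balanced
    accuracy, all-zero genotype table for the HWE test, ...)."""


class BudgetExceededError(GmdrPrsError, ValueError):
    """An exhaustive search would evaluate more combinations than allowed."""
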