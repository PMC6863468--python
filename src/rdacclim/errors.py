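"""Exception types shared across the package."""


class RdAcclimError(Exception):
    """Base class for package errors."""


class DesignError(RdAcclimError):
    """Invalid study design specification."""


class FitError(RdAcclimError):
    """A temperature-response curve cannot be fit (too few points,
    degenerate temperature design, or non-convergence)."""


class SingularDesignError(RdAcclimError):
    """The ANCOVA design is singular (e.g. a tissue class observed at a
    single acclimation temperature)."""


class ConvergenceError(RdAcclimError):
    """Mixed-model estimation failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(RdAcclimError):
    """A measurement table violates the documented CSV schema. All row and
    column problems found are aggregated into one message."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "measurement table failed validation:\n  - " + "\n  - ".join(self.problems)
        )
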