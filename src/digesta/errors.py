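"""Exception hierarchy shared across the package.

All digesta-specific failures derive from :class:`DigestaError` so callers
can catch the package's errors without swallowing unrelated bugs.
"""

from __future__ import annotations


class DigestaError(Exception):
    """Base class for all errors raised by digesta."""


class DomainError(DigestaError, ValueError):
    """An argument is outside the physically meaningful domain."""


class MeasurementInconsistencyError(DigestaError, ValueError):
    """Residual carbohydrate exceeds the amount fed.

    Carries both masses so the offending assay can be traced; deliberately
    not clipped to zero solubilization.
    """

    def __init__(self, mass_initial: float, mass_final: float):
        self.mass_initial = mass_initial
        self.mass_final = mass_final
        super().__init__(
            f"final carbohydrate mass {mass_final!r} exceeds initial mass "
            f"{mass_initial!r}; negative solubilization is rejected, not clipped"
        )


class FitError(DigestaError, ValueError):
    """Regression input is degenerate (too few or collinear points)."""


class NonPhysicalFitError(FitError):
    """The fit converged to a physically impossible parameter set."""


class ConfigError(DigestaError, ValueError):
    """A configuration object violates its documented invariants."""


class SchemaError(DigestaError, ValueError):
    """An input table does not match its documented schema."""


class MissingQCError(DigestaError, KeyError):
    """An edge references a bin that has no QC record."""

    def __init__(self, bin_id: str):
        self.bin_id = bin_id
        super().__init__(f"no QC record for bin {bin_id!r}")


class PipelineStageError(DigestaError, RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
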