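"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Invalid configuration or input that the caller can fix."""


class IntegrityError(RuntimeError):
    """Internally inconsistent pipeline state, e.g. an outcome event falling
    on a week where the condition's denominator is zero."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage and condition."""

    def __init__(self, stage: str, condition: str, message: str):
        self.stage = stage
        self.condition = condition
        super().__init__(f"stage {stage!r}, condition {condition!r}: {message}")


class FitDiagnosticError(RuntimeError):
    """Model fitting failed (separation / non-convergence / non-finite
    estimates); carries the condition being fitted."""

    def __init__(self, condition: str, message: str):
        self.condition = condition
        super().__init__(f"{condition}: {message}")
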