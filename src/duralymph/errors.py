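"""Exception hierarchy for the duralymph pipeline."""


class DuralymphError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DuralymphError):
    """Invalid configuration (bad bounds, negative SDs, unknown mode...)."""


class GenerationError(DuralymphError):
    """Synthetic-data generation failed (e.g. unsatisfiable truncation)."""


class CalibrationError(DuralymphError):
    """Generator calibration did not converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InputError(DuralymphError):
    """Invalid input to an operation (bad seed voxel, empty mask...)."""


class ComputationError(DuralymphError):
    """A quantity is mathematically undefined for the given input."""


class StageError(DuralymphError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
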