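"""Exception hierarchy used across the package."""


class EmbryoMapError(Exception):
    """Base class for all package errors."""


class FormatError(EmbryoMapError):
    """A file does not match its declared format (dimension mismatch, bad dialect)."""


class ValidationError(EmbryoMapError):
    """An in-memory object violates its invariants (negative counts, bad config)."""


class EmptyResultError(EmbryoMapError):
    """A filtering step removed everything."""


class IncompatibleModelError(EmbryoMapError):
    """A persisted reference model cannot be loaded (schema version, checksum, missing file)."""


class StageError(EmbryoMapError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


def stage_wrap(stage: str, exc: Exception) -> StageError:
    return StageError(f"{stage}: {exc}")
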