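"""Exception hierarchy shared by all pipeline stages."""


class PainmapError(Exception):
    """Base class for all painmap errors."""


class ParameterError(PainmapError, ValueError):
    """A function argument violates its contract (invalid fraction, count, range)."""


class FormatError(PainmapError, ValueError):
    """An input file does not conform to its expected format."""


class IntegrityError(PainmapError, ValueError):
    """Cross-record inconsistency, e.g. one gene ID claimed by two species."""


class StageError(PainmapError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage:{stage}] {message}")
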