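"""Exception types shared across the toolkit."""


class MitocompError(Exception):
    """Base class for all toolkit errors."""


class InputError(MitocompError):
    """Malformed or inconsistent user input (files, coordinates, labels)."""


class NotFoundWithinBound(MitocompError):
    """A bounded search finished without a certificate (e.g. no event
    scenario within ``max_events``).  Carries the bound that was exhausted."""

    def __init__(self, message: str, bound: int):
        super().__init__(message)
        self.bound = bound
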