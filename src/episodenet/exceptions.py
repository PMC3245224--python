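"""Exception hierarchy for episodenet.

All package-specific errors derive from :class:`EpisodeNetError` so callers
can catch everything the library raises with a single except clause.
"""


class EpisodeNetError(Exception):
    """Base class for all episodenet errors."""


class DivergenceError(EpisodeNetError):
    """A simulated trajectory left the overflow guard region.

    Carries the integration step index at which divergence was detected.
    """

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"trajectory diverged at step {step}")


class NoCycleError(EpisodeNetError):
    """The series contains fewer than one complete cycle."""


class DegenerateInputError(EpisodeNetError, ValueError):
    """An input is degenerate for the requested estimate (e.g. constant vector)."""


class CannotConnectError(EpisodeNetError):
    """The similarity matrix does not admit a connected network."""


class InsufficientDataError(EpisodeNetError):
    """Not enough samples / cycles / values for the requested operation."""


class PipelineError(EpisodeNetError):
    """A pipeline stage failed; the message names the stage."""
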