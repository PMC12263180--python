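"""Exception types raised by the pipeline.

All errors derive from :class:`SpherostainError` so callers can catch the
package's failures with a single except clause while letting programming
errors (TypeError etc.) propagate.
"""


class SpherostainError(Exception):
    """Base class for all errors raised by spherostain."""


class EmptySpheroidError(SpherostainError):
    """Geometry generation could not place a single cell."""


class DegenerateHistogramError(SpherostainError):
    """Automatic thresholding received a constant-intensity channel."""


class EmptyRegionError(SpherostainError):
    """A background/measurement region selected by mode is empty."""


class UnstainedPerimeterError(SpherostainError):
    """The rim reference intensity is non-positive; no half-max is defined."""


class PipelineError(SpherostainError):
    """A per-spheroid failure inside the orchestrated pipeline.

    Carries the spheroid id so batch runs can report which input failed.
    """

    def __init__(self, spheroid_id: str, message: str):
        self.spheroid_id = spheroid_id
        super().__init__(f"[{spheroid_id}] {message}")
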