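"""Exception hierarchy for the GUV partitioning pipeline.

Every stage raises a subclass of :class:`GuvPartError` so callers can
distinguish pipeline outcomes (a vesicle legitimately dropped) from
programming errors.
"""


class GuvPartError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(GuvPartError, ValueError):
    """Invalid parameters or malformed inputs, caught before any work."""


class PlacementError(GuvPartError):
    """Could not place the requested number of non-overlapping vesicles."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"placed only {achieved} of {requested} vesicles without overlap; "
            "enlarge the frame or reduce n_vesicles/radii"
        )


class ClippedAnnulusError(GuvPartError):
    """Sampling annulus extends beyond the frame border."""


class NotPhaseSeparatedError(GuvPartError):
    """Lipid-channel profile shows no de-mixed (two-level) structure."""


class DegenerateArcError(GuvPartError):
    """A phase arc is shorter than the minimum after boundary exclusion."""


class ZeroSignalError(GuvPartError):
    """Construct-channel signal is zero in both phases after background removal."""


class BackgroundError(GuvPartError):
    """No usable background pixels, or a control signal at/below background."""


class CrosstalkError(GuvPartError):
    """Cross-talk matrix unusable (singular or ill-conditioned)."""
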