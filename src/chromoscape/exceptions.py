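"""Exception and warning types used across chromoscape."""


class ChromoscapeError(Exception):
    """Base class for chromoscape errors."""


class TraceFormatError(ChromoscapeError):
    """A trace table is malformed (e.g. a mandatory column is missing)."""


class ValidationError(ChromoscapeError, ValueError):
    """Input data violates a documented invariant."""


class DegenerateLandscapeWarning(UserWarning):
    """The comparison matrix carries no variance; PC scores are all zero."""


class EmptyNetworkError(ChromoscapeError):
    """Thresholding removed every edge; retry with a lower percentile."""


class OverstretchError(ChromoscapeError):
    """A FENE bond reached its maximum extension during dynamics."""

    def __init__(self, step: int, bead: int):
        self.step = step
        self.bead = bead
        super().__init__(
            f"FENE bond at bead {bead} reached maximum extension at step {step}; "
            "reduce the timestep or re-equilibrate"
        )


class WallEscapeError(ChromoscapeError):
    """A bead left the simulation box during dynamics."""

    def __init__(self, step: int, bead: int):
        self.step = step
        self.bead = bead
        super().__init__(f"bead {bead} escaped the box at step {step}")


class InitializationError(ChromoscapeError):
    """Self-avoiding chain placement failed; try a larger box."""
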