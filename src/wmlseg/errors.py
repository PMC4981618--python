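"""Exception hierarchy for wmlseg."""


class WmlsegError(Exception):
    """Base class for all wmlseg errors."""


class InputError(WmlsegError):
    """Invalid or missing input data."""


class DimensionalityError(WmlsegError):
    """Image does not have exactly three spatial axes."""


class CoregistrationError(WmlsegError):
    """Two volumes do not share the same voxel grid."""


class DegenerateInputError(WmlsegError):
    """Input carries too little structure for the requested fit."""


class EdgePeakError(WmlsegError):
    """Histogram main peak sits at the histogram edge; no half-maximum
    crossing exists on one side."""


class PhantomSpecError(WmlsegError):
    """Phantom specification cannot be realized (e.g. lesion outside WM)."""


class PipelineError(WmlsegError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
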