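"""Exception types raised by the probemap pipeline."""


class ProbemapError(Exception):
    """Base class for all probemap-specific errors."""


class EmptyReference(ProbemapError):
    """The wide-field reference image yielded no keypoints (flat/textureless)."""


class EmptyFrame(ProbemapError):
    """A surface frame yielded no keypoints after masking."""


class DegenerateGeometry(ProbemapError):
    """Rigid estimation impossible: correspondence geometry is degenerate
    (e.g. all sampled point pairs coincident)."""


class MosaicFull(ProbemapError):
    """The mosaic already holds the maximum number of frames."""


class InsufficientOverlap(ProbemapError):
    """A frame could not be registered to the mosaic composite (gate rejected)."""


class PatchTooLarge(ProbemapError):
    """Requested heatmap patch exceeds the frame dimensions."""


class OpenPath(ProbemapError):
    """A margin polyline expected to be closed is open."""


class PathOutOfBounds(ProbemapError):
    """A simulated probe path would place the surface FOV outside the phantom."""


class SchemaError(ProbemapError):
    """A session file failed schema validation.

    Attributes
    ----------
    pointer : str
        JSON-pointer-style path of the offending field, e.g. ``/frames/3/pose``.
    """

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")
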