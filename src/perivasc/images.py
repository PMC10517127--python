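"""En-face image containers and quadrant geometry.

The analysis operates on paired en-face projections of a deep-capillary-plexus
slab: a structural OCT intensity image and an OCT-angiography (flow) image of
identical geometry, nominally 320 x 320 pixels covering 3.0 x 3.0 mm.  Images
are split into four equal corner quadrants; quadrant labels follow a row-major
convention with the origin at the top-left:

    Q1 | Q2        Q1 = top-left,  Q2 = top-right,
    ---+---        Q3 = bottom-left, Q4 = bottom-right.
    Q3 | Q4

Pixel pitch is ``extent_mm * 1000 / side_px`` micrometres (9.375 um for the
nominal geometry).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InputError


class Modality(str, enum.Enum):
    """Acquisition modality of an en-face image."""

    STRUCTURAL = "structural"
    ANGIOGRAPHY = "angiography"


class Quadrant(str, enum.Enum):
    """Corner quadrant of an en-face image (row-major, origin top-left)."""

    Q1 = "Q1"  # top-left
    Q2 = "Q2"  # top-right
    Q3 = "Q3"  # bottom-left
    Q4 = "Q4"  # bottom-right

    @property
    def opposite(self) -> "Quadrant":
        """Diagonally opposite quadrant (default contralateral rule)."""
        return _OPPOSITE[self]


_OPPOSITE = {
    Quadrant.Q1: Quadrant.Q4,
    Quadrant.Q2: Quadrant.Q3,
    Quadrant.Q3: Quadrant.Q2,
    Quadrant.Q4: Quadrant.Q1,
}

QUADRANT_ORDER = (Quadrant.Q1, Quadrant.Q2, Quadrant.Q3, Quadrant.Q4)


@dataclass
class EnFaceImage:
    """One 2-D grayscale en-face raster with physical extent and quality.

    Parameters
    ----------
    pixels:
        Square 2-D array of intensities in [0, 255], even side length.
    modality:
        ``structural`` (reflectivity) or ``angiography`` (flow signal).
    extent_mm:
        Physical side length of the field of view in millimetres.
    quality:
        Device-reported image quality score, if available.
    """

    pixels: np.ndarray
    modality: Modality
    extent_mm: float = 3.0
    quality: float | None = None
    eye_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if isinstance(self.modality, str):
            self.modality = Modality(self.modality)
        if self.pixels.ndim != 2:
            raise GeometryError(
                f"en-face image must be 2-D, got {self.pixels.ndim}-D"
            )
        h, w = self.pixels.shape
        if h != w:
            raise GeometryError(f"en-face image must be square, got {h}x{w}")
        if h % 2 != 0:
            raise GeometryError(
                f"side length must be even for quadrant splitting, got {h}"
            )
        if self.pixels.size and (
            float(self.pixels.min()) < 0 or float(self.pixels.max()) > 255
        ):
            raise InputError("intensities must lie within [0, 255]")
        if not self.extent_mm > 0:
            raise InputError(f"extent_mm must be positive, got {self.extent_mm}")

    @property
    def side_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def pitch_um(self) -> float:
        """Pixel pitch in micrometres."""
        return self.extent_mm * 1000.0 / self.side_px

    def quadrant_slices(self, quadrant: Quadrant) -> tuple[slice, slice]:
        """Row/column slices selecting one corner quadrant."""
        h = self.side_px // 2
        rows = slice(0, h) if quadrant in (Quadrant.Q1, Quadrant.Q2) else slice(h, 2 * h)
        cols = slice(0, h) if quadrant in (Quadrant.Q1, Quadrant.Q3) else slice(h, 2 * h)
        return rows, cols

    def quadrant(self, quadrant: Quadrant) -> np.ndarray:
        """View of one corner quadrant of the pixel raster."""
        rows, cols = self.quadrant_slices(quadrant)
        return self.pixels[rows, cols]


def quadrant_mask(side_px: int, quadrant: Quadrant) -> np.ndarray:
    """Boolean mask (side_px x side_px) selecting one corner quadrant."""
    if side_px % 2 != 0:
        raise GeometryError(f"side length must be even, got {side_px}")
    mask = np.zeros((side_px, side_px), dtype=bool)
    h = side_px // 2
    rows = slice(0, h) if quadrant in (Quadrant.Q1, Quadrant.Q2) else slice(h, 2 * h)
    cols = slice(0, h) if quadrant in (Quadrant.Q1, Quadrant.Q3) else slice(h, 2 * h)
    mask[rows, cols] = True
    return mask


def split_quadrants(image: EnFaceImage) -> list[tuple[Quadrant, np.ndarray]]:
    """Split an en-face image into its four corner quadrants.

    Returns ``[(Q1, a), (Q2, b), (Q3, c), (Q4, d)]`` in row-major order.
    Concatenating the four blocks reassembles the input exactly.
    """
    return [(q, image.quadrant(q).copy()) for q in QUADRANT_ORDER]


def reassemble_quadrants(parts: dict[Quadrant, np.ndarray]) -> np.ndarray:
    """Inverse of :func:`split_quadrants` (used by the reassembly check)."""
    top = np.hstack([parts[Quadrant.Q1], parts[Quadrant.Q2]])
    bottom = np.hstack([parts[Quadrant.Q3], parts[Quadrant.Q4]])
    return np.vstack([top, bottom])
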