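"""Secondary OCTA quantifications: vessel density and FAZ morphometrics.

Vessel density is the percentage of above-threshold ("white") pixels after
mean-threshold binarization of the OCTA frame, with the foveal avascular
zone (FAZ) excluded from both the threshold statistics and the pixel count.
FAZ morphometrics (area, perimeter, circularity) are computed from a
supplied binary FAZ mask; automatic FAZ segmentation is out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import EmptyMaskError, GeometryError, InputError
from .images import EnFaceImage

logger = logging.getLogger(__name__)


@dataclass
class FazMask:
    """Binary foveal-avascular-zone mask aligned to the OCTA raster."""

    mask: np.ndarray
    provenance: str = "supplied"  # "supplied" | "synthetic"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise GeometryError("FAZ mask must be 2-D")
        if self.provenance not in ("supplied", "synthetic"):
            raise InputError(f"unknown FAZ provenance {self.provenance!r}")
        if self.mask.any():
            _, n = ndimage.label(self.mask)
            center = self.mask[self.mask.shape[0] // 2, self.mask.shape[1] // 2]
            if n > 1 or not center:
                warnings.warn(
                    "FAZ mask is expected to be a single connected region "
                    "containing the image center",
                    stacklevel=2,
                )

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class VesselMetrics:
    """Per-eye vascular summary appended to the tidy output table."""

    vessel_density_pct: float
    faz_area_mm2: float
    faz_perimeter_mm: float
    faz_circularity: float


def vessel_density(octa: EnFaceImage, faz: FazMask | None = None) -> float:
    """Percent of above-mean-threshold OCTA pixels outside the FAZ.

    The threshold is the plain arithmetic mean of the in-scope (non-FAZ)
    pixels — the classical automatic "Mean" threshold — applied strictly.
    FAZ exclusion affects both the threshold statistics and the denominator.
    """
    pixels = np.asarray(octa.pixels, dtype=float)
    if faz is not None:
        if faz.mask.shape != pixels.shape:
            raise GeometryError("FAZ mask and OCTA image must have identical shape")
        pixels = pixels[~faz.mask]
    if pixels.size == 0:
        raise InputError("FAZ mask covers the entire image; no pixels to measure")
    threshold = pixels.mean()
    if pixels.max() == pixels.min():
        warnings.warn(
            "constant OCTA region: vessel density is 0 under a strict mean "
            "threshold",
            stacklevel=2,
        )
        return 0.0
    return float(100.0 * np.mean(pixels > threshold))


def _marching_squares_perimeter_px(mask: np.ndarray) -> float:
    """Sub-pixel boundary length: marching-squares contour polyline length.

    The mask is padded by one background pixel so regions touching the frame
    edge still yield closed contours; the 0.5-level contours of the binary
    image are extracted and their polyline lengths summed.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    return float(
        sum(
            np.sqrt(((c[1:] - c[:-1]) ** 2).sum(axis=1)).sum()
            for c in contours
        )
    )


def faz_metrics(
    faz: FazMask,
    extent_mm: float = 3.0,
    side_px: int | None = None,
    perimeter_estimator: str = "marching_squares",
) -> tuple[float, float, float]:
    """FAZ area (mm^2), perimeter (mm) and circularity from a binary mask.

    ``circularity = 4 * pi * area / perimeter**2`` — 1 for an ideal disc,
    smaller for elongated or irregular regions.  The perimeter estimator is
    a package convention (device software estimators vary), so absolute
    circularities are comparable within, not across, pipelines:

    - ``"marching_squares"`` (default): 0.5-level contour polyline length;
    - ``"crofton"``: Crofton-formula perimeter (4 directions).
    """
    if faz.area_px == 0:
        raise EmptyMaskError("FAZ mask is empty")
    side = side_px if side_px is not None else faz.mask.shape[0]
    pitch_mm = extent_mm / side
    area_mm2 = faz.area_px * pitch_mm**2
    if perimeter_estimator == "marching_squares":
        per_px = _marching_squares_perimeter_px(faz.mask)
    elif perimeter_estimator == "crofton":
        per_px = float(measure.perimeter_crofton(faz.mask, directions=4))
    else:
        raise InputError(f"unknown perimeter estimator {perimeter_estimator!r}")
    perimeter_mm = per_px * pitch_mm
    circularity = 4.0 * np.pi * area_mm2 / perimeter_mm**2
    return float(area_mm2), float(perimeter_mm), float(circularity)


def vessel_metrics(
    octa: EnFaceImage, faz: FazMask, perimeter_estimator: str = "marching_squares"
) -> VesselMetrics:
    """Bundle vessel density and FAZ morphometrics for one eye."""
    density = vessel_density(octa, faz)
    area, perimeter, circ = faz_metrics(
        faz, octa.extent_mm, octa.side_px, perimeter_estimator
    )
    return VesselMetrics(
        vessel_density_pct=density,
        faz_area_mm2=area,
        faz_perimeter_mm=perimeter,
        faz_circularity=circ,
    )
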