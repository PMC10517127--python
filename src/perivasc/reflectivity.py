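"""Corrected perivascular reflectivity from paired en-face OCT / OCTA images.

The metric proxies how bright the tissue around definitely-perfused vessels
appears on structural OCT.  Pipeline, per analyzed quadrant:

1. the OCTA quadrant is binarized at ``mean + 2 * SD`` of its own pixel
   values (sample SD by default);
2. connected components smaller than ``min_particle_px`` pixels (default 3,
   about 28 um at the nominal 3 mm / 320 px geometry) are discarded; the
   surviving pixels form the high-signal-strength (HSS) mask — OCTA signal
   so strong that flow there is considered definite and abundant;
3. the HSS mask is transferred onto the co-registered structural image and
   the mean structural intensity over the mask is taken;
4. that mean is divided by the mean intensity of the FULL structural en-face
   image, yielding the corrected perivascular reflectivity — a dimensionless
   ratio invariant to uniform intensity gain.

Eyes whose scans fall below a device quality score of 65 are excluded before
any measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import (
    DegenerateImageError,
    EmptyMaskError,
    GeometryError,
    InputError,
    ParameterError,
)
from .images import EnFaceImage, Modality, Quadrant

logger = logging.getLogger(__name__)

MIN_IMAGE_QUALITY = 65.0


@dataclass
class HSSMask:
    """High-signal-strength mask plus the threshold and particle census.

    Attributes
    ----------
    mask:
        Boolean array, True where OCTA signal survived thresholding and
        particle filtering.
    threshold:
        The mean + 2 SD binarization threshold that produced the mask.
    particle_count:
        Number of retained connected components.
    hss_area_px:
        Number of True pixels (sum of retained component areas).
    min_particle_px:
        Minimum component area retained (inclusive).
    connectivity:
        4 or 8 (pixel neighbourhood used for component labelling).
    """

    mask: np.ndarray
    threshold: float
    particle_count: int
    hss_area_px: int
    min_particle_px: int = 3
    connectivity: int = 8


@dataclass
class ReflectivityResult:
    """Per-quadrant reflectivity bundle (one row of the tidy output)."""

    mean_on_hss: float
    overall_mean: float
    corrected: float
    threshold: float
    hss_area_px: int
    particle_count: int
    quadrant: Quadrant


def compute_threshold(quadrant: np.ndarray, sd_ddof: int = 1) -> float:
    """Mean + 2 SD binarization threshold of a pixel block.

    ``sd_ddof=1`` (sample SD, the default) matches common imaging-software
    statistics; ``sd_ddof=0`` selects the population SD.
    """
    quadrant = np.asarray(quadrant, dtype=float)
    if quadrant.size == 0:
        raise InputError("cannot compute a threshold on an empty pixel block")
    if sd_ddof not in (0, 1):
        raise ParameterError(f"sd_ddof must be 0 or 1, got {sd_ddof}")
    if quadrant.size == 1 and sd_ddof == 1:
        raise InputError("sample SD undefined for a single pixel")
    return float(quadrant.mean() + 2.0 * quadrant.std(ddof=sd_ddof))


def binarize(quadrant: np.ndarray, threshold: float, strict: bool = True) -> np.ndarray:
    """Threshold a pixel block into a boolean mask.

    Strict comparison (``pixel > threshold``) is the default so that a
    constant image yields an empty mask rather than an all-true one.
    """
    if not np.isfinite(threshold):
        raise ParameterError(f"threshold must be finite, got {threshold}")
    quadrant = np.asarray(quadrant, dtype=float)
    return quadrant > threshold if strict else quadrant >= threshold


def filter_particles(
    mask: np.ndarray,
    min_particle_px: int = 3,
    connectivity: int = 8,
    threshold: float = float("nan"),
) -> HSSMask:
    """Retain connected components of area >= ``min_particle_px`` pixels.

    Emulates an "analyze particles" size filter: particle-like objects of
    fewer than ``min_particle_px`` connected pixels are treated as noise and
    dropped.  8-connectivity (edge or corner contact) is the default.
    """
    if min_particle_px < 1:
        raise ParameterError(f"min_particle_px must be >= 1, got {min_particle_px}")
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    # skimage: connectivity 1 = orthogonal neighbours (4), 2 = + diagonals (8)
    labels, n_raw = measure.label(
        mask, connectivity=1 if connectivity == 4 else 2, return_num=True
    )
    if n_raw == 0:
        kept = np.zeros_like(mask)
        return HSSMask(kept, float(threshold), 0, 0, min_particle_px, connectivity)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0  # background
    keep_labels = np.flatnonzero(sizes >= min_particle_px)
    kept = np.isin(labels, keep_labels) if keep_labels.size else np.zeros_like(mask)
    return HSSMask(
        mask=kept,
        threshold=float(threshold),
        particle_count=int(keep_labels.size),
        hss_area_px=int(kept.sum()),
        min_particle_px=min_particle_px,
        connectivity=connectivity,
    )


def mean_reflectivity_on_mask(structural_quadrant: np.ndarray, hss: HSSMask) -> float:
    """Mean structural intensity over the HSS pixels of one quadrant."""
    structural_quadrant = np.asarray(structural_quadrant, dtype=float)
    if structural_quadrant.shape != hss.mask.shape:
        raise GeometryError(
            f"structural quadrant {structural_quadrant.shape} and HSS mask "
            f"{hss.mask.shape} have different shapes"
        )
    if hss.hss_area_px == 0:
        raise EmptyMaskError(
            "no HSS area: no particle survived thresholding and size filtering"
        )
    return float(structural_quadrant[hss.mask].mean())


def corrected_reflectivity(
    structural_image: EnFaceImage,
    octa_image: EnFaceImage,
    quadrant: Quadrant,
    *,
    min_particle_px: int = 3,
    connectivity: int = 8,
    sd_ddof: int = 1,
    threshold_scope: str = "quadrant",
    overall_scope: str = "image",
    strict_threshold: bool = True,
) -> ReflectivityResult:
    """Corrected perivascular reflectivity of one quadrant of an eye.

    Composition of :func:`compute_threshold`, :func:`binarize`,
    :func:`filter_particles` and :func:`mean_reflectivity_on_mask`; the
    result is ``mean_on_hss / overall_mean``.

    Parameters
    ----------
    threshold_scope:
        ``"quadrant"`` (default): threshold statistics from the analyzed
        OCTA quadrant; ``"image"``: from the full OCTA frame.
    overall_scope:
        ``"image"`` (default): denominator is the mean of the full
        structural frame; ``"quadrant"``: of the analyzed quadrant only.
    """
    if structural_image.modality is not Modality.STRUCTURAL:
        raise InputError("first image must be the structural en-face OCT")
    if octa_image.modality is not Modality.ANGIOGRAPHY:
        raise InputError("second image must be the OCT-angiography frame")
    if structural_image.pixels.shape != octa_image.pixels.shape:
        raise GeometryError("structural and OCTA images must have identical shape")
    if threshold_scope not in ("quadrant", "image"):
        raise ParameterError(f"unknown threshold_scope {threshold_scope!r}")
    if overall_scope not in ("quadrant", "image"):
        raise ParameterError(f"unknown overall_scope {overall_scope!r}")

    octa_q = octa_image.quadrant(quadrant)
    thr_src = octa_image.pixels if threshold_scope == "image" else octa_q
    threshold = compute_threshold(thr_src, sd_ddof=sd_ddof)
    raw = binarize(octa_q, threshold, strict=strict_threshold)
    hss = filter_particles(raw, min_particle_px, connectivity, threshold=threshold)

    struct_q = structural_image.quadrant(quadrant)
    mean_on_hss = mean_reflectivity_on_mask(struct_q, hss)

    overall_src = (
        structural_image.pixels if overall_scope == "image" else struct_q
    )
    overall_mean = float(np.asarray(overall_src, dtype=float).mean())
    if overall_mean == 0.0:
        raise DegenerateImageError(
            "overall structural mean is zero; corrected reflectivity undefined"
        )
    return ReflectivityResult(
        mean_on_hss=mean_on_hss,
        overall_mean=overall_mean,
        corrected=mean_on_hss / overall_mean,
        threshold=threshold,
        hss_area_px=hss.hss_area_px,
        particle_count=hss.particle_count,
        quadrant=quadrant,
    )


def quality_gate(image: EnFaceImage, min_quality: float = MIN_IMAGE_QUALITY) -> bool:
    """True iff the image meets the minimum device quality score (>= 65)."""
    if image.quality is None:
        raise InputError(
            f"image {image.eye_id or '<unnamed>'} has no quality score; "
            "cannot apply the quality gate"
        )
    passed = image.quality >= min_quality
    if not passed:
        logger.info(
            "quality gate: excluding %s (quality %.1f < %.1f)",
            image.eye_id or "<unnamed>",
            image.quality,
            min_quality,
        )
    return passed


def particle_width_um(n_px: int, extent_mm: float, side_px: int) -> float:
    """Physical width of ``n_px`` consecutive pixels, in micrometres.

    At the nominal 3.0 mm / 320 px geometry, 3 px is 28.125 um — the minimum
    particle extent retained by the default size filter.
    """
    if side_px <= 0:
        raise ParameterError(f"side_px must be positive, got {side_px}")
    return n_px * (extent_mm * 1000.0 / side_px)
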