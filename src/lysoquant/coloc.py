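"""Colocalization statistics and derived biological scores.

Implements pixel-wise Pearson correlation and thresholded Manders
coefficients (the JACoP-style intensity-weighted fractions over binarized
masks), the binary-AND overlap used for object colocalization, the
lysosomal-membrane-permeabilization (LMP) score — the fraction of
lysosomal-enzyme signal found *outside* lysosomes — and the yellow/red
classification of the tandem mCherry-GFP autophagy reporter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .imgproc import detect_puncta
from .types import BinaryMask, CellROI, ValidationError

__all__ = [
    "ColocResult",
    "LMPResult",
    "ReporterResult",
    "binary_and",
    "pearson_r",
    "manders",
    "lmp_score",
    "lmp_score_intensity",
    "classify_tandem",
    "verify_compartment",
]


@dataclass
class ColocResult:
    pearson_r: float
    manders_m1: float  # fraction of A signal overlapping B
    manders_m2: float  # fraction of B signal overlapping A
    overlap_area_px: int


@dataclass
class LMPResult:
    total_catd_area_px: float
    lysosomal_catd_area_px: float
    cytosolic_fraction: float


@dataclass
class ReporterResult:
    """Tandem-reporter readout.

    ``yellow_area_px`` and ``red_area_px`` partition the raw mCherry-positive
    area exactly (yellow + red = total mCherry); the counts and the
    ``*_filtered`` areas refer to connected components surviving the puncta
    size filter.
    """

    yellow_count: int
    red_count: int
    yellow_area_px: int
    red_area_px: int
    yellow_area_filtered_px: int = 0
    red_area_filtered_px: int = 0


def binary_and(mask_a: BinaryMask, mask_b: BinaryMask) -> BinaryMask:
    """Pixelwise conjunction of two masks (the ImageCalculator AND)."""
    if mask_a.shape != mask_b.shape:
        raise ValidationError("mask shapes differ")
    return BinaryMask(mask_a.pixels & mask_b.pixels)


def pearson_r(
    plane_a: np.ndarray, plane_b: np.ndarray, roi: BinaryMask
) -> float:
    """Pearson correlation of paired pixel intensities within an ROI.

    Returns NaN (with a warning) when either channel is constant within the
    ROI, where the coefficient is undefined.
    """
    plane_a = np.asarray(plane_a, dtype=float)
    plane_b = np.asarray(plane_b, dtype=float)
    if plane_a.shape != plane_b.shape or plane_a.shape != roi.shape:
        raise ValidationError("plane and ROI shapes differ")
    a = plane_a[roi.pixels]
    b = plane_b[roi.pixels]
    if a.size < 2:
        raise ValidationError("ROI must contain at least 2 pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant plane within ROI: Pearson r undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def manders(
    plane_a: np.ndarray,
    plane_b: np.ndarray,
    mask_a: BinaryMask,
    mask_b: BinaryMask,
) -> tuple[float, float]:
    """Thresholded Manders coefficients (M1, M2).

    M1 is the fraction of channel-A intensity (within its own mask) that
    falls on pixels also positive for channel B; M2 is the symmetric
    fraction for channel B.  Restricting the numerator to ``mask_a & mask_b``
    keeps both coefficients in [0, 1].  A zero denominator (no signal in a
    channel's mask) yields NaN with a warning.
    """
    plane_a = np.asarray(plane_a, dtype=float)
    plane_b = np.asarray(plane_b, dtype=float)
    if mask_a.shape != mask_b.shape:
        raise ValidationError("mask shapes differ")
    overlap = mask_a.pixels & mask_b.pixels

    def _coef(plane, own, other_name):
        denom = float(plane[own].sum())
        if denom == 0.0:
            warnings.warn(
                f"no signal in {other_name} mask: Manders coefficient undefined",
                stacklevel=3,
            )
            return float("nan")
        return float(plane[overlap].sum() / denom)

    m1 = _coef(plane_a, mask_a.pixels, "channel-A")
    m2 = _coef(plane_b, mask_b.pixels, "channel-B")
    return m1, m2


def lmp_score(
    catd_mask: BinaryMask, lamp2_mask: BinaryMask, cell: Optional[CellROI] = None
) -> Optional[LMPResult]:
    """Area-based LMP score: non-lysosomal fraction of the enzyme mask.

    The lysosomal enzyme area is the binary AND of the enzyme mask with the
    lysosome-membrane mask; the cytosolic fraction is what remains of the
    total enzyme area after subtracting it.  Cells with no enzyme signal are
    excluded (None, with a warning) rather than scored 0.
    """
    if cell is not None:
        cm = cell.cell_mask
        catd_mask = BinaryMask(catd_mask.pixels & cm.pixels)
        lamp2_mask = BinaryMask(lamp2_mask.pixels & cm.pixels)
    total = catd_mask.area_px
    if total == 0:
        warnings.warn("cell has no enzyme-channel signal: LMP score undefined", stacklevel=2)
        return None
    lyso = binary_and(catd_mask, lamp2_mask).area_px
    return LMPResult(
        total_catd_area_px=float(total),
        lysosomal_catd_area_px=float(lyso),
        cytosolic_fraction=float((total - lyso) / total),
    )


def lmp_score_intensity(
    catd_plane: np.ndarray,
    lamp2_mask: BinaryMask,
    cell: CellROI,
    dilate_px: int = 6,
    background: Optional[float] = None,
) -> Optional[LMPResult]:
    """Intensity-weighted LMP score with local cytosolic-background subtraction.

    The lysosomal component integrates the enzyme intensity over the
    lysosome mask dilated by ``dilate_px`` (to capture the PSF tails of
    lysosome-confined spots), after subtracting the median cytosolic level
    so that genuinely diffuse signal under lysosomes is not attributed to
    them.  The total integrates the background-corrected intensity over the
    whole cell; ``background`` defaults to the mean intensity outside the
    cell (the camera/noise floor).
    """
    plane = np.asarray(catd_plane, dtype=float)
    cm = cell.cell_mask.pixels
    if plane.shape != cm.shape:
        raise ValidationError("plane and cell mask shapes differ")
    dil = ndimage.binary_dilation(
        lamp2_mask.pixels, iterations=max(dilate_px, 0)
    ) if dilate_px > 0 else lamp2_mask.pixels
    dil = dil & cm
    # cytosolic reference region: cytoplasm proper (no nucleus, no lysosome
    # neighbourhoods), eroded away from the cell rim where PSF blur dims the
    # diffuse plateau
    cyto_core = ndimage.binary_erosion(cell.cytoplasm_mask.pixels, iterations=3)
    cyto = cyto_core & ~dil
    if background is None:
        outside = ~cm
        background = float(plane[outside].mean()) if outside.any() else 0.0
    total = float((plane[cm] - background).sum())
    if total <= 0:
        warnings.warn("cell has no enzyme-channel signal: LMP score undefined", stacklevel=2)
        return None
    diffuse_level = float(plane[cyto].mean()) if cyto.any() else background
    # summed unclipped so zero-mean noise cancels; clamped to [0, total] at the end
    lyso = float((plane[dil] - diffuse_level).sum())
    lyso = min(max(lyso, 0.0), total)
    return LMPResult(
        total_catd_area_px=total,
        lysosomal_catd_area_px=lyso,
        cytosolic_fraction=float(1.0 - lyso / total),
    )


def classify_tandem(
    gfp_mask: BinaryMask, mcherry_mask: BinaryMask, min_area_px: int = 10
) -> ReporterResult:
    """Yellow/red dot classification of the tandem autophagy reporter.

    Yellow (autophagosome) pixels are mCherry AND GFP; red (autolysosome)
    pixels are the remaining mCherry-positive pixels, so the two areas
    partition the mCherry mask exactly.  Counts apply the same
    connected-component size filter as puncta detection.
    """
    yellow = binary_and(gfp_mask, mcherry_mask)
    red = BinaryMask(mcherry_mask.pixels & ~yellow.pixels)
    ypuncta = detect_puncta(yellow, min_area_px=min_area_px, channel="yellow")
    rpuncta = detect_puncta(red, min_area_px=min_area_px, channel="red")
    return ReporterResult(
        yellow_count=ypuncta.count,
        red_count=rpuncta.count,
        yellow_area_px=yellow.area_px,
        red_area_px=red.area_px,
        yellow_area_filtered_px=ypuncta.total_area_px,
        red_area_filtered_px=rpuncta.total_area_px,
    )


def verify_compartment(
    catd_nonlyso_mask: BinaryMask, organelle_masks: dict[str, BinaryMask]
) -> dict[str, float]:
    """Overlap fractions of the non-lysosomal enzyme mask with other organelles.

    Purely descriptive: for each named organelle mask, the fraction of the
    non-lysosomal mask area that co-stains with it.  An empty non-lysosomal
    mask yields 0 for every organelle.
    """
    area = catd_nonlyso_mask.area_px
    report = {}
    for name, om in organelle_masks.items():
        if om.shape != catd_nonlyso_mask.shape:
            raise ValidationError(f"organelle mask {name!r} shape differs")
        if area == 0:
            report[name] = 0.0
        else:
            report[name] = float(
                (catd_nonlyso_mask.pixels & om.pixels).sum() / area
            )
    return report
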