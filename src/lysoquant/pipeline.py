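"""Field-level drivers tying the per-cell operations together.

Each driver takes a :class:`MultiChannelImage` plus segmented cell ROIs and
returns tidy per-cell tables, mirroring the manual workflow: denoise,
threshold inside the cell mask, binarize, size-filter, measure.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import pandas as pd

from . import coloc as _coloc
from . import imgproc, positioning
from .types import BinaryMask, CellROI, MultiChannelImage, PunctaSet

__all__ = [
    "segment_channel",
    "quantify_puncta",
    "quantify_coloc",
    "quantify_tandem",
    "quantify_position",
]

DEFAULT_DOG = (1.0, 4.0)


def segment_channel(
    image: MultiChannelImage,
    channel: str,
    roi: Optional[CellROI] = None,
    method: str = "isodata",
    dog_sigmas: Optional[tuple[float, float]] = DEFAULT_DOG,
    fixed_value: Optional[float] = None,
) -> BinaryMask:
    """Denoise (DoG) and threshold one channel, optionally within a cell."""
    plane = image.plane(channel)
    if dog_sigmas is not None:
        plane = imgproc.dog_denoise(plane, *dog_sigmas)
    roi_mask = roi.cell_mask if roi is not None else None
    return imgproc.threshold(
        plane, method=method, fixed_value=fixed_value, roi=roi_mask,
        origin_channel=channel,
    )


def quantify_puncta(
    image: MultiChannelImage,
    rois: Sequence[CellROI],
    channels: Sequence[str] = ("puncta_a", "puncta_b"),
    min_area_px: int = 10,
    method: str = "isodata",
    dog_sigmas: Optional[tuple[float, float]] = DEFAULT_DOG,
    connectivity: int = 8,
) -> tuple[pd.DataFrame, dict[tuple[str, str], PunctaSet]]:
    """Per-cell puncta counts and areas for the requested channels."""
    rows = []
    sets: dict[tuple[str, str], PunctaSet] = {}
    for roi in rois:
        for channel in channels:
            mask = segment_channel(image, channel, roi, method=method, dog_sigmas=dog_sigmas)
            puncta = imgproc.detect_puncta(
                mask, min_area_px=min_area_px, connectivity=connectivity,
                channel=channel, cell_id=roi.cell_id,
            )
            sets[(roi.cell_id, channel)] = puncta
            row = imgproc.puncta_per_cell(puncta, roi, image.pixel_size_um)
            row["threshold"] = mask.threshold
            rows.append(row)
    return pd.DataFrame(rows), sets


def quantify_coloc(
    image: MultiChannelImage,
    rois: Sequence[CellROI],
    channel_a: str = "puncta_a",
    channel_b: str = "puncta_b",
    min_area_px: int = 10,
    method: str = "isodata",
    dog_sigmas: Optional[tuple[float, float]] = DEFAULT_DOG,
    lmp_variant: str = "area",
) -> pd.DataFrame:
    """Per-cell Pearson/Manders colocalization and LMP score.

    Pearson is computed on the raw intensities within the whole-cell mask;
    Manders on raw intensities over the thresholded masks.  The LMP score
    is area-based by default (``lmp_variant='intensity'`` selects the
    background-corrected intensity-weighted variant).
    """
    rows = []
    for roi in rois:
        mask_a = segment_channel(image, channel_a, roi, method=method, dog_sigmas=dog_sigmas)
        mask_b = segment_channel(image, channel_b, roi, method=method, dog_sigmas=dog_sigmas)
        plane_a = image.plane(channel_a)
        plane_b = image.plane(channel_b)
        cell_mask = roi.cell_mask
        r = _coloc.pearson_r(plane_a, plane_b, cell_mask)
        m1, m2 = _coloc.manders(plane_a, plane_b, mask_a, mask_b)
        overlap = _coloc.binary_and(mask_a, mask_b).area_px
        if lmp_variant == "intensity":
            lmp = _coloc.lmp_score_intensity(plane_b, mask_a, roi)
        else:
            lmp = _coloc.lmp_score(mask_b, mask_a, roi)
        rows.append(
            {
                "cell_id": roi.cell_id,
                "animal_id": roi.animal_id,
                "group_id": roi.group_id,
                "pearson_r": r,
                "m1": m1,
                "m2": m2,
                "overlap_area_px": overlap,
                "total_catd": lmp.total_catd_area_px if lmp else float("nan"),
                "lysosomal_catd": lmp.lysosomal_catd_area_px if lmp else float("nan"),
                "cytosolic_fraction": lmp.cytosolic_fraction if lmp else float("nan"),
                "threshold_a": mask_a.threshold,
                "threshold_b": mask_b.threshold,
            }
        )
    return pd.DataFrame(rows)


def quantify_tandem(
    image: MultiChannelImage,
    roi: Optional[CellROI] = None,
    gfp_channel: str = "gfp",
    mcherry_channel: str = "mcherry",
    min_area_px: int = 10,
    method: str = "isodata",
    dog_sigmas: Optional[tuple[float, float]] = DEFAULT_DOG,
) -> _coloc.ReporterResult:
    """Yellow/red classification of a tandem-reporter cell.

    Without a segmented ROI the cell mask is derived by thresholding the
    cell-body channel (in place of manual cell selection).
    """
    if roi is None:
        cell_mask = imgproc.threshold(
            image.plane("cell"), method=method, origin_channel="cell"
        )
        roi = CellROI(
            cell_id="cell00",
            cytoplasm_mask=cell_mask,
            nucleus_mask=BinaryMask(cell_mask.pixels & False),
        )
    gfp = segment_channel(image, gfp_channel, roi, method=method, dog_sigmas=dog_sigmas)
    mch = segment_channel(image, mcherry_channel, roi, method=method, dog_sigmas=dog_sigmas)
    return _coloc.classify_tandem(gfp, mch, min_area_px=min_area_px)


def quantify_position(
    image: MultiChannelImage,
    rois: Sequence[CellROI],
    channel: str = "puncta_a",
    min_ratio: float = 2.0,
    mean_radius_kind: str = "arithmetic",
    min_area_px: int = 10,
    method: str = "isodata",
    dog_sigmas: Optional[tuple[float, float]] = DEFAULT_DOG,
) -> tuple[pd.DataFrame, list[positioning.PositioningResult]]:
    """Lysosome-to-nucleus-border distances for area-gated cells."""
    results = []
    frames = []
    for roi in rois:
        gate = positioning.area_gate(roi, min_ratio=min_ratio)
        if not gate:
            warnings.warn(
                f"{roi.cell_id}: cytoplasm:nucleus ratio below {min_ratio}, skipped",
                stacklevel=2,
            )
            continue
        ellipse = positioning.fit_nucleus_ellipse(
            roi.nucleus_mask, mean_radius_kind=mean_radius_kind
        )
        mask = segment_channel(image, channel, roi, method=method, dog_sigmas=dog_sigmas)
        puncta = imgproc.detect_puncta(
            mask, min_area_px=min_area_px, channel=channel, cell_id=roi.cell_id
        )
        res = positioning.lysosome_distances(
            puncta, ellipse, image.pixel_size_um, cell_id=roi.cell_id, gate_passed=True
        )
        results.append(res)
        t = res.table.copy()
        t.insert(0, "cell_id", roi.cell_id)
        t.insert(1, "animal_id", roi.animal_id)
        frames.append(t)
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "cell_id", "animal_id", "label",
                "distance_to_center_px", "distance_to_border_px", "distance_to_border_um",
            ]
        )
    )
    return table, results
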