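"""Lysosome-to-nucleus positioning analysis.

The nuclear ROI is reduced to its moment-equivalent ellipse; each
lysosome's distance to the nucleus border is defined as the Euclidean
distance from its centroid to the ellipse centre minus the ellipse's mean
radius (a + b)/2 — the subtraction convention, not the true point-to-
boundary distance.  Cells are admitted only when the cytoplasm:nucleus
area ratio passes a 2:1 gate, preventing bias from cells with little
visible cytoplasm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from skimage import measure

from .types import BinaryMask, CellROI, PunctaSet, ValidationError

__all__ = [
    "NucleusEllipse",
    "PositioningResult",
    "fit_nucleus_ellipse",
    "area_gate",
    "lysosome_distances",
    "positioning_summary",
]


@dataclass
class NucleusEllipse:
    """Moment-equivalent ellipse of a nuclear mask."""

    center: tuple[float, float]  # (row, col)
    semi_axis_major: float
    semi_axis_minor: float
    orientation: float  # radians, skimage convention
    mean_radius_kind: Literal["arithmetic", "geometric"] = "arithmetic"

    @property
    def mean_radius(self) -> float:
        a, b = self.semi_axis_major, self.semi_axis_minor
        if self.mean_radius_kind == "geometric":
            return math.sqrt(a * b)
        return 0.5 * (a + b)


@dataclass
class PositioningResult:
    """Per-lysosome distances for one cell."""

    table: pd.DataFrame  # label, distance_to_center_px, distance_to_border_px/um
    cell_id: str
    gate_passed: bool


def fit_nucleus_ellipse(
    nucleus_mask: BinaryMask,
    mean_radius_kind: Literal["arithmetic", "geometric"] = "arithmetic",
) -> NucleusEllipse:
    """Fit the ellipse with the region's centroid and second central moments.

    Semi-axes are 2*sqrt(eigenvalue) of the central second-moment matrix,
    which for a filled ellipse recovers its true semi-axes.  The mask must
    be non-empty and a single connected component.
    """
    if not nucleus_mask.pixels.any():
        raise ValidationError("nucleus mask is empty")
    labels = measure.label(nucleus_mask.pixels, connectivity=2)
    if labels.max() != 1:
        raise ValidationError("nucleus mask must be a single connected component")
    rp = measure.regionprops(labels)[0]
    return NucleusEllipse(
        center=(float(rp.centroid[0]), float(rp.centroid[1])),
        semi_axis_major=float(rp.axis_major_length) / 2.0,
        semi_axis_minor=float(rp.axis_minor_length) / 2.0,
        orientation=float(rp.orientation),
        mean_radius_kind=mean_radius_kind,
    )


def area_gate(cell: CellROI, min_ratio: float = 2.0) -> bool:
    """Admit a cell iff cytoplasm area / nucleus area >= min_ratio.

    The boundary is inclusive: a cell at exactly the minimum ratio passes.
    """
    nuc = cell.nucleus_mask.area_px
    if nuc == 0:
        raise ValidationError("nucleus mask is empty")
    cyto = cell.cytoplasm_mask.area_px
    if cyto == 0:
        raise ValidationError("cytoplasm mask is empty")
    return (cyto / nuc) >= min_ratio


def lysosome_distances(
    puncta: PunctaSet,
    ellipse: NucleusEllipse,
    pixel_size_um: float,
    cell_id: str = "",
    gate_passed: bool = True,
) -> PositioningResult:
    """Distance of each lysosome centroid to the nucleus border.

    distance_to_border = |centroid - ellipse centre| - mean radius.
    Negative values (centroids inside the mean-radius circle) are retained;
    they carry positional information.
    """
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be positive")
    cents = puncta.centroids()
    if len(cents):
        d_center = np.hypot(
            cents[:, 0] - ellipse.center[0], cents[:, 1] - ellipse.center[1]
        )
    else:
        d_center = np.empty(0)
    d_border = d_center - ellipse.mean_radius
    table = pd.DataFrame(
        {
            "label": [p.label for p in puncta.items],
            "distance_to_center_px": d_center,
            "distance_to_border_px": d_border,
            "distance_to_border_um": d_border * pixel_size_um,
        }
    )
    return PositioningResult(
        table=table, cell_id=cell_id or puncta.cell_id, gate_passed=gate_passed
    )


def positioning_summary(
    results: list[PositioningResult],
    level: Literal["cell", "animal"] = "cell",
    animal_ids: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Median and quartiles of border distances per cell or per animal.

    The animal level aggregates per-cell medians (the animal is the
    independent unit), then reports their median and quartiles per animal.
    Quartiles use linear interpolation (25th/75th percentiles).
    """
    frames = []
    for res in results:
        t = res.table.copy()
        t["cell_id"] = res.cell_id
        frames.append(t)
    if not frames:
        return pd.DataFrame(
            columns=["unit", "n", "median_um", "q1_um", "q3_um"]
        )
    all_d = pd.concat(frames, ignore_index=True)

    def _summ(g: pd.DataFrame) -> pd.Series:
        v = g["distance_to_border_um"].to_numpy()
        return pd.Series(
            {
                "n": len(v),
                "median_um": float(np.median(v)),
                "q1_um": float(np.percentile(v, 25)),
                "q3_um": float(np.percentile(v, 75)),
            }
        )

    if level == "cell":
        out = all_d.groupby("cell_id").apply(_summ, include_groups=False).reset_index()
        return out.rename(columns={"cell_id": "unit"})
    if level == "animal":
        if animal_ids is None:
            raise ValidationError("animal-level summary needs a cell->animal mapping")
        cell_medians = (
            all_d.groupby("cell_id")["distance_to_border_um"].median().reset_index()
        )
        cell_medians["animal"] = cell_medians["cell_id"].map(animal_ids)
        if cell_medians["animal"].isna().any():
            raise ValidationError("animal_ids missing for some cells")
        rows = []
        for animal, g in cell_medians.groupby("animal"):
            v = g["distance_to_border_um"].to_numpy()
            rows.append(
                {
                    "unit": animal,
                    "n": len(v),
                    "median_um": float(np.median(v)),
                    "q1_um": float(np.percentile(v, 25)),
                    "q3_um": float(np.percentile(v, 75)),
                }
            )
        return pd.DataFrame(rows)
    raise ValidationError("level must be 'cell' or 'animal'")
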