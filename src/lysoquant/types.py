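"""Core in-memory containers shared across the pipeline.

Images are plain 2D float arrays grouped by biological role (e.g. the
cell-body marker, the nucleus stain, two puncta channels); masks are boolean
arrays that remember which channel and threshold produced them.  All
containers validate their invariants at construction time so downstream code
can assume shapes agree and intensities are finite and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MultiChannelImage",
    "BinaryMask",
    "CellROI",
    "Punctum",
    "PunctaSet",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class MultiChannelImage:
    """Co-registered 2D intensity planes keyed by biological role.

    Parameters
    ----------
    planes
        Mapping role -> 2D array of non-negative, finite intensities.
        All planes must share one shape.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    metadata
        Free-form acquisition descriptors (simulator parameters, thresholds
        applied, source file, ...).
    """

    planes: dict[str, np.ndarray]
    pixel_size_um: float = 0.08
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValidationError("planes: at least one channel required")
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) != 1:
            raise ValidationError(f"planes: inconsistent shapes {shapes}")
        for role, plane in self.planes.items():
            arr = np.asarray(plane, dtype=float)
            if arr.ndim != 2:
                raise ValidationError(f"planes[{role!r}]: expected 2D array")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"planes[{role!r}]: non-finite intensities")
            if arr.min() < 0:
                raise ValidationError(f"planes[{role!r}]: negative intensities")
            self.planes[role] = arr
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape

    @property
    def channels(self) -> list[str]:
        return list(self.planes)

    def plane(self, role: str) -> np.ndarray:
        try:
            return self.planes[role]
        except KeyError:
            raise KeyError(
                f"channel {role!r} not present; available: {self.channels}"
            ) from None


@dataclass
class BinaryMask:
    """A boolean pixel mask plus provenance (source channel, threshold used)."""

    pixels: np.ndarray
    origin_channel: Optional[str] = None
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValidationError("pixels: expected a 2D array")
        self.pixels = arr.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        from .coloc import binary_and

        return binary_and(self, other)

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(~self.pixels, origin_channel=self.origin_channel)


@dataclass
class CellROI:
    """One cell's cytoplasmic and nuclear masks plus identifiers.

    The two masks are stored *disjoint*: the cytoplasm mask excludes the
    nuclear footprint, and ``cell_mask`` is their union.  This convention
    keeps cytosolic/lysosomal partitions and the cytoplasm:nucleus area
    gate unambiguous.
    """

    cell_id: str
    cytoplasm_mask: BinaryMask
    nucleus_mask: BinaryMask
    animal_id: str = ""
    group_id: str = ""

    def __post_init__(self) -> None:
        if self.cytoplasm_mask.shape != self.nucleus_mask.shape:
            raise ValidationError("cytoplasm and nucleus masks differ in shape")
        overlap = self.cytoplasm_mask.pixels & self.nucleus_mask.pixels
        if overlap.any():
            # enforce the disjoint convention silently: nucleus wins
            self.cytoplasm_mask = BinaryMask(
                self.cytoplasm_mask.pixels & ~self.nucleus_mask.pixels,
                origin_channel=self.cytoplasm_mask.origin_channel,
            )

    @property
    def cell_mask(self) -> BinaryMask:
        """Union of cytoplasm and nucleus footprints."""
        return BinaryMask(self.cytoplasm_mask.pixels | self.nucleus_mask.pixels)


@dataclass
class Punctum:
    label: int
    centroid: tuple[float, float]  # (row, col), sub-pixel
    area_px: int


@dataclass
class PunctaSet:
    """Connected bright objects of one channel within one cell."""

    items: list[Punctum]
    channel: str = ""
    cell_id: str = ""

    def __post_init__(self) -> None:
        labels = [p.label for p in self.items]
        if len(labels) != len(set(labels)):
            raise ValidationError("puncta labels must be unique")

    @property
    def count(self) -> int:
        return len(self.items)

    @property
    def total_area_px(self) -> int:
        return int(sum(p.area_px for p in self.items))

    def centroids(self) -> np.ndarray:
        if not self.items:
            return np.empty((0, 2))
        return np.array([p.centroid for p in self.items], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [p.label for p in self.items],
                "row": [p.centroid[0] for p in self.items],
                "col": [p.centroid[1] for p in self.items],
                "area_px": [p.area_px for p in self.items],
                "channel": self.channel,
                "cell_id": self.cell_id,
            }
        )
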