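"""Synthetic fluorescence fields with known ground truth.

The generator emulates single-plane confocal acquisitions of labelled
neurons: an elliptical nucleus inside a jittered superelliptical cell body,
a diffuse cell-body marker channel, and one or two punctate organelle
channels.  Puncta are isotropic Gaussian spots; a controllable fraction of
channel-B puncta share their centres exactly with channel-A puncta
(colocalized lysosomal signal) and a controllable fraction of the total
channel-B intensity is spread uniformly over the cytoplasm (leaked,
cytosolic signal).  Images are blurred by a Gaussian PSF and corrupted by
Poisson photon noise plus additive Gaussian read noise — the standard
fluorescence noise model.

Every hidden quantity (true centres, pairings, nuclear geometry, diffuse
fraction) is recorded in a :class:`GroundTruth` so downstream detection,
colocalization, permeabilization and positioning estimates can be scored
against truth.  Identical parameters and seed give bit-identical output.

Besides images the module simulates two tabular inputs: ratiometric pH
calibration tables (linear ratio-vs-pH with lognormal noise) and nested
cell-within-animal measurement tables with separate between-animal and
within-animal variance components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import BinaryMask, CellROI, MultiChannelImage, ValidationError

__all__ = [
    "ImageSimParams",
    "GroundTruth",
    "CellTruth",
    "simulate_cell_image",
    "simulate_tandem_image",
    "simulate_ph_table",
    "simulate_grouped_measurements",
]

# same-channel centres are kept at least one ground-truth puncta diameter
# (2 * the bookkeeping disk radius of 2*puncta_radius_px) apart so each
# thresholded blob maps 1:1 onto a true punctum at low noise
_SEP_FACTOR = 4.0


@dataclass
class ImageSimParams:
    """Parameters of one simulated field.

    ``puncta_radius_px`` is the Gaussian spot scale (sigma); the ground-truth
    "area" bookkeeping uses the disk of radius ``2 * puncta_radius_px``.
    ``coloc_fraction`` is the fraction of channel-B puncta whose centres
    coincide exactly with channel-A puncta; ``diffuse_fraction`` is the
    fraction of the total channel-B signal placed as uniform cytosolic
    intensity.
    """

    image_size_px: tuple[int, int] = (320, 320)
    pixel_size_um: float = 0.08
    n_cells: int = 1
    nucleus_axes_px: tuple[tuple[float, float], tuple[float, float]] = (
        (20.0, 26.0),
        (13.0, 17.0),
    )
    cytoplasm_to_nucleus_area_ratio: float = 5.0
    puncta_per_cell: tuple[int, int] = (8, 16)
    puncta_radius_px: float = 2.0
    coloc_fraction: float = 0.5
    diffuse_fraction: float = 0.0
    psf_sigma_px: float = 1.0
    photon_scale: float = 200.0
    read_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h <= 0 or w <= 0:
            raise ValidationError("image_size_px: dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        (a_lo, a_hi), (b_lo, b_hi) = self.nucleus_axes_px
        if not (0 < a_lo <= a_hi) or not (0 < b_lo <= b_hi):
            raise ValidationError("nucleus_axes_px: ranges must be positive and ordered")
        if self.cytoplasm_to_nucleus_area_ratio <= 0:
            raise ValidationError("cytoplasm_to_nucleus_area_ratio must be positive")
        lo, hi = self.puncta_per_cell
        if lo < 0 or hi < lo:
            raise ValidationError("puncta_per_cell: need 0 <= lo <= hi")
        if self.puncta_radius_px <= 0:
            raise ValidationError("puncta_radius_px must be positive")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValidationError("coloc_fraction must lie in [0, 1]")
        if not 0.0 <= self.diffuse_fraction <= 1.0:
            raise ValidationError("diffuse_fraction must lie in [0, 1]")
        if self.psf_sigma_px < 0:
            raise ValidationError("psf_sigma_px must be >= 0")
        if self.photon_scale <= 0:
            raise ValidationError("photon_scale must be positive")
        if self.read_noise_sd < 0:
            raise ValidationError("read_noise_sd must be >= 0")


@dataclass
class CellTruth:
    """Hidden geometry and content of one simulated cell."""

    cell_id: str
    nucleus_center: tuple[float, float]
    nucleus_semi_axes: tuple[float, float]  # (a, b), a >= b
    nucleus_angle_rad: float
    puncta_centers: dict[str, np.ndarray]  # role -> (n, 2) array of (row, col)
    colocalized_ids: list[tuple[int, int]]  # (index in A, index in B)
    true_cytosolic_fraction: float
    true_distances_px: np.ndarray  # per channel-A punctum, to nucleus border
    punctate_total: float = 0.0  # pre-noise channel-B punctate signal
    diffuse_total: float = 0.0  # pre-noise channel-B diffuse signal

    @property
    def nucleus_mean_radius(self) -> float:
        a, b = self.nucleus_semi_axes
        return 0.5 * (a + b)


@dataclass
class GroundTruth:
    """All hidden parameters of one simulated dataset."""

    cells: list[CellTruth] = field(default_factory=list)
    true_ph: Optional[np.ndarray] = None
    group_effects: Optional[dict[str, float]] = None
    params: Optional[dict] = None


# ---------------------------------------------------------------------------
# geometry

def _superellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    ra: float,
    rb: float,
    angle: float,
    exponent: float = 2.5,
    jitter: Optional[np.ndarray] = None,
    jitter_phases: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Filled superellipse with optional smooth angular radius jitter."""
    rows, cols = np.indices(shape, dtype=float)
    dy = rows - center[0]
    dx = cols - center[1]
    u = dy * math.cos(angle) + dx * math.sin(angle)
    v = -dy * math.sin(angle) + dx * math.cos(angle)
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    with np.errstate(divide="ignore"):
        r_boundary = (
            np.abs(np.cos(theta) / ra) ** exponent
            + np.abs(np.sin(theta) / rb) ** exponent
        ) ** (-1.0 / exponent)
    if jitter is not None:
        mult = np.ones_like(theta)
        for k, (amp, ph) in enumerate(zip(jitter, jitter_phases), start=2):
            mult += amp * np.cos(k * theta + ph)
        r_boundary = r_boundary * mult
    return rho <= r_boundary


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    angle: float,
) -> np.ndarray:
    return _superellipse_mask(shape, center, a, b, angle, exponent=2.0)


def _make_cell_geometry(
    params: ImageSimParams, rng: np.random.Generator, center: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, CellTruth]:
    """One cell: returns (cell_union_mask, nucleus_mask, partial truth)."""
    (a_lo, a_hi), (b_lo, b_hi) = params.nucleus_axes_px
    a = rng.uniform(a_lo, a_hi)
    b = rng.uniform(b_lo, b_hi)
    if b > a:
        a, b = b, a
    angle = rng.uniform(0, math.pi)
    # cell body scaled so |cell| ~ (1 + ratio) * |nucleus|; radial jitter is
    # kept small enough that the nucleus stays strictly inside
    scale = math.sqrt(1.0 + params.cytoplasm_to_nucleus_area_ratio)
    jitter = rng.uniform(0.0, 0.04, size=3)
    phases = rng.uniform(0, 2 * math.pi, size=3)
    # small nucleus offset from the cell-body centre
    off = rng.uniform(-0.15 * b, 0.15 * b, size=2)
    nuc_center = (center[0] + off[0], center[1] + off[1])

    shape = params.image_size_px
    cell = _superellipse_mask(
        shape, center, scale * a, scale * b, angle, exponent=2.5,
        jitter=jitter, jitter_phases=phases,
    )
    nucleus = _ellipse_mask(shape, nuc_center, a, b, angle)
    nucleus &= cell  # safety; jitter amplitudes guarantee this is a no-op
    truth = CellTruth(
        cell_id="",
        nucleus_center=nuc_center,
        nucleus_semi_axes=(a, b),
        nucleus_angle_rad=angle,
        puncta_centers={},
        colocalized_ids=[],
        true_cytosolic_fraction=params.diffuse_fraction,
        true_distances_px=np.empty(0),
    )
    return cell, nucleus, truth


def _cell_centers(params: ImageSimParams, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Lay cells out on a jittered grid; fail early if the field is too small."""
    h, w = params.image_size_px
    g = math.ceil(math.sqrt(params.n_cells))
    slot_h, slot_w = h / g, w / g
    (_, a_hi), _ = params.nucleus_axes_px
    extent = 1.1 * a_hi * math.sqrt(1.0 + params.cytoplasm_to_nucleus_area_ratio)
    if min(slot_h, slot_w) < 2 * extent:
        raise ValidationError(
            "image_size_px: field too small for the requested n_cells and cell size"
        )
    centers = []
    order = rng.permutation(g * g)[: params.n_cells]
    for idx in order:
        gi, gj = divmod(int(idx), g)
        margin_h = slot_h / 2 - extent
        margin_w = slot_w / 2 - extent
        cy = (gi + 0.5) * slot_h + rng.uniform(-margin_h, margin_h)
        cx = (gj + 0.5) * slot_w + rng.uniform(-margin_w, margin_w)
        centers.append((cy, cx))
    return centers


# ---------------------------------------------------------------------------
# puncta placement and rendering

def _candidate_pixels(
    cell: np.ndarray, nucleus: np.ndarray, margin: float
) -> np.ndarray:
    """Pixels of the cytoplasm deep enough to hold a whole punctum."""
    inside = ndimage.distance_transform_edt(cell) >= margin
    away_from_nucleus = ndimage.distance_transform_edt(~nucleus) >= margin / 2
    ok = inside & away_from_nucleus & ~nucleus
    return np.argwhere(ok)


def _place_points(
    rng: np.random.Generator,
    candidates: np.ndarray,
    n: int,
    min_sep: float,
    avoid: Optional[np.ndarray] = None,
    max_tries: Optional[int] = None,
) -> np.ndarray:
    """Rejection-sample n sub-pixel points with a minimum pairwise separation."""
    if max_tries is None:
        max_tries = 500 * max(n, 1)
    placed: list[np.ndarray] = []
    keep_away = [] if avoid is None or len(avoid) == 0 else [avoid]
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ValidationError(
                "puncta_per_cell: cannot place puncta at the requested density"
            )
        pix = candidates[rng.integers(len(candidates))]
        pt = pix + rng.uniform(-0.5, 0.5, size=2)
        blocks = placed + keep_away
        if blocks:
            allpts = np.vstack([np.atleast_2d(p) for p in blocks])
            if np.min(np.hypot(*(allpts - pt).T)) < min_sep:
                continue
        placed.append(pt)
    if not placed:
        return np.empty((0, 2))
    return np.vstack(placed)


def _render_spots(
    shape: tuple[int, int], centers: np.ndarray, sigma: float
) -> np.ndarray:
    """Sum of unit-peak isotropic Gaussians evaluated on local stamps."""
    img = np.zeros(shape, dtype=float)
    if len(centers) == 0:
        return img
    half = int(math.ceil(4 * sigma))
    for cy, cx in centers:
        r0, r1 = int(cy) - half, int(cy) + half + 1
        c0, c1 = int(cx) - half, int(cx) + half + 1
        r0c, r1c = max(r0, 0), min(r1, shape[0])
        c0c, c1c = max(c0, 0), min(c1, shape[1])
        if r0c >= r1c or c0c >= c1c:
            continue
        rr = np.arange(r0c, r1c, dtype=float)[:, None]
        cc = np.arange(c0c, c1c, dtype=float)[None, :]
        img[r0c:r1c, c0c:c1c] += np.exp(
            -((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * sigma**2)
        )
    return img


def _apply_noise(
    signal: np.ndarray, params: ImageSimParams, rng: np.random.Generator
) -> np.ndarray:
    blurred = (
        ndimage.gaussian_filter(signal, params.psf_sigma_px)
        if params.psf_sigma_px > 0
        else signal
    )
    photons = rng.poisson(np.clip(params.photon_scale * blurred, 0, None)).astype(float)
    noisy = photons + rng.normal(0.0, params.read_noise_sd, size=signal.shape)
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# public simulators

def simulate_cell_image(
    params: ImageSimParams,
) -> tuple[MultiChannelImage, list[CellROI], GroundTruth]:
    """Simulate one field with channels cell / nucleus / puncta_a / puncta_b.

    Channel A plays the lysosome-membrane role (punctate only); channel B the
    lysosomal-enzyme role, split between a punctate component (fraction
    ``1 - diffuse_fraction`` of its total signal) and a uniform cytosolic
    component (``diffuse_fraction``).  ``coloc_fraction`` of B puncta sit
    exactly on A centres; the rest are kept at least one true puncta
    diameter away from every A centre.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.image_size_px
    sigma = params.puncta_radius_px
    min_sep = _SEP_FACTOR * sigma

    cell_plane = np.zeros(shape)
    nuc_plane = np.zeros(shape)
    a_signal = np.zeros(shape)
    b_signal = np.zeros(shape)

    rois: list[CellROI] = []
    truth = GroundTruth(cells=[], params=asdict(params))

    for ci, center in enumerate(_cell_centers(params, rng)):
        cell, nucleus, ct = _make_cell_geometry(params, rng, center)
        ct.cell_id = f"cell{ci:02d}"
        cyto = cell & ~nucleus
        cell_plane += 0.6 * cell
        nuc_plane += 0.8 * nucleus

        candidates = _candidate_pixels(cell, nucleus, margin=2 * sigma + 1)
        if len(candidates) == 0:
            raise ValidationError("cytoplasm too small to hold puncta")
        lo, hi = params.puncta_per_cell
        n_a = int(rng.integers(lo, hi + 1))
        n_b = int(rng.integers(lo, hi + 1))
        if params.coloc_fraction == 1.0:
            n_b = min(n_b, n_a) if n_a > 0 else 0
        a_centers = _place_points(rng, candidates, n_a, min_sep)

        n_coloc = int(round(params.coloc_fraction * n_b))
        n_coloc = min(n_coloc, n_a)
        coloc_idx = rng.choice(n_a, size=n_coloc, replace=False) if n_coloc else np.array([], int)
        b_coloc = a_centers[coloc_idx] if n_coloc else np.empty((0, 2))
        avoid = np.vstack([a_centers]) if n_a else None
        b_free = _place_points(rng, candidates, n_b - n_coloc, min_sep, avoid=avoid)
        b_centers = (
            np.vstack([b_coloc, b_free]) if (n_coloc or len(b_free)) else np.empty((0, 2))
        )

        ct.puncta_centers = {"puncta_a": a_centers, "puncta_b": b_centers}
        ct.colocalized_ids = [(int(ai), bi) for bi, ai in enumerate(coloc_idx)]

        # true distances of channel-A puncta to the nuclear border under the
        # subtraction convention: |centre - nucleus centre| - (a + b)/2
        if n_a:
            d_center = np.hypot(
                a_centers[:, 0] - ct.nucleus_center[0],
                a_centers[:, 1] - ct.nucleus_center[1],
            )
            ct.true_distances_px = d_center - ct.nucleus_mean_radius
        else:
            ct.true_distances_px = np.empty(0)

        a_signal += _render_spots(shape, a_centers, sigma)

        # split the B total between punctate and diffuse components exactly
        p_img = _render_spots(shape, b_centers, sigma)
        p_total = float(p_img.sum())
        if p_total == 0.0:
            # no puncta requested/placed: give the diffuse component the
            # total one average punctum would carry per requested punctum
            p_total = max(n_b, 1) * 2 * math.pi * sigma**2
        d = params.diffuse_fraction
        cyto_area = float(cyto.sum())
        b_cell = (1.0 - d) * p_img
        if d > 0 and cyto_area > 0:
            b_cell = b_cell + (d * p_total / cyto_area) * cyto
        b_signal += b_cell
        ct.punctate_total = (1.0 - d) * float(p_img.sum())
        ct.diffuse_total = d * p_total if cyto_area > 0 else 0.0

        rois.append(
            CellROI(
                cell_id=ct.cell_id,
                cytoplasm_mask=BinaryMask(cyto, origin_channel="cell"),
                nucleus_mask=BinaryMask(nucleus, origin_channel="nucleus"),
            )
        )
        truth.cells.append(ct)

    planes = {
        "cell": _apply_noise(cell_plane, params, rng),
        "nucleus": _apply_noise(nuc_plane, params, rng),
        "puncta_a": _apply_noise(a_signal, params, rng),
        "puncta_b": _apply_noise(b_signal, params, rng),
    }
    image = MultiChannelImage(
        planes=planes,
        pixel_size_um=params.pixel_size_um,
        metadata={"simulator": "simulate_cell_image", "seed": params.seed},
    )
    return image, rois, truth


def simulate_tandem_image(
    params: ImageSimParams, n_ap: int, n_al: int
) -> tuple[MultiChannelImage, GroundTruth]:
    """Simulate a tandem mCherry-GFP autophagy-reporter cell.

    Autophagosomes (``n_ap``) appear in both the GFP and mCherry channels at
    identical centres; autolysosomes (``n_al``) appear in mCherry only, the
    GFP moiety being quenched at lysosomal pH.
    """
    if n_ap < 0 or n_al < 0:
        raise ValidationError("n_ap and n_al must be >= 0")
    rng = np.random.default_rng(params.seed)
    shape = params.image_size_px
    sigma = params.puncta_radius_px
    min_sep = _SEP_FACTOR * sigma

    center = _cell_centers(params, rng)[0]
    cell, nucleus, ct = _make_cell_geometry(params, rng, center)
    ct.cell_id = "cell00"
    candidates = _candidate_pixels(cell, nucleus, margin=2 * sigma + 1)
    all_centers = _place_points(rng, candidates, n_ap + n_al, min_sep)
    ap_centers = all_centers[:n_ap] if n_ap else np.empty((0, 2))
    al_centers = all_centers[n_ap:] if n_al else np.empty((0, 2))

    ct.puncta_centers = {"gfp": ap_centers, "mcherry": all_centers}
    ct.colocalized_ids = [(i, i) for i in range(n_ap)]
    ct.true_cytosolic_fraction = 0.0

    gfp = _render_spots(shape, ap_centers, sigma)
    mch = _render_spots(shape, all_centers, sigma)
    planes = {
        "cell": _apply_noise(0.6 * cell.astype(float), params, rng),
        "nucleus": _apply_noise(0.8 * nucleus.astype(float), params, rng),
        "gfp": _apply_noise(gfp, params, rng),
        "mcherry": _apply_noise(mch, params, rng),
    }
    image = MultiChannelImage(
        planes=planes,
        pixel_size_um=params.pixel_size_um,
        metadata={
            "simulator": "simulate_tandem_image",
            "seed": params.seed,
            "n_ap": n_ap,
            "n_al": n_al,
        },
    )
    truth = GroundTruth(cells=[ct], params={**asdict(params), "n_ap": n_ap, "n_al": n_al})
    return image, truth


def simulate_ph_table(
    slope: float,
    intercept: float,
    ph_values: Sequence[float] = tuple(np.arange(3.5, 7.01, 0.5)),
    replicates: int = 3,
    noise_cv: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Ratiometric pH calibration table: ratio = slope*pH + intercept.

    Each row is one well; the measured two-channel emission ratio is the
    linear response multiplied by lognormal noise with coefficient of
    variation ``noise_cv``.  Calibration pH levels follow the standard
    clamped range 3.5-7.0 by default.
    """
    if slope == 0:
        raise ValidationError("slope: a flat calibration curve is not invertible")
    ph_values = np.asarray(list(ph_values), dtype=float)
    if ph_values.size == 0:
        raise ValidationError("ph_values: at least one level required")
    if ph_values.min() < 3.0 or ph_values.max() > 8.0:
        raise ValidationError("ph_values: levels must lie in [3.0, 8.0]")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for ph in ph_values:
        true_ratio = slope * ph + intercept
        for rep in range(replicates):
            if noise_cv > 0:
                sig2 = math.log(1.0 + noise_cv**2)
                mult = rng.lognormal(mean=-0.5 * sig2, sigma=math.sqrt(sig2))
            else:
                mult = 1.0
            rows.append({"ph": float(ph), "replicate": rep, "ratio": true_ratio * mult})
    return pd.DataFrame(rows)


def simulate_grouped_measurements(
    n_groups: int = 2,
    animals_per_group: int = 8,
    cells_per_animal: int = 15,
    group_means: Optional[Sequence[float]] = None,
    sd_between_animal: float = 1.0,
    sd_within_animal: float = 2.0,
    seed: int = 0,
    measurement: str = "value",
) -> pd.DataFrame:
    """Nested cell-within-animal measurement table.

    value = group mean + animal effect ~ N(0, sd_between_animal)
                       + cell noise    ~ N(0, sd_within_animal).

    Defaults mirror the in vivo design: two treatment groups, eight animals
    per group, 10-20 (here 15) cells per animal.
    """
    if n_groups < 1 or animals_per_group < 1 or cells_per_animal < 1:
        raise ValidationError("counts must be >= 1")
    if sd_between_animal < 0 or sd_within_animal < 0:
        raise ValidationError("standard deviations must be >= 0")
    if group_means is None:
        group_means = [0.0] * n_groups
    group_means = list(group_means)
    if len(group_means) != n_groups:
        raise ValidationError("group_means: need one mean per group")
    rng = np.random.default_rng(seed)
    rows = []
    for gi, mu in enumerate(group_means):
        for ai in range(animals_per_group):
            animal_effect = rng.normal(0.0, sd_between_animal)
            cell_noise = rng.normal(0.0, sd_within_animal, size=cells_per_animal)
            for ci in range(cells_per_animal):
                rows.append(
                    {
                        "group": f"g{gi}",
                        "animal": f"g{gi}_a{ai:02d}",
                        "cell": f"g{gi}_a{ai:02d}_c{ci:02d}",
                        "measurement": measurement,
                        "value": mu + animal_effect + cell_noise[ci],
                    }
                )
    return pd.DataFrame(rows)
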