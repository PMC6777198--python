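"""Synthetic axial CT slices of an aorta with circular-ROI measurement.

Mirrors the study's quantitative procedure: a circular region of
interest (ROI) placed centrally in the aortic lumen — or, for a
dissection, centrally in the true lumen — and the mean Hounsfield value
read off.  Slices are flat 2-D pixel grids: a circular lumen at a
specified enhancement, an optional mural-thrombus ring, an optional
intimal flap splitting the lumen into true and false channels, and
additive Gaussian noise.  No acquisition physics (helical sampling,
reconstruction kernels, beam hardening) is modeled.

Conventions: coordinates are 0-based ``(row, col)`` pixel indices with
the pixel-center convention; physical distances are millimetres via the
isotropic pixel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "ThrombusRing",
    "DissectionFlap",
    "PhantomGeometry",
    "PhantomSlice",
    "RoiSpec",
    "render_slice",
    "auto_place_roi",
    "measure_roi",
    "chord_offset_for_fraction",
    "save_png",
    "save_csv",
]


@dataclass(frozen=True)
class ThrombusRing:
    """Annulus of mural thrombus around the lumen."""

    inner_radius_mm: float
    outer_radius_mm: float
    hu: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_mm < self.outer_radius_mm:
            raise ValueError("thrombus radii must be positive and nested")


@dataclass(frozen=True)
class DissectionFlap:
    """Intimal flap: a straight chord splitting the lumen.

    The flap runs perpendicular to the +col axis at a signed offset from
    the lumen centre chosen so the true lumen (the +col side) occupies
    ``true_lumen_fraction`` of the lumen area.
    """

    true_lumen_fraction: float
    flap_hu: float = 40.0
    thickness_mm: float = 1.5
    false_lumen_hu: float = 90.0

    def __post_init__(self) -> None:
        if not 0 < self.true_lumen_fraction < 1:
            raise ValueError("true_lumen_fraction must lie in (0, 1)")
        if self.thickness_mm <= 0:
            raise ValueError("flap thickness must be positive")


@dataclass(frozen=True)
class PhantomGeometry:
    shape: tuple[int, int] = (128, 128)  # rows, cols
    pixel_spacing_mm: float = 0.7
    center_px: tuple[float, float] | None = None  # defaults to grid centre
    lumen_radius_mm: float = 15.0
    thrombus: ThrombusRing | None = None
    flap: DissectionFlap | None = None
    background_hu: float = -50.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.lumen_radius_mm <= 0 or self.pixel_spacing_mm <= 0:
            raise ValueError("radii and spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.thrombus and self.thrombus.inner_radius_mm < self.lumen_radius_mm:
            raise ValueError("thrombus inner radius must not cut into the lumen")

    @property
    def center(self) -> tuple[float, float]:
        return self.center_px or ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    @property
    def outer_radius_mm(self) -> float:
        return self.thrombus.outer_radius_mm if self.thrombus else self.lumen_radius_mm


@dataclass(frozen=True)
class RoiSpec:
    """Circular ROI: centre in pixel coordinates, radius in mm."""

    center_px: tuple[float, float]
    radius_mm: float
    flag: str | None = None  # e.g. "true_lumen_too_small"; never silently shrunk

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("ROI radius must be positive")


class PhantomSlice:
    """Rendered pixel grid plus the geometry metadata used to build it."""

    def __init__(
        self,
        pixels: np.ndarray,
        geometry: PhantomGeometry,
        lumen_hu: float,
        lumen_mask: np.ndarray,
        true_lumen_mask: np.ndarray,
    ):
        self.pixels = pixels
        self.geometry = geometry
        self.lumen_hu = lumen_hu
        self.lumen_mask = lumen_mask
        self.true_lumen_mask = true_lumen_mask

    @property
    def pixel_spacing_mm(self) -> float:
        return self.geometry.pixel_spacing_mm


def chord_offset_for_fraction(radius: float, fraction: float) -> float:
    """Signed chord offset d such that the circular segment {x > d} has
    the given area fraction of the disc of the given radius."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")

    def seg_fraction(d: float) -> float:
        return (radius**2 * np.arccos(d / radius) - d * np.sqrt(radius**2 - d**2)) / (
            np.pi * radius**2
        )

    eps = 1e-9 * radius
    return float(
        optimize.brentq(lambda d: seg_fraction(d) - fraction, -radius + eps, radius - eps)
    )


def render_slice(geometry: PhantomGeometry, lumen_hu: float, seed: int = 0) -> PhantomSlice:
    """Paint the phantom and add seeded Gaussian noise.

    In dissection mode ``lumen_hu`` is the true-lumen value; the false
    lumen takes the flap spec's ``false_lumen_hu``.
    """
    ny, nx = geometry.shape
    cy, cx = geometry.center
    spacing = geometry.pixel_spacing_mm
    r_out_px = geometry.outer_radius_mm / spacing
    if cy - r_out_px < -0.5 or cx - r_out_px < -0.5 or cy + r_out_px > ny - 0.5 or cx + r_out_px > nx - 0.5:
        raise ValueError("geometry exceeds the pixel grid")

    rows, cols = np.mgrid[0:ny, 0:nx]
    dy = (rows - cy) * spacing
    dx = (cols - cx) * spacing
    r = np.hypot(dy, dx)

    img = np.full((ny, nx), geometry.background_hu, dtype=float)
    if geometry.thrombus:
        ring = (r > geometry.thrombus.inner_radius_mm) & (r <= geometry.thrombus.outer_radius_mm)
        img[ring] = geometry.thrombus.hu
    lumen = r <= geometry.lumen_radius_mm

    if geometry.flap is None:
        img[lumen] = lumen_hu
        true_mask = lumen
    else:
        flap = geometry.flap
        d = chord_offset_for_fraction(geometry.lumen_radius_mm, flap.true_lumen_fraction)
        half = flap.thickness_mm / 2.0
        flap_band = lumen & (np.abs(dx - d) <= half)
        true_mask = lumen & (dx > d + half)
        false_mask = lumen & (dx < d - half)
        img[false_mask] = flap.false_lumen_hu
        img[flap_band] = flap.flap_hu
        img[true_mask] = lumen_hu

    if geometry.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, geometry.noise_sd, size=img.shape)

    return PhantomSlice(img, geometry, lumen_hu, lumen, true_mask)


def auto_place_roi(
    slice_: PhantomSlice,
    radius_fraction: float = 0.6,
    min_radius_mm: float = 2.0,
) -> RoiSpec:
    """Place the ROI the way a careful reader would.

    Centre = centroid of the (true) lumen mask; radius = the given
    fraction of the largest circle inscribed at that centre (distance
    from the centroid to the nearest non-lumen pixel).  A true lumen too
    small for the minimum ROI is flagged on the returned spec, never
    silently shrunk past the minimum.  Placement is deterministic.
    """
    mask = slice_.true_lumen_mask
    if not mask.any():
        raise ValueError("slice has no (true) lumen pixels")
    spacing = slice_.pixel_spacing_mm
    rows, cols = np.nonzero(mask)
    cy, cx = float(rows.mean()), float(cols.mean())
    dist_mm = ndimage.distance_transform_edt(mask, sampling=spacing)
    inscribed = float(dist_mm[int(round(cy)), int(round(cx))])
    radius = radius_fraction * inscribed
    flag = "true_lumen_too_small" if radius < min_radius_mm else None
    return RoiSpec(center_px=(cy, cx), radius_mm=radius, flag=flag)


def measure_roi(slice_: PhantomSlice, roi: RoiSpec) -> tuple[float, float, int]:
    """Mean HU, SD and pixel count over pixels whose centres fall in the disc."""
    ny, nx = slice_.pixels.shape
    cy, cx = roi.center_px
    spacing = slice_.pixel_spacing_mm
    r_px = roi.radius_mm / spacing
    if cy - r_px < -0.5 or cx - r_px < -0.5 or cy + r_px > ny - 0.5 or cx + r_px > nx - 0.5:
        raise ValueError("ROI extends outside the pixel grid")
    rows, cols = np.mgrid[0:ny, 0:nx]
    inside = ((rows - cy) * spacing) ** 2 + ((cols - cx) * spacing) ** 2 <= roi.radius_mm**2
    values = slice_.pixels[inside]
    if values.size == 0:
        raise ValueError("ROI contains no pixel centres")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd, int(values.size)


def save_png(slice_: PhantomSlice, path: str | Path, window: tuple[float, float] = (-150.0, 450.0)) -> None:
    """Windowed 8-bit PNG export (display only; not HU-lossless)."""
    import imageio.v3 as iio

    lo, hi = window
    scaled = np.clip((slice_.pixels - lo) / (hi - lo), 0.0, 1.0)
    iio.imwrite(Path(path), (scaled * 255).astype(np.uint8))


def save_csv(slice_: PhantomSlice, path: str | Path) -> None:
    """Lossless numeric dump, one CSV row per pixel row."""
    np.savetxt(Path(path), slice_.pixels, delimiter=",", fmt="%.6g")
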