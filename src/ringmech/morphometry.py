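"""Ring thickness morphometry and cross-sectional geometry.

Quantifies the x-y thickness of an annular tissue construct from a top-view
image: the ring is segmented by global thresholding, and thickness is
measured along radial rays from the centroid as the distance between the
inner and outer boundary crossings.  Thickness uniformity is summarised by
the coefficient of variation (sample SD over mean).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import remove_small_objects

from .mechanics import elliptical_area

__all__ = [
    "SpecimenGeometry",
    "ThicknessProfile",
    "SegmentationError",
    "segment_ring",
    "thickness_profile",
    "coefficient_of_variation",
    "area_variants",
    "read_geometry",
    "write_geometry",
]


class SegmentationError(ValueError):
    """The image does not contain exactly one plausible annular component."""


@dataclass
class SpecimenGeometry:
    """Caliper-style width/height measurements along a ring and derived areas.

    ``widths`` are top-view (x-y) thicknesses in mm, ``heights`` side-view (z)
    thicknesses at the same positions; each paired (w, h) defines an
    elliptical cross-section.  ``a0_min``/``a0_mean`` are the minimum and mean
    of those areas in mm^2.  A single height is broadcast to all widths.
    """

    widths: np.ndarray
    heights: np.ndarray
    ring_diameter: float = 5.0  # mm, nominal
    a0_min: float = field(init=False)
    a0_mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        self.heights = np.atleast_1d(np.asarray(self.heights, dtype=float))
        if self.heights.size == 1 and self.widths.size > 1:
            self.heights = np.full_like(self.widths, self.heights[0])
        self.a0_min, self.a0_mean = area_variants(self.widths, self.heights)

    def a0(self, convention: str = "minimum") -> float:
        if convention in ("minimum", "min"):
            return self.a0_min
        if convention == "mean":
            return self.a0_mean
        raise ValueError(f"unknown area convention {convention!r}")


@dataclass
class ThicknessProfile:
    """Angularly sampled ring thickness with its summary statistics."""

    angles: np.ndarray  # radians, [0, 2*pi)
    thickness: np.ndarray  # um
    mean: float
    sd: float
    cv: float

    @classmethod
    def from_samples(cls, angles, thickness) -> "ThicknessProfile":
        angles = np.asarray(angles, dtype=float)
        thickness = np.asarray(thickness, dtype=float)
        mean = float(np.mean(thickness))
        sd = float(np.std(thickness, ddof=1)) if thickness.size > 1 else 0.0
        return cls(angles, thickness, mean=mean, sd=sd, cv=sd / mean)


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """Sample standard deviation over mean (n-1 denominator by default)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError(f"need >= 2 values, got {values.size}")
    mean = float(np.mean(values))
    if mean <= 0:
        raise ValueError(f"mean must be positive for a CV, got {mean}")
    return float(np.std(values, ddof=ddof)) / mean


def area_variants(widths, heights) -> tuple[float, float]:
    """Minimum and mean elliptical area over paired width/height measurements."""
    widths = np.atleast_1d(np.asarray(widths, dtype=float))
    heights = np.atleast_1d(np.asarray(heights, dtype=float))
    if heights.size == 1 and widths.size > 1:
        heights = np.full_like(widths, heights[0])
    if widths.shape != heights.shape:
        raise ValueError(
            f"widths and heights must pair up: {widths.shape} vs {heights.shape}"
        )
    areas = np.array([elliptical_area(w, h) for w, h in zip(widths, heights)])
    return float(areas.min()), float(areas.mean())


def segment_ring(
    image: np.ndarray, min_area: int = 64
) -> tuple[np.ndarray, tuple[float, float]]:
    """Segment the annulus: global Otsu threshold, largest connected component.

    Returns the binary mask and the component centroid as (row, col) in
    pixels.  Speckles smaller than ``min_area`` are discarded; if zero
    plausible components remain, or more than one of comparable size, a
    :class:`SegmentationError` is raised.
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        raise SegmentationError("blank image: no intensity variation to threshold")
    mask = image > threshold_otsu(image)
    mask = remove_small_objects(mask, max_size=min_area - 1)
    labels = label(mask)
    props = regionprops(labels)
    if not props:
        raise SegmentationError("no foreground component after filtering")
    props.sort(key=lambda p: p.area, reverse=True)
    if len(props) > 1 and props[1].area >= 0.25 * props[0].area:
        raise SegmentationError(
            f"{len(props)} comparable foreground components; expected one annulus"
        )
    ring = props[0]
    return labels == ring.label, ring.centroid


def thickness_profile(
    mask: np.ndarray,
    center: tuple[float, float],
    n_angles: int = 360,
    pixel_size: float = 1.0,
    radial_step: float = 0.1,
    max_missing_fraction: float = 0.10,
) -> ThicknessProfile:
    """Radial thickness of an annular mask around ``center``.

    For each of ``n_angles`` equally spaced rays, thickness is the radial
    distance between the first and last foreground sample (sampled every
    ``radial_step`` px, nearest-neighbour lookup) times ``pixel_size``
    (um/px).  The ray origin is refined to the centroid of the enclosed
    lumen when the mask has one: for a ring of non-uniform thickness the
    mass centroid is pulled toward the thick side, which would make rays
    cross the wall obliquely, while the lumen centre defines the ring axis.
    Rays with no foreground crossing are recorded missing; more
    than ``max_missing_fraction`` missing rays is an error, as is a center
    lying outside the mask's bounding box.
    """
    mask = np.asarray(mask, dtype=bool)
    cy, cx = center
    h, w = mask.shape
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError(f"center {center} lies outside the image")
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    if rows.size == 0:
        raise ValueError("empty mask")
    if not (rows[0] <= cy <= rows[-1] and cols[0] <= cx <= cols[-1]):
        raise ValueError(f"center {center} lies outside the ring")

    hole = binary_fill_holes(mask) & ~mask
    if hole.any():
        hy, hx = np.nonzero(hole)
        cy, cx = float(hy.mean()), float(hx.mean())

    angles = np.arange(n_angles) * (2.0 * np.pi / n_angles)
    r_max = float(np.hypot(h, w))
    radii = np.arange(radial_step, r_max, radial_step)
    thickness = np.full(n_angles, np.nan)
    for k, theta in enumerate(angles):
        yy = np.rint(cy + radii * np.sin(theta)).astype(int)
        xx = np.rint(cx + radii * np.cos(theta)).astype(int)
        inside = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        fg = np.flatnonzero(mask[yy[inside], xx[inside]])
        if fg.size == 0:
            continue
        r_in = radii[inside][fg[0]]
        r_out = radii[inside][fg[-1]]
        thickness[k] = (r_out - r_in + radial_step) * pixel_size
    missing = np.isnan(thickness)
    if missing.mean() > max_missing_fraction:
        raise ValueError(
            f"{missing.sum()} of {n_angles} rays have no foreground crossing"
        )
    return ThicknessProfile.from_samples(angles[~missing], thickness[~missing])


def read_geometry(path) -> SpecimenGeometry:
    """Read a geometry YAML with keys widths_mm, heights_mm, ring_diameter_mm."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "widths_mm" not in data or "heights_mm" not in data:
        raise ValueError(f"{path}: geometry YAML needs widths_mm and heights_mm")
    return SpecimenGeometry(
        widths=data["widths_mm"],
        heights=data["heights_mm"],
        ring_diameter=float(data.get("ring_diameter_mm", 5.0)),
    )


def write_geometry(geometry: SpecimenGeometry, path) -> None:
    data = {
        "widths_mm": [float(v) for v in geometry.widths],
        "heights_mm": [float(v) for v in geometry.heights],
        "ring_diameter_mm": float(geometry.ring_diameter),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
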