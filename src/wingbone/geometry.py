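"""Cross-sectional geometry of cortical bone profiles.

Computes the standard engineering section properties of a binary cortical
mask: cortical area (CA), total subperiosteal area (TA), principal second
moments of area (Imax, Imin), the polar moment J = Imax + Imin, and the
polar section modulus Zp = J / r, where r is the moment arm from the
section centroid to the periosteal surface.  Zp is the usual proxy for
torsional (and average bending) rigidity of a near-circular long-bone
shaft; the shape ratio Imax/Imin quantifies how far a section departs
from circularity and therefore how heuristic Zp is.

Pixel model: each foreground pixel contributes its full area concentrated
at its center (midpoint rule).  All moments are taken about the area
centroid of the cortex.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

log = logging.getLogger(__name__)

#: shape ratio above which Zp should be treated with caution
DEFAULT_SHAPE_RATIO_CAUTION = 1.5


@dataclass
class CorticalProfile:
    """A binary cortical mask with physical pixel scale.

    ``mask`` is boolean, foreground = cortical bone.  ``pixel_scale`` is
    the edge length of one pixel in mm.
    """

    mask: np.ndarray
    pixel_scale: float
    axes_deg: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")


@dataclass
class SectionGeometry:
    """Section properties of one cortical profile (mm-based units)."""

    ca: float                      # cortical area, mm^2
    ta: float                      # total subperiosteal area, mm^2
    centroid: tuple[float, float]  # (x, y) mm, image coordinates
    imax: float                    # mm^4
    imin: float                    # mm^4
    j: float                       # polar moment, mm^4
    r_max: float                   # centroid -> periosteal extreme fiber, mm
    zp: float                      # polar section modulus, mm^3
    shape_ratio: float             # Imax / Imin
    principal_angle_deg: float = 0.0
    caution: bool = False


def _foreground_coords_mm(profile: CorticalProfile) -> np.ndarray:
    """(N, 2) array of foreground pixel-center coordinates (x, y) in mm."""
    rows, cols = np.nonzero(profile.mask)
    if rows.size == 0:
        raise ValueError("empty mask: no foreground pixels")
    s = profile.pixel_scale
    return np.column_stack([cols * s, rows * s])


def compute_areas(profile: CorticalProfile) -> tuple[float, float, tuple[float, float]]:
    """Return (CA, TA, centroid).

    CA counts cortical (foreground) pixels; TA fills the medullary cavity
    first, so it is the area enclosed by the periosteal boundary.  The
    centroid is the area centroid of the cortex alone.
    """
    coords = _foreground_coords_mm(profile)
    s = profile.pixel_scale
    ca = coords.shape[0] * s * s
    filled = ndimage.binary_fill_holes(profile.mask)
    ta = int(filled.sum()) * s * s
    cx, cy = coords.mean(axis=0)
    return ca, ta, (float(cx), float(cy))


def compute_second_moments(profile: CorticalProfile) -> tuple[float, float, float]:
    """Principal second moments of area about the centroid.

    Returns (Imax, Imin, principal_angle_deg) with the angle of the Imax
    axis measured from the image x-axis in [0, 180).
    """
    coords = _foreground_coords_mm(profile)
    if coords.shape[0] < 2 or np.allclose(coords[:, 0], coords[0, 0]) or np.allclose(
        coords[:, 1], coords[0, 1]
    ):
        raise ValueError("degenerate mask: foreground is collinear")
    s = profile.pixel_scale
    d = coords - coords.mean(axis=0)
    px_area = s * s
    # second moments of area: Ixx = sum y^2 dA resists bending about x
    ixx = float(np.sum(d[:, 1] ** 2)) * px_area
    iyy = float(np.sum(d[:, 0] ** 2)) * px_area
    ixy = float(np.sum(d[:, 0] * d[:, 1])) * px_area
    tensor = np.array([[ixx, -ixy], [-ixy, iyy]])
    evals, evecs = np.linalg.eigh(tensor)
    imin, imax = float(evals[0]), float(evals[1])
    # axis about which bending is "stiffest" corresponds to Imax eigenvector
    vx, vy = evecs[:, 1]
    angle = float(np.degrees(np.arctan2(vy, vx)) % 180.0)
    return imax, imin, angle


def periosteal_boundary(profile: CorticalProfile) -> np.ndarray:
    """Outer (periosteal) boundary as an (N, 2) polyline of (x, y) mm."""
    filled = ndimage.binary_fill_holes(profile.mask)
    contours = measure.find_contours(filled.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary found")
    outer = max(contours, key=len)  # (row, col) order
    s = profile.pixel_scale
    return np.column_stack([outer[:, 1] * s, outer[:, 0] * s])


def compute_polar_modulus(
    profile: CorticalProfile,
    imax: float,
    imin: float,
    centroid: tuple[float, float],
    radius: str = "max",
) -> tuple[float, float, float]:
    """Return (J, r, Zp) with J = Imax + Imin and Zp = J / r.

    ``radius`` selects the moment arm: "max" (default) uses the maximum
    centroid-to-periosteal distance (extreme-fiber arm), "mean" the mean
    periosteal radius.
    """
    j = imax + imin
    boundary = periosteal_boundary(profile)
    dists = np.hypot(boundary[:, 0] - centroid[0], boundary[:, 1] - centroid[1])
    if radius == "max":
        r = float(dists.max())
    elif radius == "mean":
        r = float(dists.mean())
    else:
        raise ValueError(f"unknown radius rule {radius!r}")
    return float(j), r, float(j / r)


def circularity_caution(
    geometry: SectionGeometry, threshold: float = DEFAULT_SHAPE_RATIO_CAUTION
) -> bool:
    """Flag (and log) sections elliptical enough that Zp is only heuristic."""
    flag = bool(geometry.shape_ratio > threshold)
    if flag:
        log.warning(
            "section strongly elliptical (Imax/Imin = %.3g > %.3g): "
            "Zp is a heuristic estimate of torsional rigidity",
            geometry.shape_ratio,
            threshold,
        )
    return flag


def compute_section_geometry(
    profile: CorticalProfile,
    radius: str = "max",
    caution_threshold: float = DEFAULT_SHAPE_RATIO_CAUTION,
) -> SectionGeometry:
    """Full section-property computation for one cortical profile."""
    ca, ta, centroid = compute_areas(profile)
    imax, imin, angle = compute_second_moments(profile)
    j, r, zp = compute_polar_modulus(profile, imax, imin, centroid, radius=radius)
    geom = SectionGeometry(
        ca=ca,
        ta=ta,
        centroid=centroid,
        imax=imax,
        imin=imin,
        j=j,
        r_max=r,
        zp=zp,
        shape_ratio=imax / imin,
        principal_angle_deg=angle,
    )
    geom.caution = circularity_caution(geom, caution_threshold)
    return geom


# ---------------------------------------------------------------------------
# mask I/O: PNG/TIFF masks with a JSON sidecar holding the pixel scale


def write_mask(mask: np.ndarray, path: str | Path, pixel_scale: float) -> None:
    path = Path(path)
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"pixel_scale": pixel_scale}))


def read_profile(path: str | Path, pixel_scale: float | None = None) -> CorticalProfile:
    path = Path(path)
    if pixel_scale is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(f"no pixel scale given and no sidecar at {sidecar}")
        pixel_scale = float(json.loads(sidecar.read_text())["pixel_scale"])
    mask = np.asarray(Image.open(path).convert("L")) > 127
    return CorticalProfile(mask=mask, pixel_scale=pixel_scale)
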