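"""Primary vascular canal morphometry and the laminarity index.

Workflow for one transverse thick section: extract the four cardinal
cortical octants, optionally uncurve ("straighten") each octant so the
periosteal surface becomes a constant horizontal reference line, split
branched canals at skeleton junctions, fit an ellipse to each canal,
measure its aspect ratio and the acute angle of its major axis to the
local periosteal tangent, and classify it as longitudinal,
circumferential, radial or oblique:

1. longitudinal — aspect ratio < 3;
2. circumferential — major axis within 0 deg +/- 22.5 deg of the
   periosteal tangent;
3. radial — major axis within 90 deg +/- 22.5 deg of the tangent;
4. oblique — everything else.

The laminarity index (LI) is the proportion of circumferential canals
among primary canals, estimated with the Wilson score estimator so that
small samples are not biased toward the raw fraction.  Canals of
secondary osteons are assumed to be excluded upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import norm
from skimage import measure
from skimage.morphology import skeletonize

log = logging.getLogger(__name__)

CANAL_CLASSES = ("longitudinal", "circumferential", "radial", "oblique")

#: aspect ratio below which a canal is longitudinal (criterion 1, strict <)
LONGITUDINAL_ASPECT_MAX = 3.0
#: half-width of the circumferential / radial angle bands (closed bands)
ANGLE_BAND_HALF_WIDTH = 22.5
#: minimum region size for a stable ellipse fit
MIN_CANAL_PIXELS = 5
#: moving-average window for periosteal contour smoothing, in µm
CONTOUR_SMOOTHING_UM = 50.0


# ---------------------------------------------------------------------------
# domain records


@dataclass
class CanalEllipse:
    """Ellipse fitted to a canal region: lengths in µm, angle in [0, 180)."""

    centroid: tuple[float, float]   # (x, y) µm
    major: float                    # full major-axis length a, µm
    minor: float                    # full minor-axis length b, µm
    angle_deg: float                # absolute major-axis angle
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not (self.major >= self.minor > 0):
            raise ValueError("need major >= minor > 0")
        self.angle_deg = float(self.angle_deg) % 180.0


@dataclass
class CanalMeasurement:
    aspect_ratio: float   # a / b, >= 1
    theta_deg: float      # acute angle to periosteal tangent, [0, 90]

    def __post_init__(self) -> None:
        if self.aspect_ratio < 1:
            raise ValueError("aspect ratio must be >= 1")
        if not 0.0 <= self.theta_deg <= 90.0:
            raise ValueError("theta must lie in [0, 90] degrees")


@dataclass
class LaminarityEstimate:
    n_total: int
    n_circumferential: int
    estimate: float
    ci_low: float | None
    ci_high: float | None
    confidence: float = 0.95

    @property
    def ci_half_width(self) -> float | None:
        if self.ci_low is None:
            return None
        return 0.5 * (self.ci_high - self.ci_low)


@dataclass
class DeformationReport:
    """Distortion introduced by octant straightening."""

    max_angle_deviation_deg: float
    circle_aspect_range: tuple[float, float]

    def within_gates(self, max_angle: float = 5.0, max_aspect: float = 1.17) -> bool:
        return (
            self.max_angle_deviation_deg <= max_angle
            and self.circle_aspect_range[1] <= max_aspect
        )


@dataclass
class CorticalOctant:
    label: str
    mask: np.ndarray
    contour_segment: np.ndarray   # (N, 2) µm along the periosteal surface
    center_deg: float


# ---------------------------------------------------------------------------
# periosteal contour handling


def contour_from_mask(mask: np.ndarray, pixel_scale: float) -> np.ndarray:
    """Outer (periosteal) contour of a cortical mask as (x, y) µm, CCW."""
    filled = ndimage.binary_fill_holes(np.asarray(mask, bool))
    contours = measure.find_contours(filled.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    rc = max(contours, key=len)
    pts = np.column_stack([rc[:, 1], rc[:, 0]]) * pixel_scale
    # enforce counter-clockwise orientation (positive shoelace area)
    area2 = np.sum(pts[:-1, 0] * pts[1:, 1] - pts[1:, 0] * pts[:-1, 1])
    if area2 < 0:
        pts = pts[::-1]
    return pts


def smooth_contour(points: np.ndarray, window_um: float = CONTOUR_SMOOTHING_UM) -> np.ndarray:
    """Circular moving-average smoothing of a closed contour."""
    pts = np.asarray(points, float)
    if len(pts) < 8:
        raise ValueError("contour needs at least 8 points")
    closed = np.allclose(pts[0], pts[-1])
    if closed:
        pts = pts[:-1]
    seg = np.linalg.norm(np.diff(pts, axis=0, append=pts[:1]), axis=1)
    mean_step = float(seg.mean())
    half = max(1, int(round(window_um / (2 * mean_step))))
    idx = np.arange(-half, half + 1)
    out = np.empty_like(pts)
    n = len(pts)
    for k in range(n):
        out[k] = pts[(k + idx) % n].mean(axis=0)
    if closed:
        out = np.vstack([out, out[:1]])
    return out


def tangent_at(contour: np.ndarray, point: np.ndarray | tuple[float, float]) -> float:
    """Angle (deg, [0, 180)) of the contour tangent nearest to ``point``."""
    pts = np.asarray(contour, float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    p = np.asarray(point, float)
    k = int(np.argmin(np.linalg.norm(pts - p, axis=1)))
    n = len(pts)
    d = pts[(k + 1) % n] - pts[(k - 1) % n]
    return float(np.degrees(np.arctan2(d[1], d[0])) % 180.0)


# ---------------------------------------------------------------------------
# octant extraction


def extract_cardinal_octants(
    mask: np.ndarray,
    pixel_scale: float,
    axes_deg: tuple[float, float] = (0.0, 90.0),
    labels: tuple[str, str, str, str] = ("anterior", "lateral", "posterior", "medial"),
) -> list[CorticalOctant]:
    """The four 45°-wide cardinal octants of a cortical ring.

    Octants are sectors about the section centroid centered on the two
    anatomical axes (and their opposites); the four diagonal octants are
    discarded.  ``axes_deg`` gives the angles of the two anatomical axes.
    """
    mask = np.asarray(mask, bool)
    filled = ndimage.binary_fill_holes(mask)
    if not (filled & ~mask).any():
        raise ValueError("mask is not ring-like: no enclosed medullary cavity")
    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    ang = np.degrees(np.arctan2(rows - cy, cols - cx)) % 360.0
    contour = smooth_contour(contour_from_mask(mask, pixel_scale))
    cont_ang = (
        np.degrees(
            np.arctan2(contour[:, 1] - cy * pixel_scale, contour[:, 0] - cx * pixel_scale)
        )
        % 360.0
    )
    centers = [axes_deg[0] % 360, axes_deg[1] % 360,
               (axes_deg[0] + 180) % 360, (axes_deg[1] + 180) % 360]
    octants = []
    for label, center in zip(labels, centers):
        dist = np.abs((ang - center + 180) % 360 - 180)
        sub = np.zeros_like(mask)
        sub[rows[dist <= 22.5], cols[dist <= 22.5]] = True
        cdist = np.abs((cont_ang - center + 180) % 360 - 180)
        seg = contour[cdist <= 22.5]
        # order the contour segment by angular position for a clean polyline
        seg_ang = (
            np.degrees(np.arctan2(seg[:, 1] - cy * pixel_scale, seg[:, 0] - cx * pixel_scale))
            - center + 180
        ) % 360 - 180
        seg = seg[np.argsort(seg_ang)]
        octants.append(CorticalOctant(label=label, mask=sub, contour_segment=seg,
                                      center_deg=center))
    return octants


# ---------------------------------------------------------------------------
# octant straightening


class StraightenMap:
    """Invertible map between a curved octant and its straightened frame.

    The straightened frame has the periosteal surface on the top row:
    column = arc length along the (smoothed) periosteal contour segment,
    row = depth into the cortex along the inward normal, both in units of
    ``step`` µm.
    """

    def __init__(self, anchors: np.ndarray, tangents: np.ndarray,
                 normals: np.ndarray, step: float, depth_um: float):
        self.anchors = anchors     # (W, 2) µm, points on the periosteal surface
        self.tangents = tangents   # (W, 2) unit vectors
        self.normals = normals     # (W, 2) unit inward normals
        self.step = step
        self.depth_um = depth_um

    @property
    def width(self) -> int:
        return len(self.anchors)

    @property
    def height(self) -> int:
        return int(np.ceil(self.depth_um / self.step)) + 1

    def to_original(self, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
        """Straightened (col, row) pixels -> original (x, y) µm."""
        cols = np.clip(np.asarray(cols, float), 0, self.width - 1)
        j0 = np.clip(cols.astype(int), 0, self.width - 2)
        f = (cols - j0)[..., None]
        p = self.anchors[j0] * (1 - f) + self.anchors[j0 + 1] * f
        n = self.normals[j0] * (1 - f) + self.normals[j0 + 1] * f
        return p + np.asarray(rows, float)[..., None] * self.step * n

    def to_straightened(self, points_um: np.ndarray) -> np.ndarray:
        """Original (x, y) µm -> straightened (col, row) pixel coordinates."""
        pts = np.atleast_2d(np.asarray(points_um, float))
        out = np.empty_like(pts)
        for i, p in enumerate(pts):
            j = int(np.argmin(np.linalg.norm(self.anchors - p, axis=1)))
            rel = p - self.anchors[j]
            s = j * self.step + float(rel @ self.tangents[j])
            d = float(rel @ self.normals[j])
            out[i] = (s / self.step, d / self.step)
        return out


@dataclass
class StraightenedOctant:
    image: np.ndarray
    map: StraightenMap


def straighten_octant(
    image: np.ndarray,
    contour_segment: np.ndarray,
    depth_um: float,
    pixel_scale: float,
    step_um: float | None = None,
    interior_point: np.ndarray | tuple[float, float] | None = None,
) -> StraightenedOctant:
    """Uncurve a cortical octant relative to its periosteal surface.

    Resamples the periosteal contour segment at uniform arc length and
    samples the image (bilinear) along inward normals, so the periosteal
    surface maps to the top row and arc length is preserved along it.
    Rejects octants whose curvature radius is smaller than the requested
    depth (the map would fold over).
    """
    step = pixel_scale if step_um is None else step_um
    seg = np.asarray(contour_segment, float)
    if len(seg) < 4:
        raise ValueError("contour segment too short")
    arclen = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(seg, axis=0), axis=1))])
    total = float(arclen[-1])
    n_cols = max(2, int(np.floor(total / step)) + 1)
    s = np.arange(n_cols) * step
    anchors = np.column_stack([np.interp(s, arclen, seg[:, 0]), np.interp(s, arclen, seg[:, 1])])
    grad = np.gradient(anchors, step, axis=0)
    tangents = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    if interior_point is None:
        interior_point = seg.mean(axis=0)  # curvature center side for convex arcs
    inward = np.asarray(interior_point, float) - anchors
    flip = np.sum(inward * normals, axis=1) < 0
    normals[flip] *= -1

    # fold-over gate: |kappa| * depth must stay below 1; curvature is
    # averaged over a ~40 µm window so raster noise does not dominate
    curv = np.linalg.norm(np.gradient(tangents, step, axis=0), axis=1)
    win = max(1, int(round(40.0 / step)))
    if len(curv) > win:
        kernel = np.ones(win) / win
        curv = np.convolve(curv, kernel, mode="same")
    kmax = float(curv.max())
    if kmax * depth_um >= 1.0:
        raise ValueError(
            f"contour curvature radius ({1.0 / kmax:.1f} µm) smaller than "
            f"requested depth ({depth_um:.1f} µm): straightening would fold over"
        )

    smap = StraightenMap(anchors, tangents, normals, step, depth_um)
    rows = np.arange(smap.height)
    cols = np.arange(smap.width)
    cgrid, rgrid = np.meshgrid(cols, rows)
    orig = smap.to_original(cgrid, rgrid)          # (H, W, 2) µm
    rr = orig[..., 1] / pixel_scale
    cc = orig[..., 0] / pixel_scale
    out = ndimage.map_coordinates(np.asarray(image, float), [rr, cc], order=1, cval=0.0)
    return StraightenedOctant(image=out, map=smap)


def validate_straightening(
    smap: StraightenMap,
    test_angles_deg: tuple[float, ...] = (0.0, 30.0, 45.0, 60.0, 90.0),
    circle_radius_um: float = 10.0,
    segment_length_um: float = 20.0,
    n_sites: int = 7,
) -> DeformationReport:
    """Measure the distortion a straightening map imposes.

    Overlays, in the original frame, short test segments at known angles
    to the local periosteal tangent and circles of known radius, pushes
    them through the map, and reports the worst angle deviation and the
    range of circle aspect ratios in the straightened frame.
    """
    w = smap.width
    sites = np.linspace(0.15 * w, 0.85 * w, n_sites).astype(int)
    mid = smap.depth_um / 2.0
    max_dev = 0.0
    aspects = []
    phis = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    for j in sites:
        center = smap.anchors[j] + mid * smap.normals[j]
        t, n = smap.tangents[j], smap.normals[j]
        for ang in test_angles_deg:
            a = np.radians(ang)
            direction = np.cos(a) * t + np.sin(a) * n
            ends = np.vstack([center - 0.5 * segment_length_um * direction,
                              center + 0.5 * segment_length_um * direction])
            sc = smap.to_straightened(ends)
            d = sc[1] - sc[0]
            meas = np.degrees(np.arctan2(d[1], d[0])) % 180.0
            dev = abs(meas - (ang % 180.0))
            max_dev = max(max_dev, min(dev, 180.0 - dev))
        circ = center + circle_radius_um * np.column_stack([np.cos(phis), np.sin(phis)])
        sc = smap.to_straightened(circ)
        cov = np.cov((sc - sc.mean(axis=0)).T)
        ev = np.linalg.eigvalsh(cov)
        aspects.append(float(np.sqrt(ev[1] / max(ev[0], 1e-30))))
    return DeformationReport(
        max_angle_deviation_deg=float(max_dev),
        circle_aspect_range=(float(min(aspects)), float(max(aspects))),
    )


# ---------------------------------------------------------------------------
# canal region processing


def split_branched_canal(region: np.ndarray) -> list[np.ndarray]:
    """Split a branched canal region at its skeleton junctions.

    Returns branch-free sub-regions whose pixel union equals the input
    region; an unbranched region is returned unchanged.
    """
    region = np.asarray(region, bool)
    skel = skeletonize(region)
    if skel.sum() < 3:
        return [region]
    kernel = np.ones((3, 3), int)
    kernel[1, 1] = 0
    nbrs = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    junctions = skel & (nbrs >= 3)
    if not junctions.any():
        return [region]
    branches = skel & ~junctions
    lab, nlab = ndimage.label(branches, structure=np.ones((3, 3), int))
    if nlab < 2:
        return [region]
    branch_pix = np.column_stack(np.nonzero(lab))
    branch_lab = lab[lab > 0]
    tree = cKDTree(branch_pix)
    reg_pix = np.column_stack(np.nonzero(region))
    _, idx = tree.query(reg_pix)
    assigned = branch_lab[idx]
    out = []
    for k in range(1, nlab + 1):
        sub = np.zeros_like(region)
        sel = reg_pix[assigned == k]
        if len(sel) == 0:
            continue
        sub[sel[:, 0], sel[:, 1]] = True
        out.append(sub)
    return out


def fit_canal_ellipse(
    region: np.ndarray, pixel_scale: float, is_primary: bool = True
) -> CanalEllipse:
    """Second-moment-matched ellipse of a canal pixel region.

    The fitted ellipse shares the region's centroid and central second
    moments (so a filled ellipse is recovered exactly up to
    rasterization); requires at least 5 pixels.
    """
    region = np.asarray(region, bool)
    rows, cols = np.nonzero(region)
    if rows.size < MIN_CANAL_PIXELS:
        raise ValueError(f"canal region has {rows.size} px, need >= {MIN_CANAL_PIXELS}")
    x = cols * pixel_scale
    y = rows * pixel_scale
    cx, cy = x.mean(), y.mean()
    dx, dy = x - cx, y - cy
    cov = np.array([[dx @ dx, dx @ dy], [dx @ dy, dy @ dy]]) / rows.size
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        raise ValueError("degenerate canal region: pixels are collinear")
    minor = 4.0 * np.sqrt(evals[0])
    major = 4.0 * np.sqrt(evals[1])
    vx, vy = evecs[:, 1]
    angle = float(np.degrees(np.arctan2(vy, vx)) % 180.0)
    return CanalEllipse(centroid=(float(cx), float(cy)), major=float(major),
                        minor=float(minor), angle_deg=angle, is_primary=is_primary)


def measure_canal(ellipse: CanalEllipse, tangent_deg: float) -> CanalMeasurement:
    """Aspect ratio and acute major-axis angle to the periosteal tangent."""
    diff = abs(ellipse.angle_deg - tangent_deg) % 180.0
    theta = min(diff, 180.0 - diff)
    if theta > 90.0:
        theta = 180.0 - theta
    return CanalMeasurement(aspect_ratio=ellipse.major / ellipse.minor,
                            theta_deg=float(theta))


def classify_canal(m: CanalMeasurement) -> str:
    """Assign one orientation class; the aspect-ratio test is applied first."""
    if m.aspect_ratio < LONGITUDINAL_ASPECT_MAX:
        return "longitudinal"
    if m.theta_deg <= ANGLE_BAND_HALF_WIDTH:
        return "circumferential"
    if m.theta_deg >= 90.0 - ANGLE_BAND_HALF_WIDTH:
        return "radial"
    return "oblique"


# ---------------------------------------------------------------------------
# laminarity index


def wilson_interval(
    x: int, n: int, confidence: float = 0.95, variant: str = "score"
) -> tuple[float, float, float]:
    """Wilson estimate of a proportion: (center, lo, hi).

    ``variant='score'`` is the Wilson score center and interval:
    p~ = (x + z^2/2) / (n + z^2), half-width
    z/(n + z^2) * sqrt(x(n-x)/n + z^2/4).  ``variant='plus4'`` is the
    add-two-successes-two-failures simplification.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    z = norm.ppf(0.5 + confidence / 2.0)
    if variant == "score":
        denom = n + z * z
        center = (x + z * z / 2.0) / denom
        half = (z / denom) * np.sqrt(x * (n - x) / n + z * z / 4.0)
    elif variant == "plus4":
        center = (x + 2.0) / (n + 4.0)
        half = z * np.sqrt(center * (1.0 - center) / (n + 4.0))
    else:
        raise ValueError(f"unknown Wilson variant {variant!r}")
    return float(center), float(max(center - half, 0.0)), float(min(center + half, 1.0))


def laminarity_index(
    n_circumferential: int,
    n_total: int,
    confidence: float = 0.95,
    variant: str = "score",
) -> LaminarityEstimate:
    """Laminarity index: Wilson-estimated proportion of circumferential canals.

    With no circumferential canals the index is reported as exactly 0
    with no interval; with no canals at all it is undefined.
    """
    if n_total <= 0:
        raise ValueError("laminarity undefined: no primary canals (n/a)")
    if n_circumferential < 0 or n_circumferential > n_total:
        raise ValueError("need 0 <= n_circumferential <= n_total")
    if n_circumferential == 0:
        return LaminarityEstimate(n_total=n_total, n_circumferential=0,
                                  estimate=0.0, ci_low=None, ci_high=None,
                                  confidence=confidence)
    center, lo, hi = wilson_interval(n_circumferential, n_total, confidence, variant)
    return LaminarityEstimate(n_total=n_total, n_circumferential=n_circumferential,
                              estimate=center, ci_low=lo, ci_high=hi,
                              confidence=confidence)


# ---------------------------------------------------------------------------
# whole-field drivers


def classify_canal_records(canals: pd.DataFrame, contour_um: np.ndarray) -> pd.DataFrame:
    """Classify pre-fitted canal ellipses against a periosteal contour.

    ``canals`` uses the canal-CSV schema (x_um, y_um, major_um, minor_um,
    angle_deg, is_primary).  Returns a copy with aspect_ratio, theta_deg
    and predicted_class columns.
    """
    contour = smooth_contour(contour_um)
    out = canals.copy()
    aspects, thetas, classes = [], [], []
    for _, row in canals.iterrows():
        ell = CanalEllipse(centroid=(row.x_um, row.y_um), major=row.major_um,
                           minor=row.minor_um, angle_deg=row.angle_deg,
                           is_primary=bool(row.get("is_primary", True)))
        tan = tangent_at(contour, ell.centroid)
        m = measure_canal(ell, tan)
        aspects.append(m.aspect_ratio)
        thetas.append(m.theta_deg)
        classes.append(classify_canal(m))
    out["aspect_ratio"] = aspects
    out["theta_deg"] = thetas
    out["predicted_class"] = classes
    return out


def analyze_canal_image(
    canal_mask: np.ndarray,
    contour_um: np.ndarray,
    pixel_scale: float,
    min_pixels: int = MIN_CANAL_PIXELS,
) -> pd.DataFrame:
    """Measure and classify every canal in a binary canal image.

    Labels connected canal regions, splits branched canals at skeleton
    junctions, fits an ellipse to each branch-free region, and classifies
    it against the local periosteal tangent.  Regions below
    ``min_pixels`` are dropped (logged).
    """
    contour = smooth_contour(contour_um)
    lab, nlab = ndimage.label(np.asarray(canal_mask, bool),
                              structure=np.ones((3, 3), int))
    records = []
    dropped = 0
    for k in range(1, nlab + 1):
        for sub in split_branched_canal(lab == k):
            if sub.sum() < min_pixels:
                dropped += 1
                continue
            try:
                ell = fit_canal_ellipse(sub, pixel_scale)
            except ValueError:
                dropped += 1
                continue
            tan = tangent_at(contour, ell.centroid)
            m = measure_canal(ell, tan)
            records.append({
                "x_um": ell.centroid[0], "y_um": ell.centroid[1],
                "major_um": ell.major, "minor_um": ell.minor,
                "angle_deg": ell.angle_deg, "aspect_ratio": m.aspect_ratio,
                "theta_deg": m.theta_deg, "predicted_class": classify_canal(m),
            })
    if dropped:
        log.info("dropped %d sub-threshold canal regions (< %d px)", dropped, min_pixels)
    return pd.DataFrame(records)
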