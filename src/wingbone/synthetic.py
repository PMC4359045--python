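"""Synthetic inputs for every pipeline stage.

Four generators with known ground truth:

* canal fields — annular cortices populated with elliptical vascular
  canals whose orientation class (longitudinal / circumferential /
  radial / oblique) is drawn from controlled proportions, with the canal
  angle generated relative to the local periosteal tangent so the truth
  label is exact under the classifier's own angle convention;
* cortical profiles — circular, elliptical, or offset-hole annuli
  rasterized to a binary mask with the closed-form section properties
  attached;
* growth series — logistic / Gompertz / von Bertalanffy curves with
  optional additive Gaussian noise;
* scaling datasets — pure-birth trees (rescaled to unit depth) carrying
  a bivariate trait where y = slope*x + intercept plus phylogenetically
  structured error under Brownian motion or an OU process.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import geometry as geom
from . import scaling as _scaling
from .canals import CANAL_CLASSES
from .growth import GROWTH_MODELS, growth_curve

#: default pixel scale of the histology imagery being emulated, µm/px
HISTOLOGY_PIXEL_SCALE_UM = 2.1

DEFAULT_ASPECT_RANGES = {
    "longitudinal": (1.0, 3.0),
    "circumferential": (3.5, 6.0),
    "radial": (3.5, 6.0),
    "oblique": (3.5, 6.0),
}


# ---------------------------------------------------------------------------
# canal fields


@dataclass
class SyntheticCanalFieldSpec:
    n_canals: int = 200
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"circumferential": 0.5, "longitudinal": 0.3,
                                 "radial": 0.1, "oblique": 0.1}
    )
    annulus_outer_radius: float = 900.0   # µm
    annulus_inner_radius: float = 500.0   # µm
    aspect_ratio_range_per_class: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ASPECT_RANGES)
    )
    minor_axis_um: tuple[float, float] = (10.0, 14.0)
    pixel_scale: float = HISTOLOGY_PIXEL_SCALE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_canals < 0:
            raise ValueError("n_canals must be >= 0")
        if not self.annulus_inner_radius < self.annulus_outer_radius:
            raise ValueError("degenerate annulus: inner radius must be < outer")
        unknown = set(self.class_proportions) - set(CANAL_CLASSES)
        if unknown:
            raise ValueError(f"unknown canal classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")


@dataclass
class CanalField:
    canals: pd.DataFrame       # x_um, y_um, major_um, minor_um, angle_deg,
    #                            true_class, is_primary
    mask: np.ndarray           # annular cortex mask
    contour: np.ndarray        # analytic periosteal contour, (N, 2) µm
    pixel_scale: float
    spec: SyntheticCanalFieldSpec


CANAL_COLUMNS = ["x_um", "y_um", "major_um", "minor_um", "angle_deg",
                 "true_class", "is_primary"]


def _theta_for_class(cls: str, rng: np.random.Generator) -> float:
    """Acute angle to the local periosteal tangent, per class band."""
    if cls == "circumferential":
        return float(rng.uniform(0.0, 22.5))
    if cls == "radial":
        return float(rng.uniform(67.5, 90.0))
    if cls == "oblique":
        return float(rng.uniform(22.5 + 1e-6, 67.5 - 1e-6))
    return float(rng.uniform(0.0, 90.0))  # longitudinal: angle is arbitrary


def generate_canal_field(spec: SyntheticCanalFieldSpec) -> CanalField:
    """Populate an annular cortex with canals of known orientation class.

    Canal centers are rejection-sampled so that neighboring canals do not
    touch (their fitted regions stay separable); the true class label is
    exact with respect to the analytic periosteal tangent at the canal's
    angular position.
    """
    rng = np.random.default_rng(spec.seed)
    r_out, r_in = spec.annulus_outer_radius, spec.annulus_inner_radius
    half = r_out + 6 * spec.pixel_scale
    npix = int(np.ceil(2 * half / spec.pixel_scale))
    yy, xx = np.mgrid[0:npix, 0:npix]
    cx_px = cy_px = npix / 2.0
    rr = np.hypot((xx - cx_px), (yy - cy_px)) * spec.pixel_scale
    mask = (rr <= r_out) & (rr >= r_in)
    phi = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    center = np.array([cx_px, cy_px]) * spec.pixel_scale
    contour = center + r_out * np.column_stack([np.cos(phi), np.sin(phi)])
    contour = np.vstack([contour, contour[:1]])

    classes = list(spec.class_proportions)
    probs = np.array([spec.class_proportions[c] for c in classes])
    drawn = rng.choice(classes, size=spec.n_canals, p=probs) if spec.n_canals else []

    records: list[dict] = []
    placed_xy: list[np.ndarray] = []
    placed_r: list[float] = []
    margin = 3.0 * spec.pixel_scale
    for cls in drawn:
        lo, hi = spec.aspect_ratio_range_per_class.get(cls, DEFAULT_ASPECT_RANGES[cls])
        aspect = float(rng.uniform(lo, hi))
        minor = float(rng.uniform(*spec.minor_axis_um))
        major = aspect * minor
        theta = _theta_for_class(cls, rng)
        a_semi = major / 2.0
        r_lo = r_in + a_semi + margin
        r_hi = r_out - a_semi - margin
        if r_lo >= r_hi:
            raise ValueError("annulus too thin for the requested canal sizes")
        for _ in range(400):
            ang = rng.uniform(0, 2 * np.pi)
            rad = np.sqrt(rng.uniform(r_lo**2, r_hi**2))
            pos = center + rad * np.array([np.cos(ang), np.sin(ang)])
            sep = a_semi + 4 * spec.pixel_scale
            ok = all(
                np.linalg.norm(pos - q) > sep + pr for q, pr in zip(placed_xy, placed_r)
            )
            if ok:
                break
        else:
            raise RuntimeError("could not place canal without overlap; lower n_canals")
        # local periosteal tangent of a circle is perpendicular to the radius
        tangent_deg = (np.degrees(ang) + 90.0) % 180.0
        sign = 1.0 if rng.random() < 0.5 else -1.0
        angle_abs = (tangent_deg + sign * theta) % 180.0
        placed_xy.append(pos)
        placed_r.append(a_semi)
        records.append({
            "x_um": pos[0], "y_um": pos[1], "major_um": major, "minor_um": minor,
            "angle_deg": angle_abs, "true_class": cls, "is_primary": True,
        })
    canals = pd.DataFrame(records, columns=CANAL_COLUMNS)
    return CanalField(canals=canals, mask=mask, contour=contour,
                      pixel_scale=spec.pixel_scale, spec=spec)


def render_canal_field(fld: CanalField) -> np.ndarray:
    """Rasterize the canal ellipses of a field into a binary canal image."""
    canal_mask = np.zeros_like(fld.mask)
    npix = fld.mask.shape[0]
    s = fld.pixel_scale
    for _, c in fld.canals.iterrows():
        a = c.major_um / 2.0
        b = c.minor_um / 2.0
        th = np.radians(c.angle_deg)
        # rasterize only within the ellipse's bounding box
        r0 = max(0, int((c.y_um - a) / s) - 1)
        r1 = min(npix, int((c.y_um + a) / s) + 2)
        c0 = max(0, int((c.x_um - a) / s) - 1)
        c1 = min(npix, int((c.x_um + a) / s) + 2)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dx = xx * s - c.x_um
        dy = yy * s - c.y_um
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        canal_mask[r0:r1, c0:c1] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return canal_mask


def write_canal_field(fld: CanalField, directory: str | Path, stem: str = "canal_field") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fld.canals.to_csv(directory / f"{stem}.csv", index=False)
    geom.write_mask(fld.mask, directory / f"{stem}_mask.png", fld.pixel_scale)


# ---------------------------------------------------------------------------
# cortical profiles


@dataclass
class SyntheticProfileSpec:
    shape: str = "circular"            # circular | elliptical | offset
    outer_semi_axes: tuple[float, float] = (2.0, 2.0)   # mm
    inner_semi_axes: tuple[float, float] = (1.0, 1.0)   # mm
    hole_offset: tuple[float, float] = (0.0, 0.0)       # mm
    resolution: int = 1024             # pixels across the outer major diameter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("circular", "elliptical", "offset"):
            raise ValueError(f"unknown profile shape {self.shape!r}")
        if self.resolution < 64:
            raise ValueError("resolution must be >= 64 px across the outer diameter")
        a, b = self.outer_semi_axes
        ai, bi = self.inner_semi_axes
        if a <= 0 or b <= 0 or ai < 0 or bi < 0:
            raise ValueError("semi-axes must be positive (inner may be 0 for a disc)")
        if self.shape == "offset":
            if abs(a - b) > 1e-12 or abs(ai - bi) > 1e-12:
                raise ValueError("offset shape requires circular outer and inner boundaries")
            d = float(np.hypot(*self.hole_offset))
            if ai > 0 and d + ai >= a:
                raise ValueError("hole touches or crosses the outer boundary")
        else:
            if ai >= a or bi >= b:
                raise ValueError("inner region must lie strictly inside the outer region")

    @property
    def pixel_scale(self) -> float:
        return 2.0 * max(self.outer_semi_axes) / self.resolution


@dataclass
class SyntheticProfile:
    profile: geom.CorticalProfile
    analytic: geom.SectionGeometry
    spec: SyntheticProfileSpec


def _analytic_geometry(spec: SyntheticProfileSpec) -> geom.SectionGeometry:
    """Closed-form section properties (computed from formulas, not pixels)."""
    a, b = spec.outer_semi_axes
    ai, bi = spec.inner_semi_axes
    if spec.shape in ("circular", "elliptical"):
        ca = np.pi * (a * b - ai * bi)
        ta = np.pi * a * b
        ix = np.pi / 4.0 * (a * b**3 - ai * bi**3)   # about x-axis (integrates y^2)
        iy = np.pi / 4.0 * (a**3 * b - ai**3 * bi)
        imax, imin = max(ix, iy), min(ix, iy)
        centroid = (0.0, 0.0)
        r_max = max(a, b)
    else:  # offset circular hole
        dx, dy = spec.hole_offset
        area_o = np.pi * a * a
        area_h = np.pi * ai * ai
        ca = area_o - area_h
        ta = area_o
        cx = -area_h * dx / ca
        cy = -area_h * dy / ca
        io = np.pi * a**4 / 4.0
        ih = np.pi * ai**4 / 4.0
        ixx = (io + area_o * cy**2) - (ih + area_h * (dy - cy) ** 2)
        iyy = (io + area_o * cx**2) - (ih + area_h * (dx - cx) ** 2)
        ixy = (area_o * cx * cy) - (area_h * (dx - cx) * (dy - cy))
        mean = 0.5 * (ixx + iyy)
        dev = np.sqrt((0.5 * (ixx - iyy)) ** 2 + ixy**2)
        imax, imin = mean + dev, mean - dev
        centroid = (cx, cy)
        r_max = a + float(np.hypot(cx, cy))
    j = imax + imin
    return geom.SectionGeometry(ca=float(ca), ta=float(ta), centroid=centroid,
                                imax=float(imax), imin=float(imin), j=float(j),
                                r_max=float(r_max), zp=float(j / r_max),
                                shape_ratio=float(imax / imin))


def generate_cortical_profile(spec: SyntheticProfileSpec) -> SyntheticProfile:
    """Rasterize a synthetic cortical ring with its analytic geometry attached."""
    s = spec.pixel_scale
    a, b = spec.outer_semi_axes
    ai, bi = spec.inner_semi_axes
    half = max(a, b) + 4 * s
    npix = int(np.ceil(2 * half / s))
    yy, xx = np.mgrid[0:npix, 0:npix]
    x = (xx - npix / 2.0) * s
    y = (yy - npix / 2.0) * s
    outer = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    if spec.shape == "offset":
        dx, dy = spec.hole_offset
        inner = (ai > 0) & (np.hypot(x - dx, y - dy) <= ai)
    else:
        inner = ((x / ai) ** 2 + (y / bi) ** 2 <= 1.0) if ai > 0 and bi > 0 else np.zeros_like(outer)
    mask = outer & ~inner
    profile = geom.CorticalProfile(mask=mask, pixel_scale=s)
    return SyntheticProfile(profile=profile, analytic=_analytic_geometry(spec), spec=spec)


# ---------------------------------------------------------------------------
# growth series


@dataclass
class SyntheticGrowthSpec:
    model: str = "logistic"
    A: float = 100.0           # asymptotic mass, g
    K: float = 0.1             # growth constant, 1/day
    t0: float = 30.0           # location parameter, day
    sampling_times: tuple[float, ...] = tuple(float(t) for t in range(0, 61, 2))
    noise_sd: float = 0.0      # g
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in GROWTH_MODELS:
            raise ValueError(f"unsupported growth model {self.model!r}")
        if self.A <= 0 or self.K <= 0:
            raise ValueError("A and K must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_growth_series(spec: SyntheticGrowthSpec) -> pd.DataFrame:
    """(age, mass) series from a growth model, with additive Gaussian noise."""
    if len(spec.sampling_times) == 0:
        raise ValueError("sampling_times must not be empty")
    t = np.asarray(spec.sampling_times, float)
    m = growth_curve(spec.model, t, spec.A, spec.K, spec.t0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        m = m + rng.normal(0.0, spec.noise_sd, size=m.shape)
    return pd.DataFrame({"age_days": t, "mass_g": m})


# ---------------------------------------------------------------------------
# scaling datasets


@dataclass
class SyntheticCladeSpec:
    n_tips: int = 32
    birth_rate: float = 1.0         # 1/My
    trait_model: str = "BM"         # BM | OU
    sigma2: float = 0.05            # residual variance rate
    alpha: float = 0.0              # OU strength, 1/unit depth
    true_slope: float = 0.75
    true_intercept: float = -2.0
    x_range: tuple[float, float] = (0.5, 4.0)   # log10 predictor span
    rescale_to_unit_depth: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.sigma2 < 0 or self.alpha < 0:
            raise ValueError("sigma2 and alpha must be >= 0")
        if self.trait_model not in ("BM", "OU"):
            raise ValueError(f"unknown trait model {self.trait_model!r}")


def simulate_pure_birth_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0, unit_depth: bool = True
) -> dendropy.Tree:
    """Pure-birth (Yule) tree, optionally rescaled to unit root-to-tip depth.

    The process starts from the root split (two lineages), waits
    exponential times with total rate k * birth_rate, splits a uniformly
    chosen lineage, and after reaching ``n_tips`` adds a final
    Exp(n * birth_rate) holding time so terminal branches are never
    zero-length (which would make the BM covariance singular).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace([f"s{i}" for i in range(1, n_tips + 1)])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node.birth_time = 0.0
    root = tree.seed_node
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        child.birth_time = 0.0
        root.add_child(child)
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(k)))
        node.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            node.add_child(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / (n_tips * birth_rate))
    for i, leaf in enumerate(active, start=1):
        leaf.taxon = tns.get_taxon(f"s{i}")
        leaf.split_time = t_end
    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = None
            continue
        end = getattr(node, "split_time", t_end)
        node.edge.length = end - node.birth_time
    if unit_depth and t_end > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= t_end
    return tree


def residual_covariance(
    tree: dendropy.Tree, trait_model: str, sigma2: float, alpha: float,
    order: list[str],
) -> np.ndarray:
    """sigma2-scaled residual covariance under BM or stationary OU."""
    if trait_model == "BM":
        _, v = _scaling.vcv_brownian(tree, order=order)
    else:
        _, v = _scaling.vcv_ou(tree, alpha, order=order)
    return sigma2 * v


def simulate_scaling_dataset(
    spec: SyntheticCladeSpec,
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Tree plus trait table where y = slope*x + intercept + phylo error."""
    tree = simulate_pure_birth_tree(spec.n_tips, spec.birth_rate, spec.seed,
                                    unit_depth=spec.rescale_to_unit_depth)
    labels = sorted(lbl for lbl in (leaf.taxon.label for leaf in tree.leaf_node_iter()))
    rng = np.random.default_rng(spec.seed)
    x = rng.uniform(*spec.x_range, size=spec.n_tips)
    y = spec.true_intercept + spec.true_slope * x
    if spec.sigma2 > 0:
        cov = residual_covariance(tree, spec.trait_model, spec.sigma2, spec.alpha, labels)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(spec.n_tips) * cov.max())
        y = y + chol @ rng.standard_normal(spec.n_tips)
    traits = pd.DataFrame({"species": labels, "x": x, "y": y})
    return tree, traits


def write_scaling_dataset(
    tree: dendropy.Tree, traits: pd.DataFrame, directory: str | Path,
    stem: str = "clade",
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tree.write(path=str(directory / f"{stem}.nwk"), schema="newick")
    traits.to_csv(directory / f"{stem}_traits.csv", index=False)
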