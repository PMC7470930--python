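"""Synthetic serial-section dendrite generator.

Generates trace datasets with the statistical structure the morphometry
pipeline assumes, so every stage is testable without microscopy data:

* a dendrite is a tube of ~0.3 µm radius around a tortuous, z-monotone axis
  (serial sections cut roughly transverse to the dendrite, as in a FIB/SEM
  run milling along the dendrite's course);
* spines sit at Poisson-sampled positions along the axis, each a spherical
  head of lognormal volume attached by a cylindrical neck of truncated-normal
  length protruding radially from the shaft;
* the PSD is a spherical cap on the head surface facing away from the shaft,
  with cap area coupled to head volume (A = c * V**b * lognormal noise); a
  perforated PSD is an annular cap whose central hole spans at least one
  section, so the discontinuity is recoverable from the traces;
* perforation probability follows a logistic model in log head volume whose
  intercept is calibrated so the marginal rate equals the configured group
  rate.

Every sampled quantity is recorded as ground truth, making parameter
recovery the test surface for the whole pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import expit
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .trace_io import Contour, ObjectHierarchy, SeriesMetadata, write_series

logger = logging.getLogger(__name__)

#: minimum neck length (µm); shorter protrusions grade into stubby spines
NECK_MIN = 0.05


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthGroupConfig:
    """Generative parameters of one (genotype, age) group.

    Head volumes are lognormal, parametrized by the group mean and median
    (``mu = ln(median)``, ``sigma = sqrt(2 ln(mean/median))``).  PSD area is
    ``psd_coupling_slope * V**psd_coupling_exponent`` times lognormal noise
    of sigma ``psd_noise_sd``.  ``perforation_prob`` is the target marginal
    perforation rate; with a nonzero ``perforation_volume_odds_slope`` the
    logistic intercept is calibrated so the marginal rate is preserved while
    larger spines are more likely to be perforated.
    """

    genotype: str
    age_months: float
    n_dendrites: int
    dendrite_length_mean: float          # µm
    dendrite_length_sd: float            # µm
    spine_density: float                 # spines / µm
    head_volume_mean: float              # µm³
    head_volume_median: float            # µm³
    neck_length_mean: float              # µm (pre-truncation normal mean)
    neck_length_sd: float                # µm
    psd_coupling_slope: float = 1.0      # µm² per µm³**exponent
    psd_coupling_exponent: float = 1.0
    psd_noise_sd: float = 0.3            # lognormal sigma
    perforation_prob: float = 0.05       # target marginal rate
    perforation_volume_odds_slope: float = 1.5
    shaft_radius_mean: float = 0.30      # µm
    shaft_radius_sd: float = 0.03
    section_thickness_nm: float = 50.0
    pixel_size_nm: float = 4.5

    def __post_init__(self) -> None:
        for name in (
            "n_dendrites", "dendrite_length_mean", "dendrite_length_sd",
            "spine_density", "head_volume_mean", "head_volume_median",
            "neck_length_mean", "neck_length_sd", "psd_coupling_slope",
            "shaft_radius_mean", "section_thickness_nm", "pixel_size_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.head_volume_median > self.head_volume_mean:
            raise ValueError("lognormal model requires median <= mean")
        if not 0.0 <= self.perforation_prob <= 1.0:
            raise ValueError("perforation_prob must be in [0, 1]")
        if self.psd_noise_sd < 0:
            raise ValueError("psd_noise_sd must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.genotype}_{self.age_months:g}mo"

    @property
    def section_thickness_um(self) -> float:
        return self.section_thickness_nm / 1000.0

    def neck_truth_mean(self) -> float:
        """Mean of the truncated-normal neck-length distribution."""
        a = (NECK_MIN - self.neck_length_mean) / self.neck_length_sd
        return float(
            sps.truncnorm.mean(a, np.inf, loc=self.neck_length_mean,
                               scale=self.neck_length_sd)
        )


@dataclass
class SpineTruth:
    spine_id: str
    dendrite_id: str
    head_volume: float
    head_radius: float
    neck_length: float
    psd_area: float          # realized (after clamping to the head surface)
    perforated: bool
    psd_cos_inner: float     # 1.0 for macular PSDs
    psd_cos_outer: float


@dataclass
class DendriteTruth:
    dendrite_id: str
    arc_length: float        # target at sampling; realized after build_geometry
    n_spines: int


@dataclass
class GroupTruth:
    """All sampled ground-truth values of one group."""

    genotype: str
    age_months: float
    spines: list[SpineTruth] = field(default_factory=list)
    dendrites: list[DendriteTruth] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.genotype}_{self.age_months:g}mo"


# ---------------------------------------------------------------------------
# distribution helpers
# ---------------------------------------------------------------------------

def lognormal_params_from_mean_median(mean: float, median: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) matching a given mean and median.

    mu = ln(median); sigma = sqrt(2 ln(mean/median)).  Requires
    mean >= median > 0 (right skew); mean == median degenerates to a point
    mass at the median.
    """
    if median <= 0:
        raise ValueError("median must be > 0")
    if mean < median:
        raise ValueError("mean < median is incompatible with a lognormal model")
    mu = math.log(median)
    sigma = math.sqrt(2.0 * math.log(mean / median))
    return mu, sigma


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(101)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _calibrate_perforation_intercept(
    target: float, slope: float, mu: float, sigma: float
) -> float:
    """Intercept b0 so that E[logistic(b0 + slope*ln V)] = target.

    The expectation over ln V ~ N(mu, sigma^2) is evaluated by Gauss-Hermite
    quadrature; b0 is solved by bisection (the expectation is monotone).
    """
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    lnv = mu + sigma * _GH_NODES

    def marginal(b0: float) -> float:
        return float(np.sum(_GH_WEIGHTS * expit(b0 + slope * lnv)))

    return float(optimize.brentq(lambda b: marginal(b) - target, -60.0, 60.0))


def _psd_cap_angles(
    area: float, head_radius: float, perforated: bool, section_thickness: float
) -> tuple[float, float, float]:
    """(cos_inner, cos_outer, realized_area) of a PSD cap on a sphere.

    The cap is the set of head-surface points within polar angle
    [acos(cos_inner), acos(cos_outer)] of the PSD axis; a macular PSD has
    cos_inner = 1 (no hole).  A perforated PSD's hole is sized to span at
    least one section plane so the discontinuity survives slicing.  The
    outer angle is capped at ~126 degrees; the realized area is clamped
    accordingly.
    """
    r = head_radius
    full = 2.0 * math.pi * r * r  # area per unit of cos-angle span
    if perforated:
        sin_i = min(0.65, max(0.30, 1.2 * section_thickness / r))
        cos_i = math.sqrt(1.0 - sin_i * sin_i)
    else:
        cos_i = 1.0
    cos_o = cos_i - area / full
    cos_min = -0.6
    if cos_o < cos_min:
        cos_o = cos_min
    realized = full * (cos_i - cos_o)
    return cos_i, cos_o, realized


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

def sample_spine_population(
    config: SynthGroupConfig, rng: np.random.Generator
) -> GroupTruth:
    """Draw the per-dendrite and per-spine ground truth for one group.

    Dendrite lengths ~ Normal(mean, sd) clipped to [5, 25] µm; spine counts
    ~ Poisson(density x length); head volumes lognormal; neck lengths
    truncated-normal >= 0.05 µm; PSD areas coupled to volume with lognormal
    noise; perforation Bernoulli with volume-dependent odds.
    """
    mu, sigma = lognormal_params_from_mean_median(
        config.head_volume_mean, config.head_volume_median
    )
    b0 = _calibrate_perforation_intercept(
        config.perforation_prob, config.perforation_volume_odds_slope, mu, sigma
    )
    a = (NECK_MIN - config.neck_length_mean) / config.neck_length_sd

    truth = GroupTruth(genotype=config.genotype, age_months=config.age_months)
    for d in range(config.n_dendrites):
        did = f"{truth.label}_d{d}"
        length = float(
            np.clip(
                rng.normal(config.dendrite_length_mean, config.dendrite_length_sd),
                5.0, 25.0,
            )
        )
        n_spines = int(rng.poisson(config.spine_density * length))
        truth.dendrites.append(
            DendriteTruth(dendrite_id=did, arc_length=length, n_spines=n_spines)
        )
        for s in range(n_spines):
            v = float(rng.lognormal(mu, sigma)) if sigma > 0 else math.exp(mu)
            r = (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
            neck = float(
                sps.truncnorm.rvs(
                    a, np.inf, loc=config.neck_length_mean,
                    scale=config.neck_length_sd, random_state=rng,
                )
            )
            area = config.psd_coupling_slope * v ** config.psd_coupling_exponent
            if config.psd_noise_sd > 0:
                area *= float(rng.lognormal(0.0, config.psd_noise_sd))
            if np.isinf(b0):
                perforated = b0 > 0
            else:
                p = float(expit(b0 + config.perforation_volume_odds_slope * math.log(v)))
                perforated = bool(rng.random() < p)
            cos_i, cos_o, realized = _psd_cap_angles(
                area, r, perforated, config.section_thickness_um
            )
            truth.spines.append(
                SpineTruth(
                    spine_id=f"{did}_s{s}",
                    dendrite_id=did,
                    head_volume=v,
                    head_radius=r,
                    neck_length=neck,
                    psd_area=realized,
                    perforated=perforated,
                    psd_cos_inner=cos_i,
                    psd_cos_outer=cos_o,
                )
            )
    return truth


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

@dataclass
class SpineGeom:
    spine_id: str
    head_center: np.ndarray
    head_radius: float
    direction: np.ndarray    # unit vector, shaft surface -> head
    neck_radius: float
    neck_p0: np.ndarray
    neck_p1: np.ndarray
    psd_cos_inner: float
    psd_cos_outer: float


@dataclass
class DendriteScene:
    dendrite_id: str
    axis: np.ndarray         # (n, 3) polyline, z-monotone
    shaft_radius: float
    spines: list[SpineGeom]


_AXIS_STEP = 0.05  # µm; axis integration step
_MAX_TILT = 0.30   # rad; max axis deviation from the milling (z) direction


def _tortuous_axis(length: float, rng: np.random.Generator) -> np.ndarray:
    """z-monotone random axis of the given arc length (random-walk tilt)."""
    n_steps = max(2, round(length / _AXIS_STEP))
    pts = np.zeros((n_steps + 1, 3))
    tilt = rng.uniform(0.0, 0.15)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    for k in range(n_steps):
        tilt = float(np.clip(tilt + rng.normal(0.0, 0.02), 0.0, _MAX_TILT))
        phi += rng.normal(0.0, 0.25)
        step = np.array(
            [math.sin(tilt) * math.cos(phi), math.sin(tilt) * math.sin(phi),
             math.cos(tilt)]
        )
        pts[k + 1] = pts[k] + _AXIS_STEP * step
    return pts


def _radial_direction(tangent: np.ndarray, azimuth: float) -> np.ndarray:
    """Unit vector perpendicular to the axis tangent at the given azimuth."""
    t = tangent / np.linalg.norm(tangent)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(t, ref)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return math.cos(azimuth) * u + math.sin(azimuth) * v


def build_geometry(
    truth: GroupTruth, config: SynthGroupConfig, rng: np.random.Generator
) -> list[DendriteScene]:
    """Realize the sampled truth as 3D scenes (one per dendrite).

    Spine heads are spheres attached by cylindrical necks protruding
    radially from the shaft tube.  Placement collisions between heads are
    resolved by jittered re-placement (up to 100 attempts, then an error).
    The realized axis arc length is written back into the dendrite truth.
    """
    spines_by_dendrite: dict[str, list[SpineTruth]] = {}
    for s in truth.spines:
        spines_by_dendrite.setdefault(s.dendrite_id, []).append(s)

    scenes = []
    for dtruth in truth.dendrites:
        axis = _tortuous_axis(dtruth.arc_length, rng)
        n_seg = len(axis) - 1
        dtruth.arc_length = n_seg * _AXIS_STEP  # realized arc length
        shaft_radius = float(
            np.clip(rng.normal(config.shaft_radius_mean, config.shaft_radius_sd),
                    0.15, 0.5)
        )
        placed: list[SpineGeom] = []
        for st in spines_by_dendrite.get(dtruth.dendrite_id, []):
            for attempt in range(100):
                u = rng.uniform(0.05, 0.95)
                seg = int(u * n_seg)
                anchor = axis[seg]
                tangent = axis[seg + 1] - axis[seg]
                direction = _radial_direction(tangent, rng.uniform(0, 2 * math.pi))
                offset = shaft_radius + st.neck_length + st.head_radius
                center = anchor + offset * direction
                ok = all(
                    np.linalg.norm(center - q.head_center)
                    >= st.head_radius + q.head_radius + 0.02
                    for q in placed
                )
                if ok:
                    break
            else:
                raise RuntimeError(
                    f"could not place spine {st.spine_id!r} without overlap "
                    "after 100 attempts"
                )
            neck_radius = float(np.clip(0.35 * st.head_radius, 0.04, 0.09))
            placed.append(
                SpineGeom(
                    spine_id=st.spine_id,
                    head_center=center,
                    head_radius=st.head_radius,
                    direction=direction,
                    neck_radius=neck_radius,
                    neck_p0=anchor + 0.8 * shaft_radius * direction,
                    neck_p1=center - 0.5 * st.head_radius * direction,
                    psd_cos_inner=st.psd_cos_inner,
                    psd_cos_outer=st.psd_cos_outer,
                )
            )
        scenes.append(
            DendriteScene(
                dendrite_id=dtruth.dendrite_id,
                axis=axis,
                shaft_radius=shaft_radius,
                spines=placed,
            )
        )
    return scenes


# ---------------------------------------------------------------------------
# slicing
# ---------------------------------------------------------------------------

def _circle_points(
    cx: float, cy: float, rho: float, max_sagitta: float
) -> np.ndarray:
    """Closed-contour vertices of a circle, area-preserving polygonization.

    Vertex count is chosen so the chord sagitta stays below ``max_sagitta``
    (the pixel size); the vertex radius is inflated so the polygon area
    equals the disc area exactly, keeping slab-volume estimates unbiased.
    """
    if rho <= 0:
        raise ValueError("rho must be > 0")
    frac = min(0.5, max_sagitta / rho)
    n = max(12, math.ceil(math.pi / math.acos(1.0 - frac)))
    r_eff = rho * math.sqrt(2.0 * math.pi / (n * math.sin(2.0 * math.pi / n)))
    ang = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack([cx + r_eff * np.cos(ang), cy + r_eff * np.sin(ang)])


def _axis_point_at_z(axis: np.ndarray, z: float) -> Optional[np.ndarray]:
    """Interpolate the (z-monotone) axis polyline at height z."""
    zs = axis[:, 2]
    if z < zs[0] or z > zs[-1]:
        return None
    i = int(np.searchsorted(zs, z, side="right")) - 1
    i = min(max(i, 0), len(axis) - 2)
    dz = zs[i + 1] - zs[i]
    t = 0.0 if dz == 0 else (z - zs[i]) / dz
    return axis[i] + t * (axis[i + 1] - axis[i])


def _sphere_chain(p0: np.ndarray, p1: np.ndarray, radius: float,
                  spacing: float) -> np.ndarray:
    """(n, 4) array of sphere (x, y, z, r) filling the segment p0 -> p1."""
    length = float(np.linalg.norm(p1 - p0))
    n = max(2, math.ceil(length / spacing) + 1)
    t = np.linspace(0.0, 1.0, n)
    centers = p0 + t[:, None] * (p1 - p0)
    return np.column_stack([centers, np.full(n, radius)])


def _union_contours(
    spheres: np.ndarray, z: float, max_sagitta: float
) -> list[np.ndarray]:
    """Closed contours of the union of sphere cross-sections at height z."""
    discs = []
    for cx, cy, cz, r in spheres:
        dz = z - cz
        if abs(dz) >= r:
            continue
        rho = math.sqrt(r * r - dz * dz)
        if rho < 1e-4:
            continue
        discs.append(Polygon(_circle_points(cx, cy, rho, max_sagitta)))
    if not discs:
        return []
    merged = unary_union(discs)
    polys = [merged] if merged.geom_type == "Polygon" else list(merged.geoms)
    out = []
    for poly in polys:
        pts = np.asarray(poly.exterior.coords)[:-1]
        if len(pts) >= 3:
            out.append(pts)
        else:
            logger.warning("degenerate cross-section at z=%.3f dropped", z)
    return out


def _psd_arcs(
    center: np.ndarray,
    r: float,
    axis_dir: np.ndarray,
    cos_inner: float,
    cos_outer: float,
    z: float,
) -> list[np.ndarray]:
    """Open arc traces of a (possibly annular) spherical cap at height z.

    The cap is {p on sphere: cos_outer <= cos(angle(p - c, axis)) <=
    cos_inner}; its intersection with a section plane is zero, one or two
    circular arcs, returned as in-plane polylines.
    """
    dz = z - center[2]
    if abs(dz) >= r:
        return []
    rho = math.sqrt(r * r - dz * dz)
    ax, ay, az = axis_dir
    lat = math.hypot(ax, ay)
    if lat < 1e-9:
        # PSD axis along z: the circle is entirely in or out of the cap
        cosg = dz * az / r
        if cos_outer <= cosg <= cos_inner:
            ang = np.linspace(0.0, 2.0 * math.pi, 64)
            return [np.column_stack([center[0] + rho * np.cos(ang),
                                     center[1] + rho * np.sin(ang)])]
        return []
    psi0 = math.atan2(ay, ax)
    lo = (r * cos_outer - dz * az) / (rho * lat)
    hi = (r * cos_inner - dz * az) / (rho * lat)
    if lo > 1.0 or hi < -1.0 or hi < lo:
        return []
    u1 = math.acos(min(1.0, max(-1.0, hi)))   # inner limit (hole edge)
    u2 = math.acos(min(1.0, max(-1.0, lo)))   # outer limit
    if hi >= 1.0:
        intervals = [(-u2, u2)]               # single arc through psi0
    else:
        intervals = [(u1, u2), (-u2, -u1)]    # hole splits the arc in two
    arcs = []
    for a0, a1 in intervals:
        span = a1 - a0
        if span < 0.02:
            continue
        n = max(2, math.ceil(span / 0.08) + 1)
        ang = psi0 + np.linspace(a0, a1, n)
        arcs.append(
            np.column_stack([center[0] + rho * np.cos(ang),
                             center[1] + rho * np.sin(ang)])
        )
    return arcs


def slice_to_series(
    scene: DendriteScene,
    section_thickness_nm: float,
    pixel_size_nm: float,
    source_id: str = "",
) -> tuple[SeriesMetadata, list[Contour], ObjectHierarchy]:
    """Cut one dendrite scene into serial sections.

    The scene is translated so everything fits inside the stack with a
    one-section margin; solids become closed contours (the shaft as an
    idealized disc around the axis, heads as circles, necks as unions of
    sphere cross-sections) and PSD caps become open arc traces.
    """
    t = section_thickness_nm / 1000.0
    px = pixel_size_nm / 1000.0

    # collect bounds over axis tube and all spine solids
    lo = np.min(scene.axis, axis=0) - scene.shaft_radius
    hi = np.max(scene.axis, axis=0) + scene.shaft_radius
    for sp in scene.spines:
        lo = np.minimum(lo, sp.head_center - sp.head_radius)
        hi = np.maximum(hi, sp.head_center + sp.head_radius)
        for p in (sp.neck_p0, sp.neck_p1):
            lo = np.minimum(lo, p - sp.neck_radius)
            hi = np.maximum(hi, p + sp.neck_radius)
    shift = t - lo  # one-section margin, all coordinates positive
    axis = scene.axis + shift
    n_sections = int(math.ceil((hi + shift)[2] / t)) + 2

    metadata = SeriesMetadata(
        pixel_size_nm=pixel_size_nm,
        section_thickness_nm=section_thickness_nm,
        n_sections=n_sections,
        source_id=source_id or scene.dendrite_id,
    )
    hierarchy = ObjectHierarchy()
    did = scene.dendrite_id
    hierarchy.add(did, "shaft", None)

    contours: list[Contour] = []
    z_levels = np.arange(n_sections) * t

    # shaft: one disc per section between the axis ends (flat-cut ends)
    for k, z in enumerate(z_levels):
        p = _axis_point_at_z(axis, z)
        if p is None:
            continue
        contours.append(
            Contour(
                section=k,
                object_id=did,
                points=_circle_points(p[0], p[1], scene.shaft_radius, px),
                closed=True,
            )
        )

    for sp in scene.spines:
        sid = sp.spine_id
        hierarchy.add(sid, "spine_head", did)
        center = sp.head_center + shift
        k_lo = max(0, int(math.floor((center[2] - sp.head_radius) / t)) )
        k_hi = min(n_sections - 1, int(math.ceil((center[2] + sp.head_radius) / t)))
        for k in range(k_lo, k_hi + 1):
            dz = z_levels[k] - center[2]
            if abs(dz) >= sp.head_radius:
                continue
            rho = math.sqrt(sp.head_radius**2 - dz * dz)
            if rho < 1e-4:
                continue
            contours.append(
                Contour(
                    section=k,
                    object_id=sid,
                    points=_circle_points(center[0], center[1], rho, px),
                    closed=True,
                )
            )

        nid = f"{sid}_neck"
        hierarchy.add(nid, "spine_neck", sid)
        chain = _sphere_chain(
            sp.neck_p0 + shift, sp.neck_p1 + shift, sp.neck_radius,
            spacing=min(sp.neck_radius, t) / 2.0,
        )
        zmin, zmax = chain[:, 2].min() - sp.neck_radius, chain[:, 2].max() + sp.neck_radius
        for k in range(max(0, int(zmin // t)), min(n_sections, int(zmax // t) + 2)):
            for pts in _union_contours(chain, z_levels[k], px):
                contours.append(Contour(section=k, object_id=nid, points=pts, closed=True))

        pid = f"{sid}_psd"
        hierarchy.add(pid, "psd", sid)
        for k in range(k_lo, k_hi + 1):
            for pts in _psd_arcs(
                center, sp.head_radius, sp.direction,
                sp.psd_cos_inner, sp.psd_cos_outer, z_levels[k],
            ):
                contours.append(Contour(section=k, object_id=pid, points=pts, closed=False))

    hierarchy.validate()
    return metadata, contours, hierarchy


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_group(
    config: SynthGroupConfig,
    seed: int | np.random.SeedSequence,
    out_dir: Optional[Path] = None,
) -> tuple[GroupTruth, list[tuple[SeriesMetadata, list[Contour], ObjectHierarchy]], pd.DataFrame]:
    """Sample, build and slice one group; optionally write series files."""
    rng = np.random.default_rng(seed)
    truth = sample_spine_population(config, rng)
    scenes = build_geometry(truth, config, rng)
    series = []
    rows = []
    for scene in scenes:
        md, contours, hierarchy = slice_to_series(
            scene, config.section_thickness_nm, config.pixel_size_nm,
            source_id=f"synthetic-{scene.dendrite_id}",
        )
        series.append((md, contours, hierarchy))
        fname = f"{scene.dendrite_id}.json"
        rows.append(
            {
                "file": fname,
                "genotype": config.genotype,
                "age_months": config.age_months,
                "dendrite_id": scene.dendrite_id,
                "n_sections": md.n_sections,
                "n_contours": len(contours),
                "n_spines_true": len(scene.spines),
            }
        )
        if out_dir is not None:
            write_series(md, contours, hierarchy, Path(out_dir) / fname)
    manifest = pd.DataFrame(rows)
    return truth, series, manifest


def truth_tables(truths: Sequence[GroupTruth]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten ground truth into per-spine and per-dendrite tables."""
    spine_rows = []
    dend_rows = []
    for g in truths:
        for s in g.spines:
            spine_rows.append(
                {
                    "genotype": g.genotype, "age_months": g.age_months,
                    "spine_id": s.spine_id, "dendrite_id": s.dendrite_id,
                    "head_volume_um3": s.head_volume,
                    "neck_length_um": s.neck_length,
                    "psd_area_um2": s.psd_area,
                    "perforated": s.perforated,
                }
            )
        for d in g.dendrites:
            dend_rows.append(
                {
                    "genotype": g.genotype, "age_months": g.age_months,
                    "dendrite_id": d.dendrite_id,
                    "arc_length_um": d.arc_length,
                    "n_spines": d.n_spines,
                }
            )
    return pd.DataFrame(spine_rows), pd.DataFrame(dend_rows)


def generate_dataset(
    configs: Sequence[SynthGroupConfig],
    master_seed: int,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Generate a full multi-group dataset on disk.

    One JSON series file per dendrite, plus ``manifest.csv`` binding files
    to groups and ``truth_spines.csv`` / ``truth_dendrites.csv`` with the
    generative ground truth.  Output is reproducible for a fixed seed.
    """
    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels in configs")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(master_seed).spawn(len(configs))
    manifests = []
    truths = []
    for config, child in zip(configs, children):
        truth, _, manifest = generate_group(config, child, out_dir=out_dir)
        truths.append(truth)
        manifests.append(manifest)
    manifest = pd.concat(manifests, ignore_index=True)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    spines, dendrites = truth_tables(truths)
    spines.to_csv(out_dir / "truth_spines.csv", index=False, float_format="%.8g")
    dendrites.to_csv(out_dir / "truth_dendrites.csv", index=False, float_format="%.8g")
    return manifest
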