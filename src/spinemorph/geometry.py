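"""Morphometry from serial-section contour traces.

All quantities follow the serial-reconstruction conventions used with
Reconstruct-style tracing:

* object volume = sum over traced sections of (contour area x section
  thickness) — the rectangle rule, no interpolation between sections;
* surface area = sum of (contour perimeter x thickness), plus the two
  extremal contour areas when end caps are included;
* PSD area = section thickness x summed length of the open PSD traces in
  consecutive sections;
* neck length and dendrite length are 3D polyline lengths, with the z
  position of section k at k x thickness.

These estimators carry a stair-step bias relative to smooth surfaces (the
lateral surface of a sphere is overestimated, volumes are unbiased only on
average over section phase); the bias is documented, not corrected, because
it is the convention the source measurements were made with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon

from .trace_io import (
    Contour,
    DendriteRecord,
    ObjectHierarchy,
    SeriesMetadata,
    SpineRecord,
)

logger = logging.getLogger(__name__)


class GeometryError(ValueError):
    """A geometric precondition is violated (degenerate or invalid input)."""


@dataclass
class MorphometryConfig:
    """Tunable knobs of the measurement pipeline.

    size_cutoff
        Head-volume threshold (µm³) splitting small (thin-type) from large
        (mushroom-type) spines; volumes exactly at the cutoff count as small.
    include_end_caps
        Add the two extremal contour areas to the lateral surface area.
    boundary_policy
        ``exclude_touching`` drops spines whose head reaches the first or
        last section from downstream statistics; ``include_all`` keeps them.
    """

    size_cutoff: float = 0.04
    include_end_caps: bool = True
    boundary_policy: str = "exclude_touching"

    def __post_init__(self) -> None:
        if self.size_cutoff <= 0:
            raise ValueError("size_cutoff must be > 0")
        if self.boundary_policy not in ("exclude_touching", "include_all"):
            raise ValueError(f"unknown boundary_policy {self.boundary_policy!r}")


# ---------------------------------------------------------------------------
# planar primitives
# ---------------------------------------------------------------------------

def _require_simple(points: np.ndarray) -> None:
    if not Polygon(points).is_valid:
        raise GeometryError("contour is self-intersecting or degenerate")


def contour_area(contour: Contour) -> float:
    """Planimetric area (µm²) of a closed contour, by the shoelace formula.

    The absolute value is taken so vertex orientation (image y-axis points
    down) never flips the sign.
    """
    if not contour.closed:
        raise GeometryError("contour_area requires a closed contour")
    pts = contour.points
    _require_simple(pts)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def contour_perimeter(contour: Contour) -> float:
    """Perimeter (µm) of a closed contour."""
    if not contour.closed:
        raise GeometryError("contour_perimeter requires a closed contour")
    pts = contour.points
    return float(np.sum(np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)))


def contour_centroid(contour: Contour) -> np.ndarray:
    """Area centroid of a closed contour (µm)."""
    if not contour.closed:
        raise GeometryError("contour_centroid requires a closed contour")
    c = Polygon(contour.points).centroid
    return np.array([c.x, c.y])


def polyline_length_2d(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


# ---------------------------------------------------------------------------
# per-object quantities
# ---------------------------------------------------------------------------

def object_volume(contours: Sequence[Contour], section_thickness: float) -> float:
    """Volume (µm³) of one traced solid: sum of contour areas x thickness."""
    closed = [c for c in contours if c.closed]
    if not closed:
        raise GeometryError("object_volume: object has no closed contours")
    return sum(contour_area(c) for c in closed) * section_thickness


def object_surface_area(
    contours: Sequence[Contour],
    section_thickness: float,
    include_end_caps: bool = True,
) -> float:
    """Surface area (µm²): lateral (perimeter x thickness) + optional end caps.

    The caps are the areas of the contours on the first and last traced
    sections.  Relative to a smooth surface the lateral term overestimates
    (stair-step artifact); no correction is applied.
    """
    closed = [c for c in contours if c.closed]
    if not closed:
        raise GeometryError("object_surface_area: object has no closed contours")
    area = sum(contour_perimeter(c) for c in closed) * section_thickness
    if include_end_caps:
        # two caps even for a single-section object (top and bottom of the slab)
        lo = min(c.section for c in closed)
        hi = max(c.section for c in closed)
        area += sum(contour_area(c) for c in closed if c.section == lo)
        area += sum(contour_area(c) for c in closed if c.section == hi)
    return area


def psd_area(traces: Sequence[Contour], section_thickness: float) -> float:
    """PSD area (µm²) = thickness x summed in-plane length of the open traces."""
    if not traces:
        raise GeometryError("psd_area: no PSD traces given")
    total = 0.0
    for t in traces:
        length = polyline_length_2d(t.points)
        if length == 0.0:
            logger.warning(
                "zero-length PSD trace for object %r on section %d contributes 0",
                t.object_id, t.section,
            )
        total += length
    return total * section_thickness


def path_length(points: np.ndarray) -> float:
    """3D polyline length (µm)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise GeometryError("path_length requires >= 2 points of shape (n, 3)")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def dendrite_path_length(
    shaft_contours: Sequence[Contour], section_thickness: float
) -> tuple[float, np.ndarray]:
    """Dendrite length (µm) along the polyline of per-section shaft centroids.

    Returns the length and the (n, 3) axis polyline.  Centroids are
    area-weighted when a section holds several shaft contours.  Requires the
    shaft to be traced on at least two sections.
    """
    closed = [c for c in shaft_contours if c.closed]
    by_section: dict[int, list[Contour]] = {}
    for c in closed:
        by_section.setdefault(c.section, []).append(c)
    if len(by_section) < 2:
        raise GeometryError("dendrite_path_length: shaft traced on < 2 sections")
    axis = []
    for sec in sorted(by_section):
        cs = by_section[sec]
        areas = np.array([contour_area(c) for c in cs])
        cents = np.array([contour_centroid(c) for c in cs])
        if areas.sum() == 0:
            raise GeometryError(f"zero-area shaft contour(s) on section {sec}")
        xy = (cents * areas[:, None]).sum(axis=0) / areas.sum()
        axis.append([xy[0], xy[1], sec * section_thickness])
    axis = np.asarray(axis)
    return path_length(axis), axis


def spine_density(n_spines: int, dendrite_length: float) -> float:
    """Spines per µm: total spine count divided by dendrite length."""
    if dendrite_length <= 0:
        raise GeometryError("spine_density: dendrite length must be > 0")
    return n_spines / dendrite_length


# ---------------------------------------------------------------------------
# neck length
# ---------------------------------------------------------------------------

def _point_to_polyline_distance(point: np.ndarray, polyline: np.ndarray) -> float:
    """Min distance from a 3D point to a 3D polyline (exact per segment)."""
    p = np.asarray(point, dtype=float)
    a = polyline[:-1]
    b = polyline[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(proj - p, axis=1)))


def neck_length_from_trace(
    neck_contours: Sequence[Contour], section_thickness: float
) -> float:
    """Neck length from explicit open neck polyline traces.

    The per-section open traces are chained in section order into one 3D
    polyline (each point placed at its section's z).
    """
    open_traces = sorted(
        (c for c in neck_contours if not c.closed), key=lambda c: c.section
    )
    if not open_traces:
        raise GeometryError("neck_length_from_trace: no open neck traces")
    pts = np.vstack(
        [
            np.column_stack(
                [c.points, np.full(len(c.points), c.section * section_thickness)]
            )
            for c in open_traces
        ]
    )
    if len(pts) < 2:
        raise GeometryError("neck polyline needs >= 2 points")
    return path_length(pts)


def neck_length_from_anchors(
    head_center: np.ndarray,
    head_radius: float,
    shaft_axis: np.ndarray,
    shaft_radius: float,
) -> float:
    """Surrogate neck length when no explicit neck polyline exists.

    Distance from the spine head centre to the nearest point of the shaft
    axis, minus the head radius and the local shaft radius — i.e. the free
    gap between head base and shaft surface.  Clamped at 0 for sessile
    (stubby-like) spines whose head sits on the shaft.
    """
    d = _point_to_polyline_distance(head_center, shaft_axis)
    return max(0.0, d - head_radius - shaft_radius)


# ---------------------------------------------------------------------------
# whole-series measurement
# ---------------------------------------------------------------------------

@dataclass
class SeriesMeasurement:
    """Everything measured from one series file."""

    dendrites: list[DendriteRecord] = field(default_factory=list)
    spines: list[SpineRecord] = field(default_factory=list)


def measure_series(
    metadata: SeriesMetadata,
    contours: Sequence[Contour],
    hierarchy: ObjectHierarchy,
    config: Optional[MorphometryConfig] = None,
) -> SeriesMeasurement:
    """Run the full morphometry over one loaded series.

    For every dendrite: path length through shaft-contour centroids and spine
    density.  For every spine head: volume, surface area, neck length (from
    an explicit open neck trace when present, otherwise the head/shaft anchor
    surrogate), PSD area, perforation flag and size class.

    Spines reaching the first or last section are flagged
    ``touches_boundary``; the flag records the fact, record filtering is the
    caller's (or the boundary policy's) concern.
    """
    from .classify import classify_size, detect_perforation

    config = config or MorphometryConfig()
    t = metadata.section_thickness_um
    by_object: dict[str, list[Contour]] = {}
    for c in contours:
        by_object.setdefault(c.object_id, []).append(c)

    out = SeriesMeasurement()
    for did in hierarchy.by_kind("shaft"):
        shaft_contours = by_object.get(did, [])
        length, axis = dendrite_path_length(shaft_contours, t)
        shaft_areas = [contour_area(c) for c in shaft_contours if c.closed]
        shaft_radius = float(np.median(np.sqrt(np.asarray(shaft_areas) / np.pi)))

        spine_ids: list[str] = []
        for sid in hierarchy.children(did, "spine_head"):
            head = by_object.get(sid, [])
            head_closed = [c for c in head if c.closed]
            if not head_closed:
                logger.warning("spine %r has no head contours; skipped", sid)
                continue
            volume = object_volume(head_closed, t)
            surface = object_surface_area(head_closed, t, config.include_end_caps)
            areas = np.array([contour_area(c) for c in head_closed])
            cents = np.array([contour_centroid(c) for c in head_closed])
            zs = np.array([c.section * t for c in head_closed])
            w = areas / areas.sum()
            head_center = np.array(
                [(cents[:, 0] * w).sum(), (cents[:, 1] * w).sum(), (zs * w).sum()]
            )
            head_radius = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
            touches = any(
                c.section in (0, metadata.n_sections - 1) for c in head_closed
            )

            neck_ids = hierarchy.children(sid, "spine_neck")
            neck_len: Optional[float]
            open_neck = [
                c for nid in neck_ids for c in by_object.get(nid, []) if not c.closed
            ]
            if open_neck:
                neck_len = neck_length_from_trace(open_neck, t)
            else:
                neck_len = neck_length_from_anchors(
                    head_center, head_radius, axis, shaft_radius
                )

            psd_traces = [
                c
                for pid in hierarchy.children(sid, "psd")
                for c in by_object.get(pid, [])
            ]
            if psd_traces:
                area_psd = psd_area(psd_traces, t)
                perforated = detect_perforation(psd_traces)
            else:
                area_psd = 0.0
                perforated = False

            out.spines.append(
                SpineRecord(
                    spine_id=sid,
                    dendrite_id=did,
                    head_volume=volume,
                    head_surface_area=surface,
                    neck_length=neck_len,
                    psd_area=area_psd,
                    perforated=perforated,
                    size_class=classify_size(volume, config.size_cutoff),
                    touches_boundary=touches,
                )
            )
            spine_ids.append(sid)
        out.dendrites.append(
            DendriteRecord(dendrite_id=did, path_length=length, spine_ids=spine_ids)
        )
    return out
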