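"""Serial-section trace data model and I/O.

A *series* is a stack of planar contours traced on consecutive serial
sections (FIB/SEM milling planes).  Each traced object — dendritic shaft,
spine head, spine neck, or PSD — contributes one or more contours, and the
objects form a hierarchy (spine heads belong to a dendrite, necks and PSDs
belong to a spine head).

The native on-disk format is a small JSON schema:

.. code-block:: json

    {
      "metadata": {"pixel_size_nm": 4.5, "section_thickness_nm": 50.0,
                   "n_sections": 200, "source_id": "synthetic-wt-1mo-d0"},
      "objects":  [{"id": "d0", "kind": "shaft", "parent_id": null}, ...],
      "contours": [{"section": 12, "object_id": "d0", "closed": true,
                    "points": [[x_px, y_px], ...]}, ...]
    }

Coordinates are stored in pixels and converted to micrometres on load using
``pixel_size_nm``; the z position of section ``k`` is ``k *
section_thickness_nm`` (section 0 at z = 0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OBJECT_KINDS = ("shaft", "spine_head", "spine_neck", "psd")

#: parent kind required for each child kind (None = root object)
_PARENT_KIND = {
    "shaft": None,
    "spine_head": "shaft",
    "spine_neck": "spine_head",
    "psd": "spine_head",
}


class ValidationError(ValueError):
    """A series file or in-memory series violates a structural invariant."""


@dataclass(frozen=True)
class SeriesMetadata:
    """Physical calibration of a serial-section series."""

    pixel_size_nm: float
    section_thickness_nm: float
    n_sections: int
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValidationError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if self.section_thickness_nm <= 0:
            raise ValidationError(
                f"section_thickness_nm must be > 0, got {self.section_thickness_nm}"
            )
        if self.n_sections < 1:
            raise ValidationError(f"n_sections must be >= 1, got {self.n_sections}")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def section_thickness_um(self) -> float:
        return self.section_thickness_nm / 1000.0


@dataclass
class Contour:
    """One planar trace on one section, coordinates in micrometres.

    Closed contours outline a solid cross-section (shaft, spine head, neck);
    open traces are polylines (PSD segments).
    """

    section: int
    object_id: str
    points: np.ndarray  # (n, 2) float, µm
    closed: bool

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError(
                f"contour points must be (n, 2), got shape {self.points.shape}"
            )
        if self.section < 0:
            raise ValidationError(f"negative section index {self.section}")
        n_min = 3 if self.closed else 2
        if len(self.points) < n_min:
            raise ValidationError(
                f"{'closed' if self.closed else 'open'} contour of object "
                f"{self.object_id!r} needs >= {n_min} points, got {len(self.points)}"
            )


@dataclass
class ObjectHierarchy:
    """Object kinds and the spine→dendrite / psd→spine / neck→spine parent map."""

    kinds: dict[str, str] = field(default_factory=dict)
    parents: dict[str, Optional[str]] = field(default_factory=dict)

    def add(self, object_id: str, kind: str, parent_id: Optional[str] = None) -> None:
        if kind not in OBJECT_KINDS:
            raise ValidationError(f"unknown object kind {kind!r} for id {object_id!r}")
        if object_id in self.kinds:
            raise ValidationError(f"duplicate object id {object_id!r}")
        self.kinds[object_id] = kind
        self.parents[object_id] = parent_id

    def children(self, object_id: str, kind: Optional[str] = None) -> list[str]:
        return [
            oid
            for oid, pid in self.parents.items()
            if pid == object_id and (kind is None or self.kinds[oid] == kind)
        ]

    def by_kind(self, kind: str) -> list[str]:
        return [oid for oid, k in self.kinds.items() if k == kind]

    def validate(self) -> None:
        """Check referential integrity, parent-kind rules and acyclicity."""
        for oid, pid in self.parents.items():
            kind = self.kinds[oid]
            want = _PARENT_KIND[kind]
            if want is None:
                if pid is not None:
                    raise ValidationError(
                        f"{kind} object {oid!r} must not have a parent (got {pid!r})"
                    )
                continue
            if pid is None:
                raise ValidationError(f"{kind} object {oid!r} has no parent")
            if pid not in self.kinds:
                raise ValidationError(
                    f"{kind} object {oid!r} references missing parent id {pid!r}"
                )
            if self.kinds[pid] != want:
                raise ValidationError(
                    f"{kind} object {oid!r} has parent {pid!r} of kind "
                    f"{self.kinds[pid]!r}, expected {want!r}"
                )
        # at most one neck trace per spine
        for sid in self.by_kind("spine_head"):
            necks = self.children(sid, "spine_neck")
            if len(necks) > 1:
                raise ValidationError(f"spine {sid!r} has {len(necks)} neck objects")
        # parent chains are finite (kind rules already forbid cycles, but a
        # hand-built hierarchy may bypass add()); walk each chain defensively
        for oid in self.parents:
            seen = {oid}
            cur = self.parents.get(oid)
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"cycle in hierarchy at object {oid!r}")
                seen.add(cur)
                cur = self.parents.get(cur)


@dataclass
class SpineRecord:
    """Derived per-spine metrics (volumes in µm³, areas in µm², lengths in µm)."""

    spine_id: str
    dendrite_id: str
    head_volume: float
    head_surface_area: float
    neck_length: Optional[float]  # None = no neck trace and no usable anchors
    psd_area: float
    perforated: bool
    size_class: str  # "small" | "large"
    touches_boundary: bool

    def __post_init__(self) -> None:
        if self.head_volume <= 0:
            raise ValidationError(
                f"spine {self.spine_id!r}: head_volume must be > 0, got {self.head_volume}"
            )
        if self.psd_area < 0:
            raise ValidationError(f"spine {self.spine_id!r}: psd_area must be >= 0")
        if self.neck_length is not None and self.neck_length < 0:
            raise ValidationError(f"spine {self.spine_id!r}: neck_length must be >= 0")
        if self.size_class not in ("small", "large"):
            raise ValidationError(f"spine {self.spine_id!r}: bad size_class {self.size_class!r}")


@dataclass
class DendriteRecord:
    """Per-dendrite path length, spine membership and spine density."""

    dendrite_id: str
    path_length: float  # µm
    spine_ids: list[str]

    def __post_init__(self) -> None:
        if self.path_length <= 0:
            raise ValidationError(
                f"dendrite {self.dendrite_id!r}: path_length must be > 0"
            )

    @property
    def n_spines(self) -> int:
        return len(self.spine_ids)

    @property
    def spine_density(self) -> float:
        """Spines per µm of dendrite length."""
        return self.n_spines / self.path_length


def _check_simple(contour: Contour) -> None:
    """Closed contours must be simple polygons (shapely validity check)."""
    if not contour.closed:
        return
    from shapely.geometry import Polygon

    if not Polygon(contour.points).is_valid:
        raise ValidationError(
            f"closed contour of object {contour.object_id!r} on section "
            f"{contour.section} is self-intersecting or degenerate"
        )


def load_series(
    path: str | Path, check_simple: bool = False
) -> tuple[SeriesMetadata, list[Contour], ObjectHierarchy]:
    """Read a JSON series file and convert coordinates to micrometres.

    Parameters
    ----------
    path
        Series file path.
    check_simple
        Also verify that every closed contour is a simple polygon (slower;
        geometry routines re-check on use).

    Raises
    ------
    ValidationError
        Orphan ids, bad calibration, out-of-range section indices.
    json.JSONDecodeError
        Malformed JSON.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    try:
        md = doc["metadata"]
        metadata = SeriesMetadata(
            pixel_size_nm=float(md["pixel_size_nm"]),
            section_thickness_nm=float(md["section_thickness_nm"]),
            n_sections=int(md["n_sections"]),
            source_id=str(md.get("source_id", "")),
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: missing metadata key {exc}") from exc

    hierarchy = ObjectHierarchy()
    for obj in doc.get("objects", []):
        hierarchy.add(str(obj["id"]), str(obj["kind"]), obj.get("parent_id"))
    hierarchy.validate()

    scale = metadata.pixel_size_um
    contours: list[Contour] = []
    for c in doc.get("contours", []):
        oid = str(c["object_id"])
        if oid not in hierarchy.kinds:
            raise ValidationError(f"{path}: contour references unknown object id {oid!r}")
        section = int(c["section"])
        if section >= metadata.n_sections:
            raise ValidationError(
                f"{path}: contour of {oid!r} on section {section} >= "
                f"n_sections {metadata.n_sections}"
            )
        contour = Contour(
            section=section,
            object_id=oid,
            points=np.asarray(c["points"], dtype=float) * scale,
            closed=bool(c["closed"]),
        )
        if check_simple:
            _check_simple(contour)
        contours.append(contour)
    return metadata, contours, hierarchy


def write_series(
    metadata: SeriesMetadata,
    contours: Iterable[Contour],
    hierarchy: ObjectHierarchy,
    path: str | Path,
) -> None:
    """Write a series to the JSON format (coordinates stored in pixels).

    Validates the hierarchy before writing; refuses to serialize an
    inconsistent series.
    """
    hierarchy.validate()
    scale = metadata.pixel_size_um
    doc = {
        "metadata": {
            "pixel_size_nm": metadata.pixel_size_nm,
            "section_thickness_nm": metadata.section_thickness_nm,
            "n_sections": metadata.n_sections,
            "source_id": metadata.source_id,
        },
        "objects": [
            {"id": oid, "kind": hierarchy.kinds[oid], "parent_id": hierarchy.parents[oid]}
            for oid in hierarchy.kinds
        ],
        "contours": [],
    }
    for c in contours:
        if c.object_id not in hierarchy.kinds:
            raise ValidationError(f"contour references unknown object id {c.object_id!r}")
        if c.section >= metadata.n_sections:
            raise ValidationError(
                f"contour of {c.object_id!r} on section {c.section} >= "
                f"n_sections {metadata.n_sections}"
            )
        doc["contours"].append(
            {
                "section": c.section,
                "object_id": c.object_id,
                "closed": c.closed,
                "points": (c.points / scale).tolist(),
            }
        )
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def spine_table(spines: Sequence[SpineRecord]) -> pd.DataFrame:
    rows = [
        {
            "spine_id": s.spine_id,
            "dendrite_id": s.dendrite_id,
            "head_volume_um3": s.head_volume,
            "surface_area_um2": s.head_surface_area,
            "neck_length_um": s.neck_length if s.neck_length is not None else np.nan,
            "psd_area_um2": s.psd_area,
            "perforated": s.perforated,
            "size_class": s.size_class,
            "touches_boundary": s.touches_boundary,
        }
        for s in spines
    ]
    columns = [
        "spine_id", "dendrite_id", "head_volume_um3", "surface_area_um2",
        "neck_length_um", "psd_area_um2", "perforated", "size_class",
        "touches_boundary",
    ]
    return pd.DataFrame(rows, columns=columns)


def dendrite_table(dendrites: Sequence[DendriteRecord]) -> pd.DataFrame:
    rows = [
        {
            "dendrite_id": d.dendrite_id,
            "path_length_um": d.path_length,
            "n_spines": d.n_spines,
            "spine_density_per_um": d.spine_density,
        }
        for d in dendrites
    ]
    columns = ["dendrite_id", "path_length_um", "n_spines", "spine_density_per_um"]
    return pd.DataFrame(rows, columns=columns)


def export_spine_table(
    spines: Sequence[SpineRecord],
    dendrites: Sequence[DendriteRecord],
    spines_path: str | Path,
    dendrites_path: str | Path,
) -> None:
    """Write spines.csv / dendrites.csv with >= 6 significant digits."""
    if not spines:
        logger.warning("exporting an empty spine table to %s", spines_path)
    spine_table(spines).to_csv(spines_path, index=False, float_format="%.8g")
    dendrite_table(dendrites).to_csv(dendrites_path, index=False, float_format="%.8g")
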