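"""Shared fixtures: hand-built contours and generated synthetic datasets."""

from __future__ import annotations

import math

import numpy as np
import pytest

from spinemorph.trace_io import Contour, ObjectHierarchy, SeriesMetadata


def make_contour(points, section=0, object_id="obj", closed=True) -> Contour:
    return Contour(
        section=section, object_id=object_id,
        points=np.asarray(points, dtype=float), closed=closed,
    )


def square_contour(side=1.0, offset=(0.0, 0.0), section=0, object_id="obj") -> Contour:
    ox, oy = offset
    pts = [(ox, oy), (ox + side, oy), (ox + side, oy + side), (ox, oy + side)]
    return make_contour(pts, section=section, object_id=object_id)


def sphere_circle_contours(
    radius: float,
    thickness: float,
    center=(0.0, 0.0, 0.0),
    object_id: str = "sph",
    n_vertices: int = 720,
    section_offset: int = 0,
) -> list[Contour]:
    """Analytic circular cross-sections of a sphere on a section grid.

    Sections sit at z = k * thickness; only sections cutting the sphere get
    a contour.  Vertices are dense enough that polygon area error is
    negligible next to the slab-sum discretization itself.
    """
    cx, cy, cz = center
    contours = []
    k_lo = math.floor((cz - radius) / thickness)
    k_hi = math.ceil((cz + radius) / thickness)
    if k_lo + section_offset < 0:
        section_offset = -k_lo  # keep section indices nonnegative
    ang = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    for k in range(k_lo, k_hi + 1):
        dz = k * thickness - cz
        if abs(dz) >= radius:
            continue
        rho = math.sqrt(radius**2 - dz**2)
        # radius correction so the polygon area equals the disc area
        r_eff = rho * math.sqrt(
            2.0 * math.pi / (n_vertices * math.sin(2.0 * math.pi / n_vertices))
        )
        pts = np.column_stack([cx + r_eff * np.cos(ang), cy + r_eff * np.sin(ang)])
        contours.append(
            Contour(
                section=k + section_offset, object_id=object_id,
                points=pts, closed=True,
            )
        )
    return contours


def minimal_series() -> tuple[SeriesMetadata, list[Contour], ObjectHierarchy]:
    """One section, one shaft contour — the smallest valid series."""
    metadata = SeriesMetadata(
        pixel_size_nm=4.5, section_thickness_nm=50.0, n_sections=1,
        source_id="minimal",
    )
    hierarchy = ObjectHierarchy()
    hierarchy.add("d0", "shaft", None)
    contours = [square_contour(side=0.5, object_id="d0")]
    return metadata, contours, hierarchy


@pytest.fixture(scope="session")
def tiny_group():
    """One small generated group with its truth, series and manifest."""
    from spinemorph.presets import tiny_preset
    from spinemorph.synthetic import generate_group

    cfg = tiny_preset(n_dendrites=3, dendrite_length_mean=7.0)[0]
    truth, series, manifest = generate_group(cfg, seed=7)
    return cfg, truth, series, manifest


@pytest.fixture(scope="session")
def paper_run(tmp_path_factory):
    """Full study-scale pipeline run (8 groups, 65 dendrites) at seed 1."""
    import pandas as pd

    from spinemorph.pipeline import RunConfig, run_full_analysis

    out = tmp_path_factory.mktemp("paper_run")
    report = run_full_analysis(RunConfig(preset="paper_scale", out_dir=out, seed=1))
    spines = pd.read_csv(out / "spines.csv")
    dendrites = pd.read_csv(out / "dendrites.csv")
    truth_spines = pd.read_csv(out / "traces" / "truth_spines.csv")
    truth_dendrites = pd.read_csv(out / "traces" / "truth_dendrites.csv")
    return {
        "out": out,
        "report": report,
        "spines": spines,
        "dendrites": dendrites,
        "truth_spines": truth_spines,
        "truth_dendrites": truth_dendrites,
    }
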