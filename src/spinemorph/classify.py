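"""Categorical spine analyses: size classes, perforated PSDs, histograms.

Spines are split into *small* (thin-type) and *large* (mushroom-type) by a
head-volume cutoff, 0.04 µm³ by default.  A volume exactly at the cutoff
counts as small; the boundary is genuinely ambiguous in the source
convention, so the tie rule is fixed here for determinism.

A PSD is *perforated* (as opposed to macular) when its traced outline shows
a discontinuity: either a section holds two or more disjoint PSD traces for
the same synapse, or the traces form a ring around an untraced region (the
doughnut-shaped PSD).  Detection is purely trace-topological.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import LineString

from .trace_io import Contour

logger = logging.getLogger(__name__)


def _round_half_up(x: float, decimals: int) -> float:
    f = 10.0 ** decimals
    return math.floor(x * f + 0.5) / f


def classify_size(head_volume: float, cutoff: float = 0.04) -> str:
    """Classify a spine as ``small`` or ``large`` by head volume (µm³).

    ``head_volume <= cutoff`` is small (tie at the cutoff goes to small).
    """
    if head_volume <= 0:
        raise ValueError(f"head_volume must be > 0, got {head_volume}")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    return "small" if head_volume <= cutoff else "large"


def _as_linestring(trace: Contour) -> LineString:
    pts = trace.points
    if trace.closed:
        pts = np.vstack([pts, pts[:1]])
    return LineString(pts)


def detect_perforation(
    traces: Sequence[Contour],
    disjoint_tol: float = 1e-6,
    adjacency_tol: float = 0.15,
) -> bool:
    """Decide whether one synapse's PSD traces describe a perforated PSD.

    True iff (a) some section carries >= 2 mutually disjoint traces of this
    PSD — the discontinuity seen in single sections — or (b) the
    section-adjacency graph of the traces contains a cycle, i.e. the traces
    wrap around an untraced hole (doughnut-shaped PSD).

    Parameters
    ----------
    traces
        All traces of one PSD object (any mix of sections).
    disjoint_tol
        Two traces in one section closer than this (µm) are treated as one
        continuous stretch.
    adjacency_tol
        Traces on consecutive sections within this in-plane distance (µm)
        are considered connected when building the adjacency graph.
    """
    if not traces:
        logger.warning("detect_perforation called with no PSD traces")
        return False

    by_section: dict[int, list[LineString]] = {}
    for t in traces:
        by_section.setdefault(t.section, []).append(_as_linestring(t))

    # branch (a): within-section discontinuity
    for lines in by_section.values():
        n = len(lines)
        if n < 2:
            continue
        for i in range(n):
            for j in range(i + 1, n):
                if lines[i].distance(lines[j]) > disjoint_tol:
                    return True

    # branch (b): ring of traces across sections enclosing an untraced region.
    # Nodes are traces; edges join spatially close traces on consecutive
    # sections; any cycle in this graph means the PSD wraps around a hole.
    nodes: list[tuple[int, LineString]] = [
        (sec, ln) for sec, lines in sorted(by_section.items()) for ln in lines
    ]
    n_nodes = len(nodes)
    parent = list(range(n_nodes))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n_nodes):
        sec_i, ln_i = nodes[i]
        for j in range(i + 1, n_nodes):
            sec_j, ln_j = nodes[j]
            if abs(sec_i - sec_j) != 1:
                continue
            if ln_i.distance(ln_j) <= adjacency_tol:
                ri, rj = find(i), find(j)
                if ri == rj:
                    return True  # closing edge of a cycle
                parent[ri] = rj
    return False


def relative_frequency(count: int, total: int) -> float:
    """Percentage 100*count/total, rounded half-up to one decimal place."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    return _round_half_up(100.0 * count / total, 1)


def fold_change(pct_a: float, pct_b: float) -> float:
    """Ratio pct_a / pct_b, rounded half-up to two decimal places."""
    if pct_b <= 0:
        raise ValueError("denominator percentage must be > 0")
    return _round_half_up(pct_a / pct_b, 2)


@dataclass(frozen=True)
class FrequencyTable:
    """Per-group small/large and perforation counts with derived percentages."""

    genotype: str
    age_months: float
    n_total: int
    n_small: int
    n_large: int
    n_perforated: int

    def __post_init__(self) -> None:
        if self.n_small + self.n_large != self.n_total:
            raise ValueError(
                f"n_small + n_large = {self.n_small + self.n_large} != "
                f"n_total = {self.n_total}"
            )
        if not 0 <= self.n_perforated <= self.n_total:
            raise ValueError("n_perforated outside [0, n_total]")

    @property
    def pct_small(self) -> float:
        return relative_frequency(self.n_small, self.n_total)

    @property
    def pct_large(self) -> float:
        return relative_frequency(self.n_large, self.n_total)

    @property
    def pct_perforated(self) -> float:
        return relative_frequency(self.n_perforated, self.n_total)


def frequency_table(
    genotype: str,
    age_months: float,
    head_volumes: Sequence[float],
    perforated: Sequence[bool],
    cutoff: float = 0.04,
) -> FrequencyTable:
    """Build the per-group frequency table from per-spine measurements."""
    if len(head_volumes) != len(perforated):
        raise ValueError("head_volumes and perforated must be the same length")
    classes = [classify_size(v, cutoff) for v in head_volumes]
    return FrequencyTable(
        genotype=genotype,
        age_months=age_months,
        n_total=len(classes),
        n_small=sum(c == "small" for c in classes),
        n_large=sum(c == "large" for c in classes),
        n_perforated=int(sum(bool(p) for p in perforated)),
    )


@dataclass(frozen=True)
class VolumeHistogram:
    """Left-closed, right-open head-volume histogram with relative frequencies."""

    bin_width: float
    edges: np.ndarray       # len(bins) + 1, edges[k] = k * bin_width offsets
    counts: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.frequencies.sum(), 1.0, atol=1e-12):
            raise ValueError("relative frequencies must sum to 1")


def bin_volumes(volumes: Sequence[float], bin_width: float = 0.04) -> VolumeHistogram:
    """Bin head volumes into [k*w, (k+1)*w) bins and normalize to frequencies."""
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise ValueError("bin_volumes: empty volume list")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    idx = np.floor(v / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    return VolumeHistogram(
        bin_width=bin_width,
        edges=edges,
        counts=counts,
        frequencies=counts / counts.sum(),
    )
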