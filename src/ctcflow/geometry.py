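"""Lagrangian geometry: the circular cell and the tethered vessel walls.

The cell is a 10 um disc (by default) whose mechanics live in two spring
networks: an annular actin-cortex band discretized as two concentric,
cross-linked rings, and the nuclear envelope as a single chord-braced ring.
The cytoplasm between them is plain viscous fluid — no springs cross the
gap.  The vessel wall is two straight rows of points, each tethered to a
fixed anchor and linked to its neighbors by stiff springs, forming a
uniform rigid wall.

All coordinates are in cm (CGS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .mechanics import SpringNetwork

__all__ = [
    "BoundaryPointSet",
    "CellGeometrySpec",
    "VesselGeometry",
    "build_cell",
    "build_vessel",
    "mark_cortex_arc",
]

UM = 1e-4  # one micron in cm


@dataclass
class BoundaryPointSet:
    """Ordered Lagrangian material points with structure tags.

    ``groups`` maps structure names (``cortex_outer``, ``cortex_inner``,
    ``nucleus``, ``wall_bottom``, ``wall_top``) to index arrays, each in
    contour order.  ``ds`` is the per-point boundary quadrature weight
    (initial arc spacing, cm), frozen at construction.
    """

    xy: np.ndarray  # (N, 2) cm
    tag: np.ndarray  # (N,) unicode, one of cortex/nucleus/wall_top/wall_bottom
    marker: np.ndarray  # (N,) bool, member of the stained arc
    ds: np.ndarray  # (N,) cm
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.marker = np.asarray(self.marker, dtype=bool)
        self.ds = np.asarray(self.ds, dtype=float)

    def __len__(self) -> int:
        return len(self.xy)

    def copy(self) -> "BoundaryPointSet":
        return BoundaryPointSet(
            self.xy.copy(), self.tag.copy(), self.marker.copy(), self.ds.copy(),
            {k: v.copy() for k, v in self.groups.items()},
        )

    @staticmethod
    def concat(a: "BoundaryPointSet", b: "BoundaryPointSet") -> tuple["BoundaryPointSet", int]:
        """Concatenate two point sets; returns the merged set and the index
        offset applied to ``b`` (for shifting spring endpoint ids)."""
        off = len(a)
        groups = {k: v.copy() for k, v in a.groups.items()}
        for k, v in b.groups.items():
            if k in groups:
                raise ConfigurationError(f"duplicate point group {k!r}")
            groups[k] = v + off
        return (
            BoundaryPointSet(
                np.vstack([a.xy, b.xy]),
                np.concatenate([a.tag, b.tag]),
                np.concatenate([a.marker, b.marker]),
                np.concatenate([a.ds, b.ds]),
                groups,
            ),
            off,
        )


@dataclass
class CellGeometrySpec:
    """Initial cell layout: a disc with an annular cortex band and a nucleus."""

    center: tuple[float, float]
    diameter: float = 10 * UM
    nucleus_diameter: float = 4 * UM
    cortex_band_width: float = 2 * UM
    point_spacing: float = 0.15 * UM

    def validate(self) -> None:
        if self.cortex_band_width >= self.diameter / 2:
            raise ConfigurationError("cortex band width must be < cell radius")
        inner_radius = self.diameter / 2 - self.cortex_band_width
        if self.nucleus_diameter / 2 >= inner_radius:
            raise ConfigurationError(
                "nucleus overlaps the cortex band: nucleus radius "
                f"{self.nucleus_diameter / 2:g} >= inner cortex radius {inner_radius:g}"
            )
        if self.point_spacing <= 0:
            raise ConfigurationError("point spacing must be > 0")


@dataclass
class VesselGeometry:
    """Straight channel: two wall rows ``width`` apart, tethered to anchors."""

    length: float = 75 * UM
    width: float = 30 * UM
    point_spacing: float = 0.15 * UM
    y_bottom: float = 0.0  # y of the bottom wall row, cm
    domain_height: float | None = None  # periodic box height, if known

    def validate(self) -> None:
        if self.length <= 0 or self.width <= 0 or self.point_spacing <= 0:
            raise ConfigurationError("vessel dimensions must be > 0")
        if self.domain_height is not None and self.width >= self.domain_height:
            raise ConfigurationError(
                f"vessel width {self.width:g} must be < domain height {self.domain_height:g}"
            )


def _ring(center, radius, spacing):
    """Closed ring of points; returns (xy, n, arc spacing actually used)."""
    n = int(round(2 * math.pi * radius / spacing))
    if n < 3:
        raise ConfigurationError(
            f"point spacing {spacing:g} too coarse for ring radius {radius:g} "
            f"(only {n} points; need >= 3)"
        )
    theta = 2 * math.pi * np.arange(n) / n
    xy = np.column_stack([center[0] + radius * np.cos(theta),
                          center[1] + radius * np.sin(theta)])
    return xy, n, 2 * math.pi * radius / n


def _ring_springs(idx, closed=True):
    """Consecutive-neighbor pairs along a contour given by index array."""
    i = idx
    j = np.roll(idx, -1)
    if not closed:
        i, j = i[:-1], j[:-1]
    return i, j


def _rest_lengths(xy, i, j):
    d = xy[j] - xy[i]
    return np.hypot(d[:, 0], d[:, 1])


def build_cell(spec: CellGeometrySpec, stiffness: float = 50.0,
               nucleus_stiffness: float | None = None,
               nucleus_brace_step: int = 5):
    """Build the cell's point set and its cortex and nucleus networks.

    The cortex band is two concentric rings at the outer cell radius and at
    ``outer - band width``, each with circumferential springs, cross-linked
    by radial rungs (inner point to nearest outer point) and one diagonal
    per rung.  The nuclear envelope is a single ring with circumferential
    springs plus chordal braces every ``nucleus_brace_step`` points.  All
    rest lengths equal initial inter-point distances, so the cell starts
    stress-free.

    Returns ``(points, cortex_network, nucleus_network)``; network ids index
    the returned point set.
    """
    spec.validate()
    if nucleus_stiffness is None:
        nucleus_stiffness = stiffness
    r_out = spec.diameter / 2
    r_in = r_out - spec.cortex_band_width
    r_nuc = spec.nucleus_diameter / 2
    c = spec.center

    xy_out, n_out, ds_out = _ring(c, r_out, spec.point_spacing)
    xy_in, n_in, ds_in = _ring(c, r_in, spec.point_spacing)
    xy_nuc, n_nuc, ds_nuc = _ring(c, r_nuc, spec.point_spacing)

    xy = np.vstack([xy_out, xy_in, xy_nuc])
    idx_out = np.arange(n_out)
    idx_in = n_out + np.arange(n_in)
    idx_nuc = n_out + n_in + np.arange(n_nuc)
    tag = np.array(["cortex"] * (n_out + n_in) + ["nucleus"] * n_nuc)
    ds = np.concatenate([np.full(n_out, ds_out), np.full(n_in, ds_in),
                         np.full(n_nuc, ds_nuc)])
    points = BoundaryPointSet(
        xy, tag, np.zeros(len(xy), dtype=bool), ds,
        {"cortex_outer": idx_out, "cortex_inner": idx_in, "nucleus": idx_nuc},
    )

    # cortex: two circumferential rings + radial rungs + diagonals
    si, sj = [], []
    for ring_idx in (idx_out, idx_in):
        a, b = _ring_springs(ring_idx)
        si.append(a)
        sj.append(b)
    # rung: each inner point to its nearest outer point (by angle); diagonal
    # to the next outer point, triangulating the band
    nearest = np.round(np.arange(n_in) * n_out / n_in).astype(int) % n_out
    si.append(idx_in)
    sj.append(idx_out[nearest])
    si.append(idx_in)
    sj.append(idx_out[(nearest + 1) % n_out])
    ci = np.concatenate(si)
    cj = np.concatenate(sj)
    cortex = SpringNetwork(
        ci, cj, np.full(len(ci), float(stiffness)), _rest_lengths(xy, ci, cj),
        kind="elastic",
    )

    # nucleus: ring + chordal braces every k-th point
    a, b = _ring_springs(idx_nuc)
    k = max(2, min(nucleus_brace_step, n_nuc - 1))
    bi = idx_nuc
    bj = idx_nuc[(np.arange(n_nuc) + k) % n_nuc]
    ni = np.concatenate([a, bi])
    nj = np.concatenate([b, bj])
    nucleus = SpringNetwork(
        ni, nj, np.full(len(ni), float(nucleus_stiffness)),
        _rest_lengths(xy, ni, nj), kind="elastic",
    )
    return points, cortex, nucleus


def build_vessel(geom: VesselGeometry, stiffness: float = 2000.0):
    """Build the two tethered wall rows and their spring network.

    Each wall point carries a zero-rest-length tether to its fixed anchor
    (its initial position) and stiff links to its row neighbors.  Under
    zero load the wall is exactly stationary; under flow the tethers make
    it effectively rigid.

    Returns ``(points, tethers, links)``: the wall point set, the tether
    network (``anchors`` are the initial positions), and the elastic
    neighbor-link network.
    """
    geom.validate()
    n = int(round(geom.length / geom.point_spacing))
    if n < 2:
        raise ConfigurationError("vessel too short for the wall point spacing")
    dx = geom.length / n
    x = dx * np.arange(n)
    y0, y1 = geom.y_bottom, geom.y_bottom + geom.width
    xy = np.vstack([np.column_stack([x, np.full(n, y0)]),
                    np.column_stack([x, np.full(n, y1)])])
    idx_bot = np.arange(n)
    idx_top = n + np.arange(n)
    tag = np.array(["wall_bottom"] * n + ["wall_top"] * n)
    points = BoundaryPointSet(
        xy, tag, np.zeros(2 * n, dtype=bool), np.full(2 * n, dx),
        {"wall_bottom": idx_bot, "wall_top": idx_top},
    )
    tethers = SpringNetwork(
        np.arange(2 * n), np.arange(2 * n),
        np.full(2 * n, float(stiffness)), np.zeros(2 * n),
        kind="tether", anchors=xy.copy(),
    )
    # neighbor links along each row; the periodic seam link is omitted
    # (raw coordinates are not wrapped), rigidity comes from the tethers
    li = np.concatenate([idx_bot[:-1], idx_top[:-1]])
    lj = np.concatenate([idx_bot[1:], idx_top[1:]])
    links = SpringNetwork(
        li, lj, np.full(len(li), float(stiffness)), _rest_lengths(xy, li, lj),
        kind="elastic",
    )
    return points, tethers, links


def mark_cortex_arc(points: BoundaryPointSet, span: float, start: float = 0.0,
                    center: tuple[float, float] | None = None) -> BoundaryPointSet:
    """Set the marker flag on outer-cortex points in a polar-angle window.

    The stained arc visualizes rolling: its translocation around the cell
    perimeter over time is the rotation readout.  ``span``/``start`` are in
    radians about the cell center; points with initial polar angle in
    ``[start, start + span)`` (mod 2*pi) are marked.  Marks are set in
    place and the point set returned.
    """
    if not 0.0 < span <= 2 * math.pi:
        raise ConfigurationError("arc span must lie in (0, 2*pi]")
    if "cortex_outer" not in points.groups:
        raise ConfigurationError("point set has no outer cortex ring")
    idx = points.groups["cortex_outer"]
    if center is None:
        center = points.xy[idx].mean(axis=0)
    rel = points.xy[idx] - np.asarray(center)
    theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]) - start, 2 * math.pi)
    sel = theta < span
    if span == 2 * math.pi:
        sel[:] = True
    if not sel.any():
        raise ConfigurationError("cortex arc selection is empty")
    points.marker[idx[sel]] = True
    return points
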