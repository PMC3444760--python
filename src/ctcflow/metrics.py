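"""Shape and motion descriptors and locomotion-mode classification.

The deformation readouts quantify the stiffness-sweep outcomes: area and
perimeter of the outer cortex contour, circularity
4*pi*A/P^2 (1 for a circle, smaller for elongated shapes), and the
principal-axis aspect ratio from the boundary's second moments.

Rolling is detected through the stained cortex arc: the cumulative,
unwrapped rotation of the marked points' mean polar angle about the
instantaneous centroid.  The mode classifier applies simple threshold
rules on adhesion occupancy, adhesion turnover, marker rotation, and
centroid speed to label a trajectory window as floating, rolling,
anchoring, or crawling — the successive stages of the adhesion cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing, Polygon

from .errors import MetricsError, StructuralError

__all__ = [
    "ShapeMetrics",
    "ModeThresholds",
    "ModeLabel",
    "shape_metrics",
    "marker_rotation",
    "classify_mode",
    "stiffness_signature",
]


@dataclass(frozen=True)
class ShapeMetrics:
    area: float  # cm^2
    perimeter: float  # cm
    circularity: float  # 4 pi A / P^2
    major_axis: float  # cm
    minor_axis: float  # cm
    aspect_ratio: float  # major / minor, >= 1
    centroid: tuple[float, float]  # cm

    @property
    def clasmatosis_flag(self) -> bool:
        """Extreme elongation diagnostic (cytoplasmic-fragmentation-like)."""
        return self.aspect_ratio > 4.0


def shape_metrics(boundary_xy: np.ndarray) -> ShapeMetrics:
    """Shape descriptors of a closed boundary contour (points in order).

    Area by the shoelace formula, perimeter as the closed segment sum, and
    axis lengths from the eigenvalues of the boundary point covariance
    (for points uniformly spaced on an ellipse with semi-axes a >= b the
    eigenvalues are a^2/2 and b^2/2, so axes = 2*sqrt(2*lambda)).

    Raises ``MetricsError`` on degenerate or self-intersecting contours —
    the latter typically flags a numerically blown-up cell shape.
    """
    xy = np.asarray(boundary_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[0] < 3 or xy.shape[1] != 2:
        raise MetricsError("need at least 3 ordered boundary points")
    ring = LinearRing(xy)
    if not ring.is_simple:
        raise MetricsError("self-intersecting boundary contour")
    poly = Polygon(xy)
    area = poly.area
    perim = ring.length
    if area <= 0 or perim <= 0:
        raise MetricsError("degenerate contour (zero area or perimeter)")
    circ = 4.0 * math.pi * area / perim**2
    centroid = xy.mean(axis=0)
    cov = np.cov((xy - centroid).T)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    evals = np.clip(evals, 0.0, None)
    major = 2.0 * math.sqrt(2.0 * evals[0])
    minor = 2.0 * math.sqrt(2.0 * evals[1])
    return ShapeMetrics(
        area=float(area), perimeter=float(perim), circularity=float(circ),
        major_axis=float(major), minor_axis=float(minor),
        aspect_ratio=float(major / minor) if minor > 0 else float("inf"),
        centroid=(float(centroid[0]), float(centroid[1])),
    )


def _marker_angle(xy: np.ndarray, marked: np.ndarray, ring: np.ndarray) -> float:
    """Circular-mean polar angle of the marked arc about the ring centroid."""
    center = xy[ring].mean(axis=0)
    rel = xy[marked] - center
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    return float(np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang))))


def marker_rotation(trajectory, marked_ids: np.ndarray | None = None) -> float:
    """Cumulative unwrapped rotation (radians) of the stained cortex arc.

    Positive is counter-clockwise.  Rigid translation of the cell yields
    zero; rigid rotation by an angle yields that angle.
    """
    snaps = trajectory.snapshots
    if len(snaps) < 2:
        raise MetricsError("need at least 2 snapshots for rotation")
    pts = trajectory.points
    ring = pts.groups["cortex_outer"]
    if marked_ids is None:
        marked_ids = np.flatnonzero(pts.marker)
    marked_ids = np.asarray(marked_ids, dtype=np.intp)
    if len(marked_ids) == 0:
        raise StructuralError("no marked cortex points in trajectory")
    angles = np.array([_marker_angle(s.xy, marked_ids, ring) for s in snaps])
    steps = np.mod(np.diff(angles) + math.pi, 2.0 * math.pi) - math.pi
    return float(np.sum(steps))


@dataclass(frozen=True)
class ModeThresholds:
    """Decision constants for the locomotion-mode classifier.

    Defaults are calibration constants of this package (the underlying
    modes are defined only qualitatively).  The rotation threshold is set
    against the free-rotation bound of a particle in the local shear
    (omega = gamma/2, about 1.6 rad over a 4-unit window at the default
    flow): sustained adhesive translocation with at least 1 rad of stain
    rotation counts as rolling, provided the cell is still adhered in the
    tail of the window.  A cell moving at >= half the local undisturbed
    flow speed with (almost) no adhesions in the tail is floating; a cell
    pinned below 10% of the flow speed by long-lived links is anchoring.
    """

    rotation_min: float = 1.0  # rad over the window
    float_speed_fraction: float = 0.5
    float_free_fraction: float = 0.9  # tail time fraction with zero links
    anchor_speed_fraction: float = 0.1
    anchor_lifetime_fraction: float = 0.5  # mean lifetime / horizon
    turnover_min_per_unit: float = 2.0  # events per snapshot unit
    advance_min_fraction: float = 0.5  # net advance / cell diameter
    adhered_fraction_min: float = 0.6  # window time fraction with links
    tail_adhered_fraction: float = 0.75  # rolling must persist to the end
    crawl_adhered_fraction: float = 0.9
    tail_fraction: float = 0.25  # tail window length / full window


@dataclass(frozen=True)
class ModeLabel:
    mode: str  # floating | rolling | anchoring | crawling
    confident: bool
    evidence: dict


def _local_flow_speed(config, y: float) -> float:
    """Undisturbed parabolic profile speed at height y, cm/s."""
    y0 = config.wall_y_bottom
    H = config.vessel_width
    rel = (y - y0) / H
    return max(config.u_max * (1.0 - (2.0 * rel - 1.0) ** 2), 1e-12)


def classify_mode(trajectory, thresholds: ModeThresholds = ModeThresholds(),
                  snapshot_unit: float | None = None) -> ModeLabel:
    """Label a trajectory window with its adhesion-cascade locomotion mode.

    Pure function of (trajectory, thresholds): deterministic rules are
    evaluated in the order crawling, rolling, anchoring, floating; if none
    fires the label is floating with ``confident=False``.  The floating
    rule inspects the tail of the window, so an attach-then-detach
    trajectory (an anchoring prefix followed by free advection) is labeled
    floating.
    """
    from .config import SNAPSHOT_UNIT

    snaps = trajectory.snapshots
    if len(snaps) < 5:
        raise MetricsError("trajectory must cover at least 4 snapshot intervals")
    cfg = trajectory.config
    unit = snapshot_unit or SNAPSHOT_UNIT
    T = snaps[-1].time - snaps[0].time
    cent = trajectory.centroid()
    advance = cent[-1, 0] - cent[0, 0]
    speed = advance / T if T > 0 else 0.0
    u_local = _local_flow_speed(cfg, float(np.mean(cent[:, 1])))
    n_links = np.array([s.n_links for s in snaps])
    free_frac = float(np.mean(n_links == 0))
    adhered_frac = float(np.mean(n_links > 0))
    n_tail = max(2, int(round(thresholds.tail_fraction * len(snaps))))
    tail_links = n_links[-n_tail:]
    tail_free_frac = float(np.mean(tail_links == 0))
    tail_adhered_frac = float(np.mean(tail_links > 0))
    tail_T = snaps[-1].time - snaps[-n_tail].time
    tail_speed = ((cent[-1, 0] - cent[-n_tail, 0]) / tail_T) if tail_T > 0 else 0.0
    events = [e for e in trajectory.events
              if snaps[0].time <= e[0] <= snaps[-1].time]
    turnover = len(events) / (T / unit) if T > 0 else 0.0
    # mean achieved lifetime: broken links by log; surviving links by age
    lifetimes = []
    born = {}
    for t, kind, c, w, _ln in events:
        if kind == "create":
            born[(c, w)] = t
        elif kind == "break" and (c, w) in born:
            lifetimes.append(t - born.pop((c, w)))
    last = snaps[-1]
    for c, w, b in zip(*last.links):
        lifetimes.append(last.time - b)
    mean_life = float(np.mean(lifetimes)) if lifetimes else 0.0
    try:
        rotation = marker_rotation(trajectory)
    except (MetricsError, StructuralError):
        rotation = 0.0

    evidence = {
        "rotation_rad": rotation, "advance_cm": float(advance),
        "centroid_speed": float(speed), "local_flow_speed": u_local,
        "free_fraction": free_frac, "adhered_fraction": adhered_frac,
        "tail_free_fraction": tail_free_frac,
        "tail_adhered_fraction": tail_adhered_frac,
        "turnover_per_unit": float(turnover), "mean_link_lifetime_s": mean_life,
        "horizon_s": float(T),
    }
    th = thresholds
    advance_ok = advance >= th.advance_min_fraction * cfg.cell_diameter
    if (cfg.remodeling_enabled and adhered_frac >= th.crawl_adhered_fraction
            and turnover >= th.turnover_min_per_unit and advance_ok):
        return ModeLabel("crawling", True, evidence)
    if (adhered_frac >= th.adhered_fraction_min
            and tail_adhered_frac >= th.tail_adhered_fraction
            and turnover >= th.turnover_min_per_unit
            and abs(rotation) >= th.rotation_min and advance_ok):
        return ModeLabel("rolling", True, evidence)
    if (mean_life >= th.anchor_lifetime_fraction * T
            and adhered_frac >= th.crawl_adhered_fraction
            and abs(speed) < th.anchor_speed_fraction * u_local):
        return ModeLabel("anchoring", True, evidence)
    if (tail_free_frac >= th.float_free_fraction
            and tail_speed >= th.float_speed_fraction * u_local):
        return ModeLabel("floating", True, evidence)
    return ModeLabel("floating", False, evidence)


def stiffness_signature(labeled_runs) -> "pandas.DataFrame":
    """Per-mode effective-stiffness table (means over springs), dyn/cm.

    ``labeled_runs`` is an iterable of (label, trajectory) or records with
    ``label``/``trajectory`` entries.  Columns: cortex, near-adhesion
    cortex, nucleus, adhesion stiffness.  One row per mode present; the
    canonical cascade order is kept.
    """
    import pandas as pd

    rows = {}
    for item in labeled_runs:
        if isinstance(item, dict):
            label, traj = item["label"], item["trajectory"]
        else:
            label, traj = item
        mode = label.mode if isinstance(label, ModeLabel) else str(label)
        cfg = traj.config
        last = traj.snapshots[-1]
        S0 = cfg.baseline_stiffness
        mult = last.cortex_multiplier
        base = cfg.cortex_multiplier
        soft = mult[mult < base * (1.0 - 1e-12)]
        stiff = mult[mult >= base * (1.0 - 1e-12)]
        cortex_S = float(np.mean(stiff) * S0) if len(stiff) else base * S0
        near_S = float(np.mean(soft) * S0) if len(soft) else cortex_S
        any_links = any(s.n_links > 0 for s in traj.snapshots)
        rows[mode] = {
            "mode": mode,
            "cortex_stiffness": cortex_S,
            "near_adhesion_cortex_stiffness": near_S,
            "nucleus_stiffness": cfg.nucleus_multiplier * S0,
            "adhesion_stiffness": cfg.adhesion_stiffness if any_links else 0.0,
        }
    order = ["floating", "rolling", "anchoring", "crawling"]
    ordered = [rows[m] for m in order if m in rows]
    ordered += [v for k, v in rows.items() if k not in order]
    return pd.DataFrame(ordered).set_index("mode")
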