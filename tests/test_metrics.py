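"""Shape metrics, stain rotation, and locomotion-mode classification."""

import math

import numpy as np
import pytest
from scipy.special import ellipe

from ctcflow.config import SNAPSHOT_UNIT, SimulationConfig
from ctcflow.errors import MetricsError
from ctcflow.geometry import UM, BoundaryPointSet
from ctcflow.metrics import (
    ModeLabel,
    classify_mode,
    marker_rotation,
    shape_metrics,
    stiffness_signature,
)
from ctcflow.simulate import Snapshot, Trajectory


def ring(n=200, r=1.0, center=(0.0, 0.0)):
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])


class TestShapeMetrics:
    def test_circle_circularity_unity(self):
        m = shape_metrics(ring(200))
        assert m.circularity == pytest.approx(1.0, abs=1e-3)
        assert m.aspect_ratio == pytest.approx(1.0, abs=1e-6)
        assert m.area == pytest.approx(math.pi, rel=1e-3)

    def test_unit_square(self):
        pts = []
        corners = [(0, 0), (1, 0), (1, 1), (0, 1)]
        for a, b in zip(corners, corners[1:] + corners[:1]):
            for s in np.linspace(0, 1, 10, endpoint=False):
                pts.append((a[0] + s * (b[0] - a[0]), a[1] + s * (b[1] - a[1])))
        m = shape_metrics(np.array(pts))
        assert m.circularity == pytest.approx(math.pi / 4, rel=1e-6)

    def test_two_to_one_ellipse(self):
        a, b = 2.0, 1.0
        t = 2 * np.pi * np.arange(4000) / 4000
        xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
        m = shape_metrics(xy)
        perim = 4 * a * ellipe(1 - (b / a) ** 2)  # exact quadrature
        expected = 4 * math.pi * (math.pi * a * b) / perim**2
        assert m.circularity == pytest.approx(expected, rel=1e-3)
        assert m.aspect_ratio == pytest.approx(2.0, rel=1e-2)

    def test_rigid_motion_invariance(self, rng):
        xy = ring(150, r=5 * UM, center=(20 * UM, 15 * UM))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = xy @ R.T + np.array([3 * UM, -2 * UM])
        m0, m1 = shape_metrics(xy), shape_metrics(moved)
        assert m1.area == pytest.approx(m0.area, rel=1e-12)
        assert m1.perimeter == pytest.approx(m0.perimeter, rel=1e-12)
        assert m1.circularity == pytest.approx(m0.circularity, rel=1e-12)

    def test_area_preserving_stretch_lowers_circularity(self):
        xy = ring(300)
        for s in (1.2, 1.5, 2.0):
            stretched = xy * np.array([s, 1.0 / s])
            assert shape_metrics(stretched).circularity < shape_metrics(xy).circularity

    def test_self_intersection_rejected(self):
        bow = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
        with pytest.raises(MetricsError):
            shape_metrics(bow)

    def test_too_few_points_rejected(self):
        with pytest.raises(MetricsError):
            shape_metrics(np.array([[0, 0], [1, 1]]))


def fabricate(config, centers, angles, n_links_per_snap, events=(),
              soft_multipliers=None, n_ring=60, r=5 * UM):
    """Build a synthetic trajectory of a rigidly moving/rotating ring."""
    n_snap = len(centers)
    times = [k * SNAPSHOT_UNIT for k in range(n_snap)]
    base = ring(n_ring, r)
    marker_ids = np.arange(5)
    tag = np.array(["cortex"] * n_ring + ["wall_bottom"])
    marker = np.zeros(n_ring + 1, dtype=bool)
    marker[marker_ids] = True
    pts = BoundaryPointSet(
        np.vstack([base + centers[0], [[0.0, 0.0]]]), tag, marker,
        np.full(n_ring + 1, 1e-5),
        {"cortex_outer": np.arange(n_ring),
         "wall_bottom": np.array([n_ring])},
    )
    traj = Trajectory(config, pts, events=list(events))
    for k in range(n_snap):
        th = angles[k]
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy = np.vstack([base @ R.T + centers[k], [[0.0, 0.0]]])
        nl = n_links_per_snap[k]
        links = (np.zeros(nl, dtype=np.intp), np.full(nl, n_ring, dtype=np.intp),
                 np.zeros(nl))
        mult = soft_multipliers[k] if soft_multipliers else np.ones(n_ring)
        traj.snapshots.append(Snapshot(times[k], xy, links, mult))
    return traj


class TestMarkerRotation:
    def test_pure_translation_zero(self):
        cfg = SimulationConfig()
        centers = [(k * UM, 18 * UM) for k in range(6)]
        traj = fabricate(cfg, centers, [0.0] * 6, [0] * 6)
        assert marker_rotation(traj) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_recovered(self):
        cfg = SimulationConfig()
        n = 9
        angles = [k * (math.pi / 2) / (n - 1) for k in range(n)]
        traj = fabricate(cfg, [(20 * UM, 18 * UM)] * n, angles, [0] * n)
        assert marker_rotation(traj) == pytest.approx(math.pi / 2, abs=1e-6)

    def test_unwraps_beyond_pi(self):
        cfg = SimulationConfig()
        n = 17
        angles = [k * (2.5 * math.pi) / (n - 1) for k in range(n)]
        traj = fabricate(cfg, [(20 * UM, 18 * UM)] * n, angles, [0] * n)
        assert marker_rotation(traj) == pytest.approx(2.5 * math.pi, abs=1e-6)


def churn_events(n_per_unit, n_units, ring_id=0, wall_id=60):
    ev = []
    for k in range(int(n_per_unit * n_units)):
        t = (k + 0.5) / n_per_unit * SNAPSHOT_UNIT
        kind = "create" if k % 2 == 0 else "break"
        ev.append((t, kind, ring_id, wall_id, 0.5e-4))
    return ev


class TestClassifyMode:
    def setup_method(self):
        self.cfg = SimulationConfig()

    def test_floating(self):
        y = self.cfg.domain_height / 2
        adv = 0.9 * self.cfg.u_max * SNAPSHOT_UNIT
        centers = [(10 * UM + k * adv, y) for k in range(9)]
        label = classify_mode(fabricate(self.cfg, centers, [0.0] * 9, [0] * 9))
        assert label.mode == "floating" and label.confident

    def test_rolling(self):
        y = self.cfg.wall_y_bottom + 6 * UM
        centers = [(10 * UM + k * 2 * UM, y) for k in range(9)]
        angles = [-0.2 * k for k in range(9)]  # 1.6 rad total
        ev = churn_events(6, 4)
        label = classify_mode(fabricate(self.cfg, centers, angles,
                                        [8] * 9, events=ev))
        assert label.mode == "rolling" and label.confident

    def test_anchoring(self):
        y = self.cfg.wall_y_bottom + 5.5 * UM
        centers = [(10 * UM, y)] * 9
        label = classify_mode(fabricate(self.cfg, centers, [0.0] * 9, [10] * 9))
        assert label.mode == "anchoring" and label.confident

    def test_crawling(self):
        cfg = self.cfg.replace(remodeling_enabled=True)
        y = cfg.wall_y_bottom + 5.5 * UM
        centers = [(10 * UM + k * 1.0 * UM, y) for k in range(9)]
        ev = churn_events(6, 4)
        label = classify_mode(fabricate(cfg, centers, [-0.05 * k for k in range(9)],
                                        [9] * 9, events=ev))
        assert label.mode == "crawling" and label.confident

    def test_attach_then_detach_is_floating(self):
        # anchoring prefix then free advection -> floating by the tail rule
        y = self.cfg.wall_y_bottom + 6 * UM
        u_loc = 0.06 * (1 - (2 * 6 / 30 - 1) ** 2)
        centers, links = [], []
        x = 10 * UM
        for k in range(12):
            free = k >= 6
            x += (0.8 * u_loc * SNAPSHOT_UNIT) if free else 0.2 * UM
            centers.append((x, y))
            links.append(0 if free else 12)
        label = classify_mode(fabricate(self.cfg, centers, [0.0] * 12, links))
        assert label.mode == "floating"

    def test_deterministic(self):
        y = self.cfg.domain_height / 2
        centers = [(10 * UM + k * 9 * UM, y) for k in range(9)]
        t1 = fabricate(self.cfg, centers, [0.0] * 9, [0] * 9)
        t2 = fabricate(self.cfg, centers, [0.0] * 9, [0] * 9)
        assert classify_mode(t1) == classify_mode(t2)


class TestStiffnessSignature:
    def test_table_rows_and_softening(self):
        cfg_f = SimulationConfig(cortex_multiplier=1.0)
        y = cfg_f.domain_height / 2
        adv = 0.9 * cfg_f.u_max * SNAPSHOT_UNIT
        float_traj = fabricate(cfg_f, [(10 * UM + k * adv, y) for k in range(9)],
                               [0.0] * 9, [0] * 9)
        cfg_c = SimulationConfig(cortex_multiplier=3.0, remodeling_enabled=True)
        mult = np.full(60, 3.0)
        mult[:10] = 0.45  # softened patch near adhesions
        crawl_traj = fabricate(cfg_c, [(10 * UM + k * UM,
                                        cfg_c.wall_y_bottom + 5.5 * UM)
                                       for k in range(9)],
                               [0.0] * 9, [9] * 9,
                               soft_multipliers=[mult] * 9)
        table = stiffness_signature([
            (ModeLabel("floating", True, {}), float_traj),
            (ModeLabel("crawling", True, {}), crawl_traj),
        ])
        assert list(table.index) == ["floating", "crawling"]
        assert table.loc["floating", "adhesion_stiffness"] == 0.0
        row = table.loc["crawling"]
        assert row["near_adhesion_cortex_stiffness"] < row["cortex_stiffness"]
        assert row["cortex_stiffness"] == pytest.approx(150.0)  # 3 x 50
        assert row["nucleus_stiffness"] == pytest.approx(50.0)
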