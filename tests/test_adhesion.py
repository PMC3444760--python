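"""Dynamic adhesion: capture, strain breakage, forces, cortex remodeling."""

import numpy as np
import pytest

from ctcflow.adhesion import (
    AdhesionParams,
    AdhesionState,
    adhesion_forces,
    remodel_cortex,
    update_adhesions,
)
from ctcflow.errors import StructuralError
from ctcflow.geometry import UM
from ctcflow.mechanics import SpringNetwork

PARAMS = AdhesionParams(capture_radius=1.0 * UM, break_strain=2.0,
                        stiffness=50.0, rest_length=0.5 * UM)


def make_points(cell_y, wall_n=5):
    """One membrane point above a short row of wall points."""
    wall = np.column_stack([np.arange(wall_n) * 0.3 * UM, np.zeros(wall_n)])
    cell = np.array([[0.6 * UM, cell_y]])
    xy = np.vstack([cell, wall])
    return xy, np.array([0]), np.arange(1, wall_n + 1)


class TestUpdateAdhesions:
    def test_capture_within_radius(self):
        xy, cell, wall = make_points(0.8 * UM)
        st = update_adhesions(xy, cell, wall, AdhesionState(), PARAMS, 0.0)
        assert len(st) == 1
        assert st.events[0][1] == "create"

    def test_nearest_wall_point_chosen(self):
        xy, cell, wall = make_points(0.5 * UM)
        st = update_adhesions(xy, cell, wall, AdhesionState(), PARAMS, 0.0)
        # cell x = 0.6 um; wall points at 0.0, 0.3, 0.6, ... -> id of x=0.6
        assert xy[st.wall_id[0], 0] == pytest.approx(0.6 * UM)

    def test_no_capture_beyond_radius(self):
        xy, cell, wall = make_points(1.5 * UM)
        st = update_adhesions(xy, cell, wall, AdhesionState(), PARAMS, 0.0)
        assert len(st) == 0
        assert st.events == []

    def test_break_threshold_is_sharp(self):
        brk = PARAMS.break_length
        eps = 1e-9
        for sep, survives in [(brk - eps, True), (brk + eps, False)]:
            xy, cell, wall = make_points(0.5 * UM)
            st = update_adhesions(xy, cell, wall, AdhesionState(), PARAMS, 0.0)
            xy2 = xy.copy()
            xy2[0, 1] = sep  # stretch vertically over the bound wall point
            xy2[0, 0] = xy[st.wall_id[0], 0]
            st = update_adhesions(xy2, cell, wall, st, PARAMS, 1e-5)
            still = (len(st) == 1 and st.birth[0] == 0.0)
            assert still == survives

    def test_max_links_per_point_cap(self):
        xy, cell, wall = make_points(0.5 * UM)
        st = update_adhesions(xy, cell, wall, AdhesionState(), PARAMS, 0.0)
        st = update_adhesions(xy, cell, wall, st, PARAMS, 1e-5)
        assert len(st) == 1  # capped at one link for the single cell point

    def test_deterministic(self):
        xy, cell, wall = make_points(0.9 * UM)
        a = update_adhesions(xy.copy(), cell, wall, AdhesionState(), PARAMS, 0.0)
        b = update_adhesions(xy.copy(), cell, wall, AdhesionState(), PARAMS, 0.0)
        assert np.array_equal(a.cell_id, b.cell_id)
        assert np.array_equal(a.wall_id, b.wall_id)

    def test_event_log_monotone_and_break_after_birth(self):
        xy, cell, wall = make_points(0.5 * UM)
        st = update_adhesions(xy, cell, wall, AdhesionState(), PARAMS, 0.0)
        xy[0, 1] = 3 * UM
        st = update_adhesions(xy, cell, wall, st, PARAMS, 2e-5)
        times = [e[0] for e in st.events]
        assert times == sorted(times)
        assert st.events[-1][1] == "break"
        assert st.events[-1][0] > st.events[0][0]


class TestAdhesionForces:
    def test_empty_state_zero(self):
        xy = np.zeros((4, 2))
        assert not adhesion_forces(AdhesionState(), xy, 50.0, 0.0).any()

    def test_link_at_rest_zero(self):
        xy = np.array([[0.0, 0.5 * UM], [0.0, 0.0]])
        st = AdhesionState(np.array([0]), np.array([1]), np.array([0.0]))
        f = adhesion_forces(st, xy, 50.0, 0.5 * UM)
        assert np.allclose(f, 0.0)

    def test_zero_rest_length_magnitude(self):
        # S_A=50 dyn/cm, L_A=0, length 1e-4 cm -> 5e-3 dyn pulling together
        xy = np.array([[0.0, 1e-4], [0.0, 0.0]])
        st = AdhesionState(np.array([0]), np.array([1]), np.array([0.0]))
        f = adhesion_forces(st, xy, 50.0, 0.0)
        assert f[0, 1] == pytest.approx(-5e-3)
        assert f[1, 1] == pytest.approx(+5e-3)

    def test_action_reaction(self, rng):
        xy = rng.uniform(0, 5 * UM, size=(6, 2))
        st = AdhesionState(np.array([0, 1, 2]), np.array([3, 4, 5]),
                           np.zeros(3))
        f = adhesion_forces(st, xy, 25.0, 0.3 * UM)
        assert np.abs(f.sum(axis=0)).max() <= 1e-18

    def test_dangling_id_raises(self):
        xy = np.zeros((2, 2))
        st = AdhesionState(np.array([0]), np.array([5]), np.array([0.0]))
        with pytest.raises(StructuralError):
            adhesion_forces(st, xy, 50.0, 0.0)


class TestRemodelCortex:
    def _cortex(self):
        xy = np.array([[0.0, 0.0], [1 * UM, 0.0], [2 * UM, 0.0],
                       [6 * UM, 0.0], [7 * UM, 0.0]])
        net = SpringNetwork(np.array([0, 1, 3]), np.array([1, 2, 4]),
                            np.full(3, 50.0), np.full(3, 1e-4))
        return xy, net

    def test_no_links_restores_base(self):
        xy, net = self._cortex()
        net.multiplier[:] = 0.123
        remodel_cortex(net, xy, AdhesionState(), base_multiplier=3.0,
                       soft_multiplier=0.2, soft_radius=1.5 * UM)
        assert np.allclose(net.multiplier, 3.0)

    def test_softens_near_adhered_point_and_idempotent(self):
        xy, net = self._cortex()
        st = AdhesionState(np.array([0]), np.array([4]), np.array([0.0]))
        for _ in range(2):  # idempotent
            remodel_cortex(net, xy, st, 3.0, 0.2, 1.5 * UM)
            assert net.multiplier[0] == pytest.approx(0.6)  # 0.2 * 3
            assert net.multiplier[1] == pytest.approx(0.6)  # endpoint 1 within r
            assert net.multiplier[2] == pytest.approx(3.0)  # far spring

    def test_restored_after_break(self):
        xy, net = self._cortex()
        st = AdhesionState(np.array([0]), np.array([4]), np.array([0.0]))
        remodel_cortex(net, xy, st, 3.0, 0.2, 1.5 * UM)
        remodel_cortex(net, xy, AdhesionState(), 3.0, 0.2, 1.5 * UM)
        assert np.allclose(net.multiplier, 3.0)

    def test_invalid_soft_multiplier(self):
        xy, net = self._cortex()
        with pytest.raises(ValueError):
            remodel_cortex(net, xy, AdhesionState(), 3.0, 1.5, 1.5 * UM)


def test_params_validation():
    with pytest.raises(ValueError):
        AdhesionParams(capture_radius=0.4 * UM, rest_length=0.5 * UM).validate()
    with pytest.raises(ValueError):
        AdhesionParams(break_strain=0.9).validate()
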