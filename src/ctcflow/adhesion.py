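"""Dynamic cell–wall adhesion and adhesion-triggered cortex remodeling.

Adhesive links are short Hookean springs between membrane (outer-cortex)
points and wall points.  Receptor–ligand binding is taken to be always
effective at short range, so creation is purely geometric: an unlinked
membrane point within the capture radius of a wall point binds to its
nearest eligible wall point.  A link breaks when stretched beyond a strain
threshold.  Both rules are deterministic (nearest-neighbor with lowest-id
tie-break), so simulations are exactly reproducible.

Crawling-mode remodeling softens cortex fibers near active focal
adhesions and restores them to base stiffness immediately once the
adhesion is gone, mimicking locally signaled actin reorganization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import StructuralError
from .mechanics import SpringNetwork, network_forces

__all__ = [
    "AdhesionParams",
    "AdhesionState",
    "update_adhesions",
    "adhesion_forces",
    "remodel_cortex",
]

# floor for the breakage length scale when the rest length is zero, cm
EPS_LENGTH = 1.0e-5


@dataclass
class AdhesionParams:
    """Capture/breakage geometry and adhesive spring constants."""

    capture_radius: float = 1.0e-4  # r_on, cm
    break_strain: float = 2.0  # dimensionless, > 1
    stiffness: float = 50.0  # S_A, dyn/cm
    rest_length: float = 0.5e-4  # L_A, cm
    max_links_per_point: int = 1

    def validate(self) -> None:
        if not self.capture_radius > self.rest_length >= 0.0:
            raise ValueError("require r_on > L_A >= 0")
        if self.break_strain <= 1.0:
            raise ValueError("break strain must be > 1")
        if self.stiffness < 0:
            raise ValueError("adhesive stiffness must be >= 0")

    @property
    def break_length(self) -> float:
        return self.break_strain * max(self.rest_length, EPS_LENGTH)


@dataclass
class AdhesionState:
    """Active links plus the creation/breakage event log.

    ``cell_id``/``wall_id`` index the global point array; ``birth`` is the
    creation time of each link.  ``events`` rows are
    (time, event, cell_id, wall_id, length).
    """

    cell_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    wall_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    birth: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    events: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cell_id)

    def copy_links(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.cell_id.copy(), self.wall_id.copy(), self.birth.copy()

    def link_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.cell_id, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


def _lengths(state: AdhesionState, xy: np.ndarray) -> np.ndarray:
    d = xy[state.wall_id] - xy[state.cell_id]
    return np.hypot(d[:, 0], d[:, 1])


def update_adhesions(xy: np.ndarray, cell_ids: np.ndarray, wall_ids: np.ndarray,
                     state: AdhesionState, params: AdhesionParams,
                     t: float) -> AdhesionState:
    """One creation/breakage pass; mutates and returns ``state``.

    Breakage first (stretched links are removed and logged), then creation
    (each under-linked membrane point within ``r_on`` of a wall point gains
    a link to its nearest wall point; ties broken by lowest wall id).
    """
    params.validate()
    # --- break stretched links
    if len(state):
        ln = _lengths(state, xy)
        broken = ln > params.break_length
        if broken.any():
            for c, w, length in zip(state.cell_id[broken], state.wall_id[broken],
                                    ln[broken]):
                state.events.append((t, "break", int(c), int(w), float(length)))
            keep = ~broken
            state.cell_id = state.cell_id[keep]
            state.wall_id = state.wall_id[keep]
            state.birth = state.birth[keep]

    # --- create new links
    counts = np.zeros(len(xy), dtype=int)
    if len(state):
        np.add.at(counts, state.cell_id, 1)
    eligible = cell_ids[counts[cell_ids] < params.max_links_per_point]
    if len(eligible) and len(wall_ids):
        # wall ids sorted so that cKDTree's lowest-index tie-break maps to
        # the lowest wall id
        wsort = np.sort(wall_ids)
        tree = cKDTree(xy[wsort])
        dist, nearest = tree.query(xy[eligible], distance_upper_bound=params.capture_radius)
        hit = np.isfinite(dist)
        existing = set(zip(state.cell_id.tolist(), state.wall_id.tolist()))
        new_c, new_w = [], []
        for c, d, k in zip(eligible[hit], dist[hit], nearest[hit]):
            w = int(wsort[k])
            if (int(c), w) in existing:
                continue
            new_c.append(int(c))
            new_w.append(w)
            state.events.append((t, "create", int(c), w, float(d)))
        if new_c:
            state.cell_id = np.concatenate([state.cell_id, np.asarray(new_c, dtype=np.intp)])
            state.wall_id = np.concatenate([state.wall_id, np.asarray(new_w, dtype=np.intp)])
            state.birth = np.concatenate([state.birth, np.full(len(new_c), t)])
    return state


def adhesion_forces(state: AdhesionState, xy: np.ndarray, stiffness: float,
                    rest_length: float) -> np.ndarray:
    """Equal-and-opposite Hookean forces of every active link, dyn."""
    out = np.zeros_like(xy)
    if not len(state):
        return out
    if state.cell_id.max() >= len(xy) or state.wall_id.max() >= len(xy):
        raise StructuralError("adhesion link references a missing point id")
    net = SpringNetwork(
        state.cell_id, state.wall_id,
        np.full(len(state), float(stiffness)),
        np.full(len(state), float(rest_length)),
        kind="adhesive",
    )
    return network_forces(net, xy)


def remodel_cortex(cortex: SpringNetwork, xy: np.ndarray, state: AdhesionState,
                   base_multiplier: float, soft_multiplier: float,
                   soft_radius: float) -> SpringNetwork:
    """Soften cortex springs near active focal adhesions (in place).

    Springs with either endpoint within ``soft_radius`` of any adhered
    membrane point get multiplier ``soft_multiplier * base_multiplier``;
    every other spring is restored to ``base_multiplier``.  Idempotent for
    a fixed adhesion state, and self-restoring the step after a link
    breaks.
    """
    if not 0.0 < soft_multiplier < 1.0:
        raise ValueError("soft multiplier must lie in (0, 1)")
    if not len(state):
        cortex.multiplier[:] = base_multiplier
        return cortex
    adhered = np.unique(state.cell_id)
    tree = cKDTree(xy[adhered])
    di = tree.query(xy[cortex.i])[0]
    dj = tree.query(xy[cortex.j])[0]
    near = (di <= soft_radius) | (dj <= soft_radius)
    cortex.multiplier[:] = base_multiplier
    cortex.multiplier[near] = soft_multiplier * base_multiplier
    return cortex
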