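"""The immersed-boundary time loop and the three preset experiments.

One step of the coupled system:

  1. update adhesive links (create within capture radius, break on strain),
  2. remodel cortex stiffness near focal adhesions (crawling mode only),
  3. evaluate all Hookean spring forces on the Lagrangian points,
  4. spread the forces to the fluid grid through the regularized delta,
  5. advance the Navier–Stokes fluid (explicit advection, implicit
     viscosity, FFT pressure projection),
  6. interpolate the new velocity back to the points and advect them.

Everything is deterministic — there is no random number generator in the
loop — so identical configurations produce bit-identical trajectories.

The preset experiments mirror the three computational studies of the
model: a cortex-by-nucleus stiffness sweep of the freely flowing cell, the
four rolling cases A–D on an adhesive wall, and the crawling run in which
adhesion locally softens the cortex.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import coupling
from .adhesion import AdhesionParams, AdhesionState, adhesion_forces, remodel_cortex, update_adhesions
from .config import SNAPSHOT_UNIT, SimulationConfig
from .errors import StabilityError
from .fluid import FluidSolver, FluidState, calibrate_body_force, channel_drive_field
from .geometry import BoundaryPointSet, build_cell, build_vessel, mark_cortex_arc
from .mechanics import SpringNetwork, network_forces

__all__ = [
    "Snapshot",
    "Trajectory",
    "World",
    "build_world",
    "step",
    "run",
    "experiment_sweep",
    "experiment_rolling",
    "experiment_crawling",
    "ROLLING_CASES",
]

log = logging.getLogger(__name__)

# preset rolling cases: case -> (cortex multiplier, nucleus multiplier)
ROLLING_CASES = {"A": (3, 3), "B": (6, 3), "C": (3, 6), "D": (6, 6)}


@dataclass
class Snapshot:
    time: float
    xy: np.ndarray  # (N, 2) cm
    links: tuple  # (cell_id, wall_id, birth) arrays
    cortex_multiplier: np.ndarray

    @property
    def n_links(self) -> int:
        return len(self.links[0])


@dataclass
class Trajectory:
    """Ordered snapshots plus the static structure description."""

    config: SimulationConfig
    points: BoundaryPointSet  # initial structure (tags, markers, groups)
    snapshots: list[Snapshot] = field(default_factory=list)
    events: list = field(default_factory=list)  # adhesion event log

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    def centroid(self, group: str = "cortex_outer") -> np.ndarray:
        idx = self.points.groups[group]
        return np.array([s.xy[idx].mean(axis=0) for s in self.snapshots])


@dataclass
class World:
    """Mutable simulation state: fluid + all Lagrangian structures."""

    config: SimulationConfig
    points: BoundaryPointSet
    cortex: SpringNetwork | None
    nucleus: SpringNetwork | None
    wall_tethers: SpringNetwork
    wall_links: SpringNetwork
    adhesion: AdhesionState
    fluid: FluidState
    solver: FluidSolver
    drive: np.ndarray
    time: float = 0.0
    n_steps_done: int = 0

    @property
    def cell_ids(self) -> np.ndarray:
        return self.points.groups["cortex_outer"]

    @property
    def wall_ids(self) -> np.ndarray:
        return np.concatenate([self.points.groups["wall_bottom"],
                               self.points.groups["wall_top"]])

    def cell_centroid(self) -> np.ndarray:
        return self.points.xy[self.cell_ids].mean(axis=0)


def _offset_network(net: SpringNetwork, off: int) -> SpringNetwork:
    net.i = net.i + off
    if net.kind != "tether":
        net.j = net.j + off
    return net


def build_world(config: SimulationConfig, mark_arc: float | None = math.pi / 6) -> World:
    """Assemble walls, cell, fluid, and driving force for a configuration."""
    config.validate()
    grid = config.grid()
    S0 = config.baseline_stiffness
    wall_pts, tethers, links = build_vessel(
        config.vessel_geometry(), stiffness=S0 * config.wall_multiplier)

    if config.cell_enabled:
        cell_pts, cortex, nucleus = build_cell(
            config.cell_spec(), stiffness=S0, nucleus_stiffness=S0)
        cortex.multiplier[:] = config.cortex_multiplier
        nucleus.multiplier[:] = config.nucleus_multiplier
        if mark_arc:
            mark_cortex_arc(cell_pts, mark_arc, start=0.0,
                            center=config.cell_spec().center)
        points, off = BoundaryPointSet.concat(cell_pts, wall_pts)
        tethers = _offset_network(tethers, off)
        links = _offset_network(links, off)
    else:
        points, cortex, nucleus = wall_pts, None, None

    geom = config.vessel_geometry()
    drive = channel_drive_field(
        grid, geom,
        calibrate_body_force(config.u_max, config.vessel_width, config.viscosity))
    fl = FluidState.quiescent(grid, config.viscosity, config.density)
    # seed with the established laminar profile: the cell is dropped into
    # fully developed flow rather than a start-up transient
    rel = (grid.y() - geom.y_bottom) / geom.width
    profile = np.where((rel >= 0) & (rel <= 1),
                       config.u_max * (1.0 - (2.0 * rel - 1.0) ** 2), 0.0)
    fl.u[0] = profile[:, None]
    solver = FluidSolver(grid, config.viscosity, config.density)
    return World(config, points, cortex, nucleus, tethers, links,
                 AdhesionState(), fl, solver, drive)


def _adhesion_params(c: SimulationConfig) -> AdhesionParams:
    return AdhesionParams(c.capture_radius, c.break_strain, c.adhesion_stiffness,
                          c.adhesion_rest_length, c.max_links_per_point)


def step(world: World) -> World:
    """One immersed-boundary loop iteration (mutates and returns world)."""
    c = world.config
    xy = world.points.xy

    if c.adhesion_enabled and c.cell_enabled:
        update_adhesions(xy, world.cell_ids, world.wall_ids, world.adhesion,
                         _adhesion_params(c), world.time)
        if c.remodeling_enabled:
            remodel_cortex(world.cortex, xy, world.adhesion, c.cortex_multiplier,
                           c.soft_multiplier, c.soft_radius)

    forces = network_forces(world.wall_tethers, xy) + network_forces(world.wall_links, xy)
    if world.cortex is not None:
        forces += network_forces(world.cortex, xy) + network_forces(world.nucleus, xy)
    if len(world.adhesion):
        forces += adhesion_forces(world.adhesion, xy, c.adhesion_stiffness,
                                  c.adhesion_rest_length)

    # Eq-5 spring forces are per point; the boundary force density F(l) is
    # force per unit arclength, so divide by the local quadrature weight
    # (the spread operator then carries the ds factor back)
    density = forces / world.points.ds[:, None]
    f = world.drive + coupling.spread(xy, density, world.points.ds, world.fluid.grid)
    world.fluid = world.solver.step(world.fluid, f, c.dt)
    umax = float(np.max(np.abs(world.fluid.u)))
    if not np.isfinite(umax) or umax > 50.0 * max(c.u_max, 1e-12):
        raise StabilityError(
            f"velocity blow-up at t={world.time:.3e}s (max|u|={umax:.3e} cm/s)")

    U = coupling.interpolate(world.fluid.u, xy, world.fluid.grid)
    world.points.xy = xy + U * c.dt
    world.time += c.dt
    world.n_steps_done += 1
    return world


def _snapshot(world: World) -> Snapshot:
    return Snapshot(
        world.time, world.points.xy.copy(), world.adhesion.copy_links(),
        world.cortex.multiplier.copy() if world.cortex is not None
        else np.empty(0),
    )


def run(config: SimulationConfig, mark_arc: float | None = math.pi / 6,
        max_dt_retries: int = 3) -> Trajectory:
    """Run ``n_steps`` of the configured simulation, collecting snapshots.

    Stops early when the stop rule fires (cell centroid x beyond
    ``stop_x_fraction`` of the vessel length).  On numerical instability
    the time step is halved and the whole run restarted, up to
    ``max_dt_retries`` times, preserving determinism.
    """
    attempt = 0
    while True:
        try:
            return _run_once(config, mark_arc)
        except StabilityError:
            attempt += 1
            if attempt > max_dt_retries:
                raise
            config = config.replace(dt=config.dt / 2.0,
                                    n_steps=config.n_steps * 2,
                                    snapshot_every=config.snapshot_every * 2)
            log.warning("instability: retrying with dt=%g", config.dt)


def _run_once(config: SimulationConfig, mark_arc) -> Trajectory:
    world = build_world(config, mark_arc)
    traj = Trajectory(config, world.points.copy())
    traj.snapshots.append(_snapshot(world))
    stop_x = (None if config.stop_x_fraction is None
              else config.stop_x_fraction * config.vessel_length)
    for k in range(1, config.n_steps + 1):
        step(world)
        at_cadence = (k % config.snapshot_every == 0)
        stopped = (stop_x is not None and config.cell_enabled
                   and world.cell_centroid()[0] >= stop_x)
        if at_cadence or stopped or k == config.n_steps:
            if not at_cadence or traj.snapshots[-1].time < world.time:
                traj.snapshots.append(_snapshot(world))
        if stopped:
            break
    traj.events = list(world.adhesion.events)
    return traj


# --------------------------------------------------------------------------
# preset experiments
# --------------------------------------------------------------------------

def _horizon_steps(config: SimulationConfig, n_units: float,
                   unit: float = SNAPSHOT_UNIT) -> tuple[int, int]:
    """(n_steps, snapshot_every) covering ``n_units`` snapshot units."""
    per_unit = max(1, int(round(unit / config.dt)))
    return int(round(n_units * per_unit)), per_unit


def experiment_sweep(base: SimulationConfig | None = None,
                     levels=(1, 2, 3, 4, 5, 6),
                     positions=("center", "near_wall"),
                     metrics_fn=None) -> list[dict]:
    """Stiffness sweep of the freely flowing cell (adhesion disabled).

    Runs every (cortex multiplier) x (nucleus multiplier) x (initial
    position) combination until the cell reaches 2/3 of the vessel length
    (or the step budget).  Returns one record per run with the config,
    trajectory, and final-shape metrics.
    """
    from .metrics import shape_metrics  # local import to avoid cycle

    if base is None:
        base = SimulationConfig()
    if base.n_steps == 0:
        # a near-wall transit to 2/3 of the vessel takes ~8.5 snapshot
        # units; 12 leaves headroom for the slowest (softest) cells
        n, cad = _horizon_steps(base, 12.0)
        base = base.replace(n_steps=n, snapshot_every=cad)
    base = base.replace(adhesion_enabled=False, remodeling_enabled=False,
                        stop_x_fraction=base.stop_x_fraction or 2.0 / 3.0)
    records = []
    for kc, kn, pos in itertools.product(levels, levels, positions):
        cfg = base.replace(cortex_multiplier=float(kc), nucleus_multiplier=float(kn),
                           initial_position=pos)
        traj = run(cfg)
        idx = traj.points.groups["cortex_outer"]
        m = (metrics_fn or shape_metrics)(traj.snapshots[-1].xy[idx])
        records.append({
            "cortex_multiplier": kc, "nucleus_multiplier": kn, "position": pos,
            "config": cfg, "trajectory": traj, "metrics": m,
        })
    return records


def experiment_rolling(base: SimulationConfig | None = None,
                       cases=("A", "B", "C", "D"),
                       n_units: float = 4.0) -> dict[str, dict]:
    """The four adhesive rolling cases (adhesion on, remodeling off).

    The cell starts near the wall; snapshots fall at multiples of the
    snapshot unit t so the horizon covers t..4t.  Each record carries the
    trajectory and its locomotion-mode label.
    """
    from .metrics import classify_mode

    if base is None:
        base = SimulationConfig()
    n, cad = _horizon_steps(base, n_units)
    # snapshot 10x per unit so adhesion occupancy is well resolved; the
    # overexposed-style frames at t, 2t, ... are every 10th snapshot
    base = base.replace(initial_position="near_wall", adhesion_enabled=True,
                        remodeling_enabled=False, n_steps=n,
                        snapshot_every=max(1, cad // 10), stop_x_fraction=None)
    out = {}
    for case in cases:
        kc, kn = ROLLING_CASES[case]
        cfg = base.replace(cortex_multiplier=float(kc), nucleus_multiplier=float(kn))
        traj = run(cfg)
        label = classify_mode(traj)
        out[case] = {"config": cfg, "trajectory": traj, "label": label}
    return out


def experiment_crawling(base: SimulationConfig | None = None,
                        n_units: float = 10.0, remodeling: bool = True) -> dict:
    """Anchorage/crawling: case-C stiffness with cortex remodeling.

    The softer-cortex, stiff-nucleus cell (cortex 3x, nucleus 6x) is run
    over a 10t horizon (2.5x the rolling horizon) with adhesion-triggered
    local cortex softening.  With ``remodeling=False`` the same run
    reproduces the detachment outcome of rolling case C.
    """
    from .metrics import classify_mode

    if base is None:
        base = SimulationConfig()
    n, cad = _horizon_steps(base, n_units)
    kc, kn = ROLLING_CASES["C"]
    cfg = base.replace(initial_position="near_wall", adhesion_enabled=True,
                       remodeling_enabled=remodeling,
                       cortex_multiplier=float(kc), nucleus_multiplier=float(kn),
                       n_steps=n, snapshot_every=max(1, cad // 10),
                       stop_x_fraction=None)
    traj = run(cfg)
    return {"config": cfg, "trajectory": traj, "label": classify_mode(traj)}
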