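"""Simulation configuration: one flat dataclass, CGS units, validated.

The defaults encode the baseline microvessel scenario: a 30 um wide,
75 um long channel carrying plasma with a 0.6 mm/s parabolic peak, and a
10 um cell with a 4 um nucleus and a 2 um cortex band whose springs start
at 50 dyn/cm.  Stiffness enters through dimensionless multipliers of that
baseline, which is how the stiffness sweep and the rolling/crawling cases
are expressed (e.g. a sixfold cortex is ``cortex_multiplier = 6``).

Config files (YAML, see `ctcflow.io`) use the same field names; any
length field may instead be given with a ``_um`` suffix in microns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import ConfigurationError
from .fluid import Grid
from .geometry import UM, CellGeometrySpec, VesselGeometry

__all__ = ["SimulationConfig", "SNAPSHOT_UNIT"]

# snapshot unit "t" used by the preset experiments: time for the
# undisturbed centerline flow to advect one cell diameter (10 um / 0.6 mm/s)
SNAPSHOT_UNIT = 10 * UM / 0.06  # s, ~0.0167


# fields that carry a length in cm (accept *_um micron variants in files)
LENGTH_FIELDS = frozenset({
    "vessel_length", "vessel_width", "domain_height",
    "cell_diameter", "nucleus_diameter", "cortex_band_width",
    "initial_x", "near_wall_clearance",
    "capture_radius", "adhesion_rest_length", "soft_radius",
})


@dataclass
class SimulationConfig:
    # --- geometry (cm)
    vessel_length: float = 75 * UM
    vessel_width: float = 30 * UM
    domain_height: float = 37.5 * UM  # periodic box; dead band outside walls
    cell_diameter: float = 10 * UM
    nucleus_diameter: float = 4 * UM
    cortex_band_width: float = 2 * UM
    initial_position: str = "center"  # or "near_wall"
    initial_x: float = 15 * UM
    near_wall_clearance: float = 1 * UM
    cell_enabled: bool = True

    # --- fluid
    viscosity: float = 0.012  # g/(cm s)
    density: float = 1.0  # g/cm^3
    u_max: float = 0.06  # cm/s (0.6 mm/s)
    nx: int = 128
    ny: int = 64

    # --- stiffness (baseline dyn/cm and multipliers)
    baseline_stiffness: float = 50.0
    cortex_multiplier: float = 1.0
    nucleus_multiplier: float = 1.0
    wall_multiplier: float = 10.0

    # --- adhesion
    adhesion_enabled: bool = False
    adhesion_stiffness: float = 5.0  # S_A, dyn/cm (calibrated, see docs)
    capture_radius: float = 1.0 * UM
    adhesion_rest_length: float = 0.5 * UM
    break_strain: float = 2.0
    max_links_per_point: int = 1

    # --- cortex remodeling (crawling mode)
    remodeling_enabled: bool = False
    soft_multiplier: float = 0.15
    soft_radius: float = 3.0 * UM

    # --- numerics & output
    dt: float = 1e-5  # s
    n_steps: int = 0
    snapshot_every: int = 100  # steps between stored snapshots
    stop_x_fraction: float | None = None  # stop when centroid x >= frac * length
    point_spacing_factor: float = 0.5  # wall point spacing as a fraction of h
    cell_spacing_factor: float = 0.125  # cell point spacing as a fraction of h

    def validate(self) -> "SimulationConfig":
        if min(self.vessel_length, self.vessel_width, self.domain_height,
               self.cell_diameter) <= 0:
            raise ConfigurationError("geometry lengths must be > 0")
        if self.vessel_width >= self.domain_height:
            raise ConfigurationError("vessel width must be < domain height")
        if self.vessel_width <= self.cell_diameter:
            raise ConfigurationError("vessel width must exceed the cell diameter")
        if self.initial_position not in ("center", "near_wall"):
            raise ConfigurationError(
                f"initial_position must be 'center' or 'near_wall', got "
                f"{self.initial_position!r}"
            )
        for name in ("cortex_multiplier", "nucleus_multiplier", "wall_multiplier"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.baseline_stiffness <= 0:
            raise ConfigurationError("baseline_stiffness must be > 0")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.n_steps < 0 or self.snapshot_every < 1:
            raise ConfigurationError("n_steps >= 0 and snapshot_every >= 1 required")
        if not 0 < self.point_spacing_factor <= 0.5:
            raise ConfigurationError("point_spacing_factor must lie in (0, 0.5]")
        if not 0 < self.cell_spacing_factor <= 0.5:
            raise ConfigurationError("cell_spacing_factor must lie in (0, 0.5]")
        if self.nx < 8 or self.ny < 8:
            raise ConfigurationError("grid must be at least 8x8")
        if not 0.0 < self.soft_multiplier < 1.0:
            raise ConfigurationError("soft_multiplier must lie in (0, 1)")
        return self

    # --- derived builders -------------------------------------------------
    def grid(self) -> Grid:
        return Grid(self.nx, self.ny, self.vessel_length, self.domain_height)

    @property
    def point_spacing(self) -> float:
        return self.point_spacing_factor * self.grid().h

    @property
    def wall_y_bottom(self) -> float:
        return 0.5 * (self.domain_height - self.vessel_width)

    def vessel_geometry(self) -> VesselGeometry:
        return VesselGeometry(self.vessel_length, self.vessel_width,
                              self.point_spacing, self.wall_y_bottom,
                              self.domain_height)

    def cell_spec(self) -> CellGeometrySpec:
        if self.initial_position == "center":
            cy = self.domain_height / 2.0
        else:
            cy = (self.wall_y_bottom + self.near_wall_clearance
                  + self.cell_diameter / 2.0)
        return CellGeometrySpec(
            (self.initial_x, cy), self.cell_diameter, self.nucleus_diameter,
            self.cortex_band_width, self.cell_spacing_factor * self.grid().h,
        )

    # --- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in data.items():
            if key.endswith("_um") and key[:-3] in LENGTH_FIELDS:
                kwargs[key[:-3]] = float(value) * UM
            elif key in known:
                kwargs[key] = value
            else:
                raise ConfigurationError(f"unknown config key {key!r}")
        dup = {k for k in kwargs if k + "_um" in data and k in data}
        if dup:
            raise ConfigurationError(f"both cm and um forms given for {sorted(dup)}")
        return cls(**kwargs).validate()

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes).validate()
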