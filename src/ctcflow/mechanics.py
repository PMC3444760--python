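"""Hookean spring mechanics for the Lagrangian structures.

Every structure in the model — cell cortex, nuclear envelope, vessel wall,
and transient cell–wall adhesions — is a network of linear springs.  The
force a spring exerts on its endpoint ``X`` toward the partner point ``X*``
is

    F = S * (|X* - X| - L) * (X* - X) / |X* - X|

with stiffness ``S`` (dyn/cm) and rest length ``L`` (cm).  Units are CGS
throughout the package: lengths in cm, forces in dyn, time in s.

Networks store per-spring stiffness multipliers so that stiffness can be
modulated globally (all springs of the nuclear envelope, say) or locally
(individual cortex fibers near a focal adhesion) at run time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spring",
    "SpringNetwork",
    "spring_force",
    "network_forces",
    "set_stiffness",
    "elastic_energy",
]

log = logging.getLogger(__name__)

KINDS = ("elastic", "tether", "adhesive")


@dataclass
class Spring:
    """A single linear spring (convenience view; networks store arrays)."""

    i: int
    j: int
    stiffness: float  # dyn/cm
    rest_length: float  # cm
    kind: str = "elastic"
    multiplier: float = 1.0


@dataclass
class SpringNetwork:
    """Vectorized collection of springs acting on one global point array.

    ``i`` and ``j`` index into the point array the network acts on, except
    for tether springs, whose ``j`` indexes into ``anchors`` (fixed
    reference coordinates, e.g. the rest positions of wall points).
    """

    i: np.ndarray
    j: np.ndarray
    stiffness: np.ndarray  # base stiffness S, dyn/cm
    rest_length: np.ndarray  # L, cm
    kind: str = "elastic"
    multiplier: np.ndarray = field(default=None)  # type: ignore[assignment]
    anchors: np.ndarray | None = None  # (n_anchor, 2), tether targets

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.intp)
        self.j = np.asarray(self.j, dtype=np.intp)
        self.stiffness = np.asarray(self.stiffness, dtype=float)
        self.rest_length = np.asarray(self.rest_length, dtype=float)
        if self.multiplier is None:
            self.multiplier = np.ones_like(self.stiffness)
        self.validate()

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown spring kind {self.kind!r}")
        n = len(self.i)
        for name in ("j", "stiffness", "rest_length", "multiplier"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch")
        if np.any(self.stiffness < 0):
            raise ValueError("spring stiffness must be >= 0")
        if np.any(self.rest_length < 0):
            raise ValueError("rest length must be >= 0")
        if self.kind == "tether":
            if self.anchors is None:
                raise ValueError("tether network requires anchors")
        elif np.any(self.i == self.j):
            raise ValueError("elastic/adhesive spring with i == j")
        pairs = set(zip(self.i.tolist(), self.j.tolist()))
        if len(pairs) != n:
            raise ValueError("duplicate (i, j) spring pairs")

    def __len__(self) -> int:
        return len(self.i)

    @property
    def effective_stiffness(self) -> np.ndarray:
        """Per-spring stiffness after multiplier modulation, dyn/cm."""
        return self.stiffness * self.multiplier

    def copy(self) -> "SpringNetwork":
        return SpringNetwork(
            self.i.copy(),
            self.j.copy(),
            self.stiffness.copy(),
            self.rest_length.copy(),
            self.kind,
            self.multiplier.copy(),
            None if self.anchors is None else self.anchors.copy(),
        )


def spring_force(X, X_star, S: float, L: float) -> np.ndarray:
    """Force (dyn) exerted on ``X`` by a spring to ``X_star``.

    Positive tension (length > L) pulls ``X`` toward ``X_star``; the force
    on ``X_star`` is the exact negation.  A degenerate spring (coincident
    endpoints with L > 0) has no defined direction: the force is zeroed and
    a diagnostic logged, since such an event signals a too-large time step.
    """
    X = np.asarray(X, dtype=float)
    X_star = np.asarray(X_star, dtype=float)
    d = X_star - X
    r = float(np.hypot(d[0], d[1]))
    if r == 0.0:
        if L > 0.0:
            log.warning("degenerate spring: coincident endpoints with L=%g", L)
        return np.zeros(2)
    return S * (r - L) / r * d


def network_forces(network: SpringNetwork, xy: np.ndarray) -> np.ndarray:
    """Accumulate spring forces of ``network`` onto every point.

    Parameters
    ----------
    network
        Spring network whose ``i``/``j`` index rows of ``xy`` (tether ``j``
        indexes ``network.anchors``).
    xy
        (N, 2) current point positions, cm.

    Returns
    -------
    (N, 2) array of forces in dyn.  For a network free of tethers the
    forces are action–reaction pairs and sum to zero to round-off.
    """
    xy = np.asarray(xy, dtype=float)
    out = np.zeros_like(xy)
    if len(network) == 0:
        return out
    if np.any(network.i >= len(xy)) or (
        network.kind != "tether" and np.any(network.j >= len(xy))
    ):
        raise IndexError("spring endpoint id outside point array")
    pi = xy[network.i]
    pj = network.anchors[network.j] if network.kind == "tether" else xy[network.j]
    d = pj - pi
    r = np.hypot(d[:, 0], d[:, 1])
    S = network.effective_stiffness
    L = network.rest_length
    bad = (r == 0.0) & (L > 0.0)
    if np.any(bad):
        log.warning("%d degenerate springs (coincident endpoints); forces zeroed", int(bad.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        coef = np.where(r > 0.0, S * (r - L) / np.where(r > 0.0, r, 1.0), 0.0)
    f = coef[:, None] * d
    np.add.at(out, network.i, f)
    if network.kind != "tether":
        np.add.at(out, network.j, -f)
    return out


def elastic_energy(network: SpringNetwork, xy: np.ndarray) -> float:
    """Total elastic energy ``0.5 * sum S (|dX| - L)^2`` in erg."""
    xy = np.asarray(xy, dtype=float)
    pi = xy[network.i]
    pj = network.anchors[network.j] if network.kind == "tether" else xy[network.j]
    r = np.hypot(*(pj - pi).T)
    return float(0.5 * np.sum(network.effective_stiffness * (r - network.rest_length) ** 2))


def set_stiffness(network: SpringNetwork, selector, multiplier: float,
                  xy: np.ndarray | None = None) -> SpringNetwork:
    """Set the stiffness multiplier of selected springs (in place).

    ``selector`` is one of

    * the string ``"all"`` — every spring;
    * a set/array of spring row indices;
    * a callable ``pred(midpoints) -> bool mask`` evaluated on spring
      midpoints (requires ``xy``) — the spatial predicate form.

    The multiplier replaces the previous value for the selected springs, so
    the operation is reversible by reapplying the old value.
    """
    if multiplier <= 0:
        raise ValueError("stiffness multiplier must be > 0")
    if isinstance(selector, str):
        if selector != "all":
            raise ValueError(f"unknown selector {selector!r}")
        mask = np.ones(len(network), dtype=bool)
    elif callable(selector):
        if xy is None:
            raise ValueError("spatial predicate selector requires point positions")
        pi = xy[network.i]
        pj = network.anchors[network.j] if network.kind == "tether" else xy[network.j]
        mask = np.asarray(selector(0.5 * (pi + pj)), dtype=bool)
        if not mask.any():
            log.warning("set_stiffness: empty spatial selection; no-op")
            return network
    else:
        idx = np.asarray(sorted(selector) if isinstance(selector, set) else list(selector),
                         dtype=np.intp)
        mask = np.zeros(len(network), dtype=bool)
        mask[idx] = True
    network.multiplier[mask] = multiplier
    return network
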