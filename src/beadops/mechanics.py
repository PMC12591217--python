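"""Force-balance model for bead versus droplet operation.

A magnet motor dragged under a droplet containing a cluster of magnetic
beads engages three lumped forces:

* magnetic force on the cluster, proportional to the bead loading mass:
  ``F_mag = k_mag * m``;
* the droplet's internal (interfacial) restoring force, whose maximum is
  set by the deformed curvature length of the water-oil interface around
  the cluster and therefore scales with the cube root of the bead mass:
  ``F_int_max = k_int * m**(1/3)``;
* sliding friction on the droplet, proportional to transport velocity:
  ``F_fric = k_fric * v``.

Comparing the three forces partitions the (mass, speed) quadrant into
three regimes:

* ``DROPLET_OP`` — the interface can transmit enough force to tow the whole
  droplet: ``F_fric <= min(F_mag, F_int_max)``;
* ``BEAD_OP``    — the magnetic force exceeds the maximum interfacial force
  while friction pins the droplet, so the cluster is pulled out through the
  interface: ``F_mag > F_int_max`` and ``F_fric > F_int_max``;
* ``NO_ENGAGEMENT`` — neither motion is possible.

The two regime boundaries meet at the critical mass
``m* = (k_int / k_mag)**1.5``: below it the droplet/no-engagement line
``v = (k_mag / k_fric) * m`` applies, above it the droplet/bead curve
``v = (k_int / k_fric) * m**(1/3)``.  Ties resolve toward the less
energetic regime (equality keeps the droplet engaged; extraction requires
strictly exceeding the interfacial maximum).

Coefficients are lumped free parameters in consistent units
(uN, mg, mm/s); unit values are the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError


class ZoneLabel(str, Enum):
    NO_ENGAGEMENT = "NO_ENGAGEMENT"
    DROPLET_OP = "DROPLET_OP"
    BEAD_OP = "BEAD_OP"


@dataclass(frozen=True)
class ForceParams:
    """Lumped force coefficients (all strictly positive).

    k_mag : magnetic force per unit bead mass [uN/mg]
    k_int : maximum interfacial force per unit mass^(1/3) [uN/mg^(1/3)]
    k_fric: friction force per unit droplet velocity [uN/(mm/s)]
    """

    k_mag: float = 1.0
    k_int: float = 1.0
    k_fric: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_mag", "k_int", "k_fric"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"{name} must be strictly positive and finite, got {v}")

    @property
    def critical_mass(self) -> float:
        """Triple-point mass m* = (k_int/k_mag)^(3/2) [mg]."""
        return (self.k_int / self.k_mag) ** 1.5


@dataclass(frozen=True)
class OperationPoint:
    """One operating condition: bead loading mass [mg], motor speed [mm/s]."""

    mass: float
    speed: float

    def __post_init__(self) -> None:
        if self.mass < 0 or self.speed < 0:
            raise ConfigError("mass and speed must be >= 0")


@dataclass(frozen=True)
class BoundaryCurves:
    """Analytical zone boundaries over a mass range."""

    m_star: float
    mass: np.ndarray
    v_no_engagement: np.ndarray  # droplet/no-engagement line, defined for m <= m*
    v_bead: np.ndarray  # droplet/bead curve, defined for m >= m*


@dataclass
class ZoneDiagram:
    """Pointwise regime classification over a (mass, speed) grid."""

    mass_grid: np.ndarray
    speed_grid: np.ndarray
    labels: np.ndarray  # shape (len(speed_grid), len(mass_grid)), dtype object
    boundaries: BoundaryCurves

    def to_frame(self) -> pd.DataFrame:
        """Long-format (mass, speed, zone) table, figure/CSV-ready."""
        mm, ss = np.meshgrid(self.mass_grid, self.speed_grid)
        return pd.DataFrame(
            {
                "mass_mg": mm.ravel(),
                "speed_mm_s": ss.ravel(),
                "zone": [z.value for z in self.labels.ravel()],
            }
        )


def forces(point: OperationPoint, params: ForceParams) -> tuple[float, float, float]:
    """Return (F_mag, F_int_max, F_fric) at an operating point [uN]."""
    f_mag = params.k_mag * point.mass
    f_int = params.k_int * point.mass ** (1.0 / 3.0)
    f_fric = params.k_fric * point.speed
    return f_mag, f_int, f_fric


def classify(point: OperationPoint, params: ForceParams) -> ZoneLabel:
    """Assign the operating regime at one (mass, speed) point.

    The degenerate origin (mass = 0, speed = 0) classifies as DROPLET_OP:
    all three forces vanish and the tie-break keeps the droplet engaged.
    """
    f_mag, f_int, f_fric = forces(point, params)
    if f_fric <= min(f_mag, f_int):
        return ZoneLabel.DROPLET_OP
    if f_mag > f_int and f_fric > f_int:
        return ZoneLabel.BEAD_OP
    return ZoneLabel.NO_ENGAGEMENT


def classify_array(
    mass: np.ndarray, speed: np.ndarray, params: ForceParams
) -> np.ndarray:
    """Vectorised :func:`classify`; returns an object array of ZoneLabel."""
    mass = np.asarray(mass, dtype=float)
    speed = np.asarray(speed, dtype=float)
    f_mag = params.k_mag * mass
    f_int = params.k_int * np.cbrt(mass)
    f_fric = params.k_fric * speed
    droplet = f_fric <= np.minimum(f_mag, f_int)
    bead = ~droplet & (f_mag > f_int) & (f_fric > f_int)
    out = np.empty(mass.shape, dtype=object)
    out[...] = ZoneLabel.NO_ENGAGEMENT
    out[droplet] = ZoneLabel.DROPLET_OP
    out[bead] = ZoneLabel.BEAD_OP
    return out


def droplet_speed_limit(mass: float, params: ForceParams) -> float:
    """Highest speed at which a droplet with bead mass ``m`` still moves.

    Equals the binding boundary at that mass: the magnetic line below m*,
    the interfacial curve above it.
    """
    if mass <= 0:
        return 0.0
    return min(params.k_mag * mass, params.k_int * mass ** (1.0 / 3.0)) / params.k_fric


def bead_speed_threshold(mass: float, params: ForceParams) -> float:
    """Speed that must be strictly exceeded to extract the cluster.

    Only meaningful for mass > m*; below the critical mass extraction is
    infeasible at any speed (the magnetic force never exceeds the
    interfacial maximum) and ``inf`` is returned.
    """
    if mass <= params.critical_mass:
        return float("inf")
    return params.k_int * mass ** (1.0 / 3.0) / params.k_fric


def zone_boundaries(
    params: ForceParams, mass_range: Sequence[float] | np.ndarray
) -> BoundaryCurves:
    """Analytical boundary curves sampled over ``mass_range``.

    The droplet/no-engagement line and droplet/bead curve are reported as
    NaN outside their domains (m > m* and m < m* respectively); both pass
    through the triple point (m*, k_mag*m*/k_fric).
    """
    mass = np.asarray(mass_range, dtype=float)
    if mass.size == 0:
        raise ConfigError("empty mass range")
    if np.any(mass < 0):
        raise ConfigError("mass range must be non-negative")
    m_star = params.critical_mass
    v_ne = np.where(mass <= m_star, params.k_mag * mass / params.k_fric, np.nan)
    v_bead = np.where(mass >= m_star, params.k_int * np.cbrt(mass) / params.k_fric, np.nan)
    return BoundaryCurves(m_star=m_star, mass=mass, v_no_engagement=v_ne, v_bead=v_bead)


def phase_diagram(
    params: ForceParams,
    mass_grid: Sequence[float] | np.ndarray,
    speed_grid: Sequence[float] | np.ndarray,
) -> ZoneDiagram:
    """Classify every point of a (mass, speed) grid.

    Axis grids must be strictly increasing.
    """
    mass_grid = np.asarray(mass_grid, dtype=float)
    speed_grid = np.asarray(speed_grid, dtype=float)
    for name, g in (("mass", mass_grid), ("speed", speed_grid)):
        if g.size == 0:
            raise ConfigError(f"empty {name} grid")
        if g.size > 1 and np.any(np.diff(g) <= 0):
            raise ConfigError(f"{name} grid must be strictly increasing")
        if np.any(g < 0):
            raise ConfigError(f"{name} grid must be non-negative")
    mm, ss = np.meshgrid(mass_grid, speed_grid)
    labels = classify_array(mm, ss, params)
    return ZoneDiagram(
        mass_grid=mass_grid,
        speed_grid=speed_grid,
        labels=labels,
        boundaries=zone_boundaries(params, mass_grid),
    )


def plot_phase_diagram(diagram: ZoneDiagram, path: str) -> None:
    """Render the zone diagram with analytical boundary curves to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [ZoneLabel.NO_ENGAGEMENT, ZoneLabel.DROPLET_OP, ZoneLabel.BEAD_OP]
    colors = {"NO_ENGAGEMENT": "#f5d76e", "DROPLET_OP": "#f4b8c4", "BEAD_OP": "#9bd4e4"}
    z = np.vectorize(lambda l: order.index(l))(diagram.labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.pcolormesh(
        diagram.mass_grid,
        diagram.speed_grid,
        z,
        cmap=matplotlib.colors.ListedColormap([colors[l.value] for l in order]),
        vmin=-0.5,
        vmax=2.5,
        shading="nearest",
    )
    b = diagram.boundaries
    ax.plot(b.mass, b.v_no_engagement, "k-", lw=1.5, label="droplet/no-engagement")
    ax.plot(b.mass, b.v_bead, "k--", lw=1.5, label="droplet/bead")
    ax.axvline(b.m_star, color="k", lw=0.5, ls=":")
    ax.set_xlabel("bead loading mass [mg]")
    ax.set_ylabel("motor speed [mm/s]")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
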