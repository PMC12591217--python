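"""Fluidic state of the exosome-detection biochip.

The biochip is a sealed oil-filled cartridge whose reagent reservoirs hold
the assay droplets: one 8 ul bead droplet, four 50 ul wash droplets, one
50 ul HRP-conjugated anti-Ab42 labelling droplet, one 50 ul TMB substrate
droplet (in the detection chamber) and one 50 ul stop-buffer droplet that
carries its own inert transport beads.  Droplets are point objects on the
coil-grid lattice with volume and composition metadata; bead clusters
travel either inside a droplet or through the oil phase.

Events: move a droplet (requires the droplet-operation regime), extract a
bead cluster through the water-oil interface (bead-operation regime,
dragging a configurable carryover fraction of the droplet's free species),
re-insert a cluster into a droplet, merge two droplets, and mix (which
advances the assay capture clock).  All events conserve species amounts
and volumes exactly; repeated wash transfers attenuate carried
contaminants geometrically (residual fraction ``carryover**n`` after
``n`` washes).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from . import assay as assay_mod
from .errors import ActuationFault, ConfigError, LayoutError, StateError
from .mechanics import ForceParams, OperationPoint, ZoneLabel, classify

OIL = "oil"

#: Default per-transfer fraction of a droplet's free (unbound) species that
#: travels with an extracted bead cluster.
DEFAULT_CARRYOVER = 0.01

DEFAULT_CHAMBER_HEIGHT_MM = 3.0


@dataclass
class Reservoir:
    name: str
    cell: tuple[int, int]
    volume_ul: float
    contents: dict[str, float] = field(default_factory=dict)
    with_beads: bool = False


@dataclass
class ChipLayout:
    """Static geometry: named reservoirs, oil zone, detection chamber."""

    reservoirs: dict[str, Reservoir]
    detection_chamber: tuple[int, int]
    chamber_height_mm: float = DEFAULT_CHAMBER_HEIGHT_MM
    carryover: float = DEFAULT_CARRYOVER

    def __post_init__(self) -> None:
        cells = [r.cell for r in self.reservoirs.values()]
        if len(cells) != len(set(cells)):
            raise LayoutError("reservoir regions overlap")
        if not 0.0 <= self.carryover < 1.0:
            raise ConfigError("carryover fraction must be in [0, 1)")
        if self.chamber_height_mm <= 0:
            raise ConfigError("chamber height must be > 0")

    @property
    def wash_names(self) -> list[str]:
        return sorted(n for n in self.reservoirs if n.startswith("wash"))


@dataclass
class Droplet:
    id: str
    cell: tuple[int, int]
    volume_ul: float
    composition: dict[str, float] = field(default_factory=dict)
    beads_present: bool = False

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise ConfigError(f"droplet {self.id}: volume must be > 0")
        if any(v < 0 for v in self.composition.values()):
            raise ConfigError(f"droplet {self.id}: species amounts must be >= 0")

    def concentration_pg_ml(self, species: str) -> float:
        return self.composition.get(species, 0.0) / (self.volume_ul / 1000.0)


@dataclass
class BeadCluster:
    id: str
    mass_mg: float
    surface: assay_mod.BeadSurface
    carrier: str = OIL  # droplet id, or OIL
    carried_free: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mass_mg <= 0:
            raise ConfigError(f"cluster {self.id}: mass must be > 0")


@dataclass
class ChipState:
    """Dynamic chip contents plus an append-only event log."""

    layout: ChipLayout
    droplets: dict[str, Droplet] = field(default_factory=dict)
    clusters: dict[str, BeadCluster] = field(default_factory=dict)
    time_s: float = 0.0
    log: list[dict] = field(default_factory=list)

    def copy(self) -> "ChipState":
        return copy.deepcopy(self)

    def droplet(self, droplet_id: str) -> Droplet:
        try:
            return self.droplets[droplet_id]
        except KeyError:
            raise StateError(f"unknown droplet {droplet_id!r}") from None

    def cluster(self, cluster_id: str) -> BeadCluster:
        try:
            return self.clusters[cluster_id]
        except KeyError:
            raise StateError(f"unknown bead cluster {cluster_id!r}") from None

    def beads_in(self, droplet_id: str) -> list[BeadCluster]:
        return [c for c in self.clusters.values() if c.carrier == droplet_id]

    def bead_mass_in(self, droplet_id: str) -> float:
        return sum(c.mass_mg for c in self.beads_in(droplet_id))

    def occupied_cells(self, exclude: str | None = None) -> set[tuple[int, int]]:
        return {d.cell for d in self.droplets.values() if d.id != exclude}

    def species_totals(self) -> dict[str, float]:
        """Total amount of every species across droplets and clusters."""
        totals: dict[str, float] = {}
        for d in self.droplets.values():
            for sp, amt in d.composition.items():
                totals[sp] = totals.get(sp, 0.0) + amt
        for c in self.clusters.values():
            for sp, amt in c.carried_free.items():
                totals[sp] = totals.get(sp, 0.0) + amt
            for sp, amt in c.surface.captured.items():
                totals[sp] = totals.get(sp, 0.0) + amt
            if c.surface.bound_hrp > 0:
                totals["hrp_ab"] = totals.get("hrp_ab", 0.0) + c.surface.bound_hrp
        return totals

    def _record(self, event: str, **info) -> None:
        self.log.append({"time_s": self.time_s, "event": event, **info})


def initial_state(
    layout: ChipLayout,
    assay_params: assay_mod.AssayParams | None = None,
    bead_mass_mg: float = 2.0,
    stop_bead_mass_mg: float = 2.0,
) -> ChipState:
    """Instantiate droplets and bead clusters from a layout.

    Each reservoir spawns one droplet; the bead reservoir additionally
    spawns the assay cluster (anti-CD63 functionalised) and a reservoir
    flagged ``with_beads`` spawns an inert transport cluster (the stop
    droplet ships its own beads so it can be towed).
    """
    assay_params = assay_params or assay_mod.AssayParams()
    state = ChipState(layout=layout)
    for name, res in layout.reservoirs.items():
        state.droplets[name] = Droplet(
            id=name,
            cell=res.cell,
            volume_ul=res.volume_ul,
            composition=dict(res.contents),
        )
    if "beads" in state.droplets:
        state.droplets["beads"].beads_present = True
        state.clusters["ime_beads"] = BeadCluster(
            id="ime_beads",
            mass_mg=bead_mass_mg,
            surface=assay_mod.BeadSurface(
                capacity=assay_params.site_capacity_per_mg * bead_mass_mg
            ),
            carrier="beads",
        )
    for name, res in layout.reservoirs.items():
        if res.with_beads and name != "beads":
            state.droplets[name].beads_present = True
            state.clusters[f"{name}_beads"] = BeadCluster(
                id=f"{name}_beads",
                mass_mg=stop_bead_mass_mg,
                surface=assay_mod.BeadSurface(capacity=1e-12),  # inert transport beads
                carrier=name,
            )
    return state


def move_droplet(
    state: ChipState,
    droplet_id: str,
    dest: tuple[int, int],
    speed: float,
    params: ForceParams,
) -> ChipState:
    """Tow a droplet (with any embedded beads) to ``dest``.

    The operating point (embedded bead mass, speed) must classify as
    DROPLET_OP; otherwise the droplet either stays pinned or sheds its
    beads, and an actuation fault names the computed zone.
    """
    drop = state.droplet(droplet_id)
    dest = tuple(dest)
    mass = state.bead_mass_in(droplet_id)
    zone = classify(OperationPoint(mass=mass, speed=speed), params)
    if zone is not ZoneLabel.DROPLET_OP:
        raise ActuationFault(
            f"cannot tow droplet {droplet_id!r} at {speed} mm/s with {mass} mg beads: "
            f"operating point is {zone.value}"
        )
    src = drop.cell
    drop.cell = dest
    state._record("move_droplet", droplet=droplet_id, src=list(src), dest=list(dest), speed=speed)
    return state


def extract_beads(
    state: ChipState,
    droplet_id: str,
    speed: float,
    params: ForceParams,
    cluster_id: str | None = None,
) -> ChipState:
    """Pull a bead cluster out of a droplet, across the water-oil interface.

    Requires the BEAD_OP regime at (cluster mass, speed).  The droplet stays
    behind with unchanged volume; a fraction ``layout.carryover`` of each of
    its free (unbound) species travels with the cluster as surface wetting.
    """
    drop = state.droplet(droplet_id)
    clusters = state.beads_in(droplet_id)
    if not clusters:
        raise StateError(f"droplet {droplet_id!r} contains no beads")
    if cluster_id is None:
        cluster = clusters[0]
    else:
        cluster = state.cluster(cluster_id)
        if cluster.carrier != droplet_id:
            raise StateError(f"cluster {cluster.id!r} is not in droplet {droplet_id!r}")
    zone = classify(OperationPoint(mass=cluster.mass_mg, speed=speed), params)
    if zone is not ZoneLabel.BEAD_OP:
        raise ActuationFault(
            f"cannot extract cluster {cluster.id!r} at {speed} mm/s with "
            f"{cluster.mass_mg} mg beads: operating point is {zone.value}"
        )
    f = state.layout.carryover
    for sp in list(drop.composition):
        moved = f * drop.composition[sp]
        if moved > 0:
            drop.composition[sp] -= moved
            cluster.carried_free[sp] = cluster.carried_free.get(sp, 0.0) + moved
    cluster.carrier = OIL
    drop.beads_present = any(c.carrier == droplet_id for c in state.clusters.values())
    state._record("extract_beads", droplet=droplet_id, cluster=cluster.id, speed=speed)
    return state


def insert_beads(state: ChipState, cluster_id: str, droplet_id: str) -> ChipState:
    """Deliver an oil-borne bead cluster into a droplet.

    Any free species carried through the oil dissolve into the droplet.
    """
    cluster = state.cluster(cluster_id)
    if cluster.carrier != OIL:
        raise StateError(
            f"cluster {cluster_id!r} is already inside droplet {cluster.carrier!r}"
        )
    drop = state.droplet(droplet_id)
    for sp, amt in cluster.carried_free.items():
        drop.composition[sp] = drop.composition.get(sp, 0.0) + amt
    cluster.carried_free = {}
    cluster.carrier = droplet_id
    drop.beads_present = True
    state._record("insert_beads", droplet=droplet_id, cluster=cluster_id)
    return state


def merge(state: ChipState, droplet_a: str, droplet_b: str) -> ChipState:
    """Coalesce droplet ``b`` into droplet ``a``.

    Requires co-location or 4-adjacency.  Volumes and species amounts add;
    instant perfect mixing is assumed, so concentrations follow as
    amount / combined volume.  Bead clusters riding in ``b`` transfer to
    the merged droplet.
    """
    if droplet_a == droplet_b:
        raise ConfigError("cannot merge a droplet with itself")
    a = state.droplet(droplet_a)
    b = state.droplet(droplet_b)
    dist = abs(a.cell[0] - b.cell[0]) + abs(a.cell[1] - b.cell[1])
    if dist > 1:
        raise StateError(
            f"droplets {droplet_a!r} and {droplet_b!r} are not adjacent (distance {dist})"
        )
    a.volume_ul += b.volume_ul
    for sp, amt in b.composition.items():
        a.composition[sp] = a.composition.get(sp, 0.0) + amt
    for c in state.clusters.values():
        if c.carrier == droplet_b:
            c.carrier = droplet_a
    a.beads_present = a.beads_present or b.beads_present
    del state.droplets[droplet_b]
    state._record("merge", into=droplet_a, absorbed=droplet_b, volume_ul=a.volume_ul)
    return state


def mix(
    state: ChipState,
    droplet_id: str,
    duration_min: float,
    assay_params: assay_mod.AssayParams,
) -> ChipState:
    """Magnetically rotate the beads inside a droplet for ``duration_min``.

    Mixing is what advances the assay's binding clock: capture kinetics run
    on capturable species, and labelling kinetics run if the droplet holds
    the HRP conjugate.  Two mixes of t/2 are equivalent to one mix of t.
    """
    drop = state.droplet(droplet_id)
    clusters = state.beads_in(droplet_id)
    if not clusters:
        raise StateError(f"cannot mix droplet {droplet_id!r}: no beads present")
    for cluster in clusters:
        if cluster.surface.capacity > 1e-9:  # skip inert transport beads
            cluster.surface, removed = assay_mod.capture(
                cluster.surface, drop.composition, drop.volume_ul, duration_min, assay_params
            )
            for sp, amt in removed.items():
                drop.composition[sp] = max(drop.composition.get(sp, 0.0) - amt, 0.0)
            hrp_before = cluster.surface.bound_hrp
            assay_mod.label(cluster.surface, drop.composition, duration_min, assay_params)
            delta_hrp = cluster.surface.bound_hrp - hrp_before
            if delta_hrp > 0:  # label conjugate leaves solution as it binds
                drop.composition["hrp_ab"] = max(
                    drop.composition.get("hrp_ab", 0.0) - delta_hrp, 0.0
                )
    state.time_s += duration_min * 60.0
    state._record("mix", droplet=droplet_id, duration_min=duration_min)
    return state
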