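"""Assay-program compilation and execution.

A protocol is an ordered list of high-level commands (move a droplet, move
a bead cluster, mix, merge, incubate, read).  The compiler turns it into a
timed coil-activation schedule: breadth-first path-finding over the coil
lattice (4-connected, row-major tie-break) routes the magnet motor, and
per-command dwell times are chosen so that the force-balance regime
matches the verb — droplet tows run strictly inside the droplet-operation
zone, bead extractions strictly inside the bead-operation zone, with the
speed placed at the geometric midpoint of the feasible interval to
maximise margin to both boundaries.

The default shipped program automates the six-step bead-based sandwich
assay: (1) mix the capture beads in the sample droplet, (2) extract the
cluster across the water-oil interface into a wash droplet, (3) label with
the HRP conjugate, (4) three washes then delivery to the substrate-filled
detection chamber, (5) tow and merge the stop droplet, (6) remove the
beads from the chamber and read.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import assay as assay_mod
from . import biochip as chip_mod
from . import emgrid, readout as readout_mod
from .errors import CompilationError, ConfigError, RoutingError
from .mechanics import (
    ForceParams,
    bead_speed_threshold,
    droplet_speed_limit,
)

VERBS = {
    "MOVE_MOTOR",
    "MIX",
    "MOVE_DROPLET",
    "MOVE_BEADS",
    "INSERT_BEADS",
    "MERGE",
    "INCUBATE",
    "READ",
}

_REQUIRED_ARGS = {
    "MOVE_MOTOR": {"dest"},
    "MIX": {"droplet", "duration_min"},
    "MOVE_DROPLET": {"droplet", "dest"},
    "MOVE_BEADS": {"src", "dest"},
    "INSERT_BEADS": {"cluster", "droplet"},
    "MERGE": {"into", "absorb"},
    "INCUBATE": {"duration_min"},
    "READ": set(),
}


@dataclass(frozen=True)
class Command:
    verb: str
    args: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verb not in VERBS:
            raise ConfigError(f"unknown verb {self.verb!r}")
        missing = _REQUIRED_ARGS[self.verb] - set(self.args)
        if missing:
            raise ConfigError(f"{self.verb}: missing argument(s) {sorted(missing)}")
        for key in ("speed", "duration_min"):
            if key in self.args and float(self.args[key]) <= 0:
                raise ConfigError(f"{self.verb}: {key} must be > 0")

    def arg(self, key: str, default: str | None = None) -> str:
        if key in self.args:
            return self.args[key]
        if default is None:
            raise ConfigError(f"{self.verb}: missing argument {key!r}")
        return default


@dataclass
class Program:
    commands: list[Command]
    name: str = "unnamed"
    version: str = "1"


@dataclass(frozen=True)
class ScheduleEvent:
    time_s: float
    coil_id: int
    action: str  # "on" | "off"


@dataclass
class ActivationSchedule:
    events: list[ScheduleEvent] = field(default_factory=list)

    @property
    def runtime_s(self) -> float:
        return self.events[-1].time_s if self.events else 0.0

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            [{"time_s": e.time_s, "coil_id": e.coil_id, "action": e.action} for e in self.events]
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# path-finding

_NEIGHBOUR_OFFSETS = ((-1, 0), (0, -1), (0, 1), (1, 0))  # row-major order


def find_path(
    grid: emgrid.CoilGrid,
    start: tuple[int, int],
    goal: tuple[int, int],
    blocked: set[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Shortest 4-connected path on the coil lattice, BFS with row-major
    neighbour expansion (deterministic tie-break).  Returns the inclusive
    cell sequence; ``start == goal`` gives a length-1 path.
    """
    start, goal = tuple(start), tuple(goal)
    blocked = set(blocked or ())
    for cell, what in ((start, "start"), (goal, "goal")):
        if not grid.has_cell(cell):
            raise RoutingError(f"{what} cell {cell} not on grid")
    if goal in blocked:
        raise RoutingError(f"goal cell {goal} is blocked")
    if start == goal:
        return [start]
    prev: dict[tuple[int, int], tuple[int, int]] = {start: start}
    queue = deque([start])
    while queue:
        cell = queue.popleft()
        for dr, dc in _NEIGHBOUR_OFFSETS:
            nxt = (cell[0] + dr, cell[1] + dc)
            if nxt in prev or not grid.has_cell(nxt) or nxt in blocked:
                continue
            prev[nxt] = cell
            if nxt == goal:
                path = [nxt]
                while path[-1] != start:
                    path.append(prev[path[-1]])
                return path[::-1]
            queue.append(nxt)
    raise RoutingError(f"no path from {start} to {goal}")


# ---------------------------------------------------------------------------
# speed selection

DEFAULT_SPEED_FLOOR = 0.05  # mm/s, slowest practical droplet tow
DEFAULT_SPEED_CAP = 50.0  # mm/s, fastest commanded motor speed
DEFAULT_TRAVEL_SPEED = 20.0  # mm/s, free motor travel (no payload)


def select_droplet_speed(
    mass_mg: float,
    params: ForceParams,
    floor: float = DEFAULT_SPEED_FLOOR,
    cap: float = DEFAULT_SPEED_CAP,
) -> float:
    """Tow speed strictly inside the droplet-operation zone.

    Geometric midpoint of the feasible interval (floor, min(limit, cap)).
    """
    limit = min(droplet_speed_limit(mass_mg, params), cap)
    if not limit > floor:
        raise CompilationError(
            f"no feasible droplet-operation speed for bead mass {mass_mg} mg: "
            f"zone ceiling {limit:.4g} mm/s is below the speed floor {floor} mm/s"
        )
    return float(np.sqrt(floor * limit))


def select_bead_speed(
    mass_mg: float,
    params: ForceParams,
    cap: float = DEFAULT_SPEED_CAP,
) -> float:
    """Extraction speed strictly inside the bead-operation zone.

    Requires the bead mass to exceed the critical mass m*; below it the
    magnetic force never exceeds the maximum interfacial force and
    extraction is infeasible at any speed.
    """
    threshold = bead_speed_threshold(mass_mg, params)
    if not np.isfinite(threshold):
        raise CompilationError(
            f"bead extraction infeasible: mass {mass_mg} mg does not exceed the "
            f"critical mass m* = {params.critical_mass:.4g} mg (bead-operation zone "
            "is empty at this mass)"
        )
    if not cap > threshold:
        raise CompilationError(
            f"no feasible bead-operation speed: boundary {threshold:.4g} mm/s "
            f"exceeds the speed cap {cap} mm/s"
        )
    return float(np.sqrt(threshold * cap))


# ---------------------------------------------------------------------------
# default six-step program

DEFAULT_CAPTURE_MIN = 30.0
DEFAULT_LABEL_MIN = 30.0
DEFAULT_WASH_MIN = 1.0
DEFAULT_DEVELOP_MIN = 10.0


def default_ime_program(layout: chip_mod.ChipLayout) -> Program:
    """The shipped six-step assay program for the default chip layout.

    Exactly three wash transfers separate labelling from chamber delivery,
    one merge (the stop droplet) ends signal development, and the run
    finishes with bead removal and a READ.
    """
    required = {"beads", "sample", "label", "chamber", "stop"}
    missing = required - set(layout.reservoirs)
    if missing:
        raise CompilationError(f"layout missing reservoir(s): {sorted(missing)}")
    washes = layout.wash_names
    if len(washes) < 4:
        raise CompilationError(
            f"default program needs 4 wash reservoirs (1 pre-label + 3 post-label), "
            f"layout has {len(washes)}"
        )
    chamber = layout.reservoirs["chamber"].cell
    stage = (chamber[0] + 1, chamber[1])  # merge staging cell next to the chamber
    park = layout.reservoirs["beads"].cell

    def cmd(verb: str, **args: object) -> Command:
        return Command(verb, {k: str(v) for k, v in args.items()})

    cmds = [
        # step 1 — deliver capture beads to the sample and mix (CD63 capture)
        cmd("MOVE_BEADS", cluster="ime_beads", src="beads", dest="sample"),
        cmd("INSERT_BEADS", cluster="ime_beads", droplet="sample"),
        cmd("MIX", droplet="sample", duration_min=DEFAULT_CAPTURE_MIN),
        # step 2 — extract across the interface, first wash
        cmd("MOVE_BEADS", cluster="ime_beads", src="sample", dest=washes[0]),
        cmd("INSERT_BEADS", cluster="ime_beads", droplet=washes[0]),
        cmd("MIX", droplet=washes[0], duration_min=DEFAULT_WASH_MIN),
        # step 3 — HRP anti-Ab42 labelling
        cmd("MOVE_BEADS", cluster="ime_beads", src=washes[0], dest="label"),
        cmd("INSERT_BEADS", cluster="ime_beads", droplet="label"),
        cmd("MIX", droplet="label", duration_min=DEFAULT_LABEL_MIN),
    ]
    # step 4 — three washes, then delivery to the substrate chamber
    src = "label"
    for wash in washes[1:4]:
        cmds += [
            cmd("MOVE_BEADS", cluster="ime_beads", src=src, dest=wash),
            cmd("INSERT_BEADS", cluster="ime_beads", droplet=wash),
            cmd("MIX", droplet=wash, duration_min=DEFAULT_WASH_MIN),
        ]
        src = wash
    cmds += [
        cmd("MOVE_BEADS", cluster="ime_beads", src=src, dest="chamber"),
        cmd("INSERT_BEADS", cluster="ime_beads", droplet="chamber"),
        cmd("INCUBATE", duration_min=DEFAULT_DEVELOP_MIN),
        # step 5 — tow the stop droplet over and merge to freeze the signal
        cmd("MOVE_DROPLET", droplet="stop", dest=f"{stage[0]},{stage[1]}"),
        cmd("MERGE", into="chamber", absorb="stop"),
        # step 6 — clear all beads from the chamber, then read
        cmd("MOVE_BEADS", cluster="ime_beads", src="chamber", dest=f"{park[0]},{park[1]}"),
        cmd("MOVE_BEADS", cluster="stop_beads", src="chamber", dest=f"{park[0]},{park[1]}"),
        cmd("READ"),
    ]
    return Program(commands=cmds, name="ime-assay-6step")


# ---------------------------------------------------------------------------
# DSL

def parse_program(text: str, name: str = "unnamed") -> Program:
    """Parse the one-command-per-line protocol DSL.

    Lines are ``VERB key=value ...``; ``#`` starts a comment.
    """
    commands = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        verb, kvs = parts[0].upper(), parts[1:]
        args = {}
        for kv in kvs:
            if "=" not in kv:
                raise ConfigError(f"line {lineno}: malformed argument {kv!r}")
            k, v = kv.split("=", 1)
            args[k] = v
        commands.append(Command(verb, args))
    return Program(commands=commands, name=name)


def format_program(program: Program) -> str:
    lines = [f"# protocol: {program.name} (v{program.version})"]
    for c in program.commands:
        lines.append(" ".join([c.verb] + [f"{k}={v}" for k, v in c.args.items()]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# executor

def _parse_dest(
    value: str, state: chip_mod.ChipState
) -> tuple[int, int]:
    """A destination is either a reservoir/droplet name or ``row,col``."""
    if "," in value:
        r, c = value.split(",", 1)
        return (int(r), int(c))
    if value in state.droplets:
        return state.droplets[value].cell
    if value in state.layout.reservoirs:
        return state.layout.reservoirs[value].cell
    raise ConfigError(f"unknown destination {value!r}")


@dataclass
class RunRecord:
    """Full deterministic trace of one protocol run."""

    seed: int
    program: str
    events: list[dict]
    schedule: ActivationSchedule
    runtime_s: float
    signal: float | None = None
    readout: readout_mod.ReadoutResult | None = None

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "program": self.program,
            "runtime_s": self.runtime_s,
            "signal": self.signal,
            "readout": None
            if self.readout is None
            else {
                "i_raw": self.readout.i_raw,
                "i_readout": self.readout.i_readout,
                "i_ref": self.readout.i_ref,
                "i_bg": self.readout.i_bg,
            },
            "n_schedule_events": len(self.schedule.events),
            "events": self.events,
        }
        return json.dumps(payload, sort_keys=True)


class Executor:
    """Runs a program against grid + chip + mechanics, emitting a coil
    schedule and an event log as it goes."""

    def __init__(
        self,
        grid: emgrid.CoilGrid,
        state: chip_mod.ChipState,
        force_params: ForceParams,
        assay_params: assay_mod.AssayParams,
        seed: int = 0,
        drift: readout_mod.DriftModel | None = None,
        speed_floor: float = DEFAULT_SPEED_FLOOR,
        speed_cap: float = DEFAULT_SPEED_CAP,
        travel_speed: float = DEFAULT_TRAVEL_SPEED,
    ) -> None:
        self.grid = grid
        self.state = state
        self.force_params = force_params
        self.assay_params = assay_params
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.drift = drift or readout_mod.DriftModel()
        self.speed_floor = speed_floor
        self.speed_cap = speed_cap
        self.travel_speed = travel_speed
        self.motor = emgrid.motor_at(grid, (0, 0))
        self.schedule = ActivationSchedule()
        self.signal_state = assay_mod.SignalState()
        self.result: readout_mod.ReadoutResult | None = None

    # -- low-level motion -------------------------------------------------

    def _drive(self, path: list[tuple[int, int]], speed: float) -> None:
        """Step the motor along a path, one coil per step at speed-derived
        dwell, appending on/off events to the schedule."""
        dwell = self.grid.pitch / speed
        for cell in path:
            if cell == self.motor.current_cell:
                continue
            coil = self.grid.coil_at(cell)
            t = self.state.time_s
            emgrid.activate(self.grid, coil.id)
            self.schedule.events.append(ScheduleEvent(t, coil.id, "on"))
            self.motor = emgrid.step_motor(self.motor, self.grid, dwell)
            self.state.time_s += dwell
            self.schedule.events.append(ScheduleEvent(self.state.time_s, coil.id, "off"))
        emgrid.deactivate_all(self.grid)

    def _travel_to(self, cell: tuple[int, int], avoid_extra: set | None = None) -> None:
        """Free motor travel (no payload) avoiding droplet-occupied cells."""
        blocked = self.state.occupied_cells() - {tuple(cell)}
        if avoid_extra:
            blocked |= set(avoid_extra)
        path = find_path(self.grid, self.motor.current_cell, cell, blocked)
        self._drive(path, self.travel_speed)

    # -- command handlers --------------------------------------------------

    def run(self, program: Program) -> RunRecord:
        for idx, command in enumerate(program.commands):
            try:
                getattr(self, f"_do_{command.verb.lower()}")(command)
            except (ConfigError, CompilationError):
                raise
            except Exception as exc:
                raise type(exc)(f"step {idx} ({command.verb}): {exc}") from exc
        return RunRecord(
            seed=self.seed,
            program=program.name,
            events=self.state.log,
            schedule=self.schedule,
            runtime_s=self.state.time_s,
            signal=self.signal_state.signal if self.signal_state.signal else None,
            readout=self.result,
        )

    def _do_move_motor(self, cmd: Command) -> None:
        self._travel_to(_parse_dest(cmd.arg("dest"), self.state))

    def _do_mix(self, cmd: Command) -> None:
        droplet = cmd.arg("droplet")
        self._travel_to(self.state.droplet(droplet).cell)
        chip_mod.mix(self.state, droplet, float(cmd.arg("duration_min")), self.assay_params)

    def _do_move_droplet(self, cmd: Command) -> None:
        droplet_id = cmd.arg("droplet")
        drop = self.state.droplet(droplet_id)
        dest = _parse_dest(cmd.arg("dest"), self.state)
        mass = self.state.bead_mass_in(droplet_id)
        if "speed" in cmd.args:
            speed = float(cmd.args["speed"])
        else:
            speed = select_droplet_speed(mass, self.force_params, self.speed_floor, self.speed_cap)
        self._travel_to(drop.cell)
        blocked = self.state.occupied_cells(exclude=droplet_id) - {dest}
        path = find_path(self.grid, drop.cell, dest, blocked)
        chip_mod.move_droplet(self.state, droplet_id, dest, speed, self.force_params)
        self._drive(path, speed)

    def _do_move_beads(self, cmd: Command) -> None:
        src = cmd.arg("src")
        drop = self.state.droplet(src)
        dest = _parse_dest(cmd.arg("dest"), self.state)
        cluster_id = cmd.args.get("cluster")
        clusters = self.state.beads_in(src)
        if cluster_id is None and clusters:
            cluster_id = clusters[0].id
        cluster = self.state.cluster(cluster_id) if cluster_id else None
        mass = cluster.mass_mg if cluster else 0.0
        if "speed" in cmd.args:
            speed = float(cmd.args["speed"])
        else:
            speed = select_bead_speed(mass, self.force_params, self.speed_cap)
        self._travel_to(drop.cell)
        blocked = self.state.occupied_cells(exclude=src) - {dest}
        path = find_path(self.grid, drop.cell, dest, blocked)
        chip_mod.extract_beads(self.state, src, speed, self.force_params, cluster_id)
        self._drive(path, speed)

    def _do_insert_beads(self, cmd: Command) -> None:
        chip_mod.insert_beads(self.state, cmd.arg("cluster"), cmd.arg("droplet"))

    def _do_merge(self, cmd: Command) -> None:
        into, absorb = cmd.arg("into"), cmd.arg("absorb")
        chip_mod.merge(self.state, into, absorb)
        drop = self.state.droplet(into)
        if drop.composition.get("stop", 0.0) > 0:
            self.signal_state.stopped = True
            self.state._record("stop_reaction", droplet=into)

    def _do_incubate(self, cmd: Command) -> None:
        duration = float(cmd.arg("duration_min"))
        self._develop(duration)
        self.state.time_s += duration * 60.0
        self.state._record("incubate", duration_min=duration)

    def _develop(self, duration_min: float) -> None:
        """Advance colorimetric development if labelled beads sit in the
        substrate-filled chamber and the reaction is not stopped."""
        if self.signal_state.stopped:
            return
        chamber = self.state.droplets.get("chamber")
        if chamber is None or chamber.composition.get("tmb", 0.0) <= 0:
            return
        hrp = sum(c.surface.bound_hrp for c in self.state.beads_in("chamber"))
        self.signal_state = assay_mod.develop_signal(
            self.signal_state, hrp, duration_min, self.assay_params, rng=None
        )

    def _do_read(self, cmd: Command) -> None:
        chamber = self.state.droplets.get("chamber")
        signal = self.signal_state.signal or self.assay_params.background
        if self.assay_params.noise_sd > 0:
            signal = max(signal + self.rng.normal(0.0, self.assay_params.noise_sd), 0.0)
        self.result = readout_mod.measure_chamber(
            chamber,
            signal,
            drift=self.drift,
            rng=self.rng if self.drift.noise_sd > 0 else None,
            t_init=0.0,
            t_read=self.state.time_s,
        )
        self.state.time_s += 2 * readout_mod.DEFAULT_DURATION_S
        self.state._record(
            "read",
            i_raw=self.result.i_raw,
            i_readout=self.result.i_readout,
            signal=signal,
        )


def compile(
    program: Program,
    layout: chip_mod.ChipLayout,
    force_params: ForceParams,
    assay_params: assay_mod.AssayParams | None = None,
    grid: emgrid.CoilGrid | None = None,
) -> ActivationSchedule:
    """Compile a program to a coil-activation schedule via a dry run.

    The dry run executes the program against a blank sample (the schedule
    depends only on geometry and bead masses, not on chemistry); an
    infeasible speed for any command raises a CompilationError naming the
    violated zone constraint.
    """
    record = execute(program, layout, force_params, assay_params, grid=grid, seed=0)
    return record.schedule


def execute(
    program: Program,
    layout: chip_mod.ChipLayout,
    force_params: ForceParams | None = None,
    assay_params: assay_mod.AssayParams | None = None,
    sample: dict[str, float] | None = None,
    sample_volume_ul: float = 100.0,
    seed: int = 0,
    grid: emgrid.CoilGrid | None = None,
    drift: readout_mod.DriftModel | None = None,
    bead_mass_mg: float = 2.0,
) -> RunRecord:
    """Execute a program end-to-end and return the deterministic run record.

    ``sample`` gives species amounts (pg) loaded into the sample droplet.
    Identical (program, layout, params, seed) yield bit-identical records.
    """
    grid = grid or emgrid.build_default_grid()
    force_params = force_params or ForceParams()
    assay_params = assay_params or assay_mod.AssayParams()
    state = chip_mod.initial_state(layout, assay_params, bead_mass_mg=bead_mass_mg)
    if "sample" in state.droplets:
        drop = state.droplets["sample"]
        drop.volume_ul = sample_volume_ul
        drop.composition = dict(sample or {})
    executor = Executor(grid, state, force_params, assay_params, seed=seed, drift=drift)
    return executor.run(program)
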