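"""Electromagnetic coil-matrix model.

The actuation chip is a planar matrix of individually addressable four-turn
coils.  Energising a coil creates a localised magnetic field that attracts a
small permanent-magnet "motor" sitting above the board; stepping the active
coil along a path steps the motor cell by cell.  The default matrix holds
165 coils of 2 mm side on a 2.1 mm pitch (0.1 mm inter-coil gap), each driven
by 0.4 A DC, addressed through 8-port switch devices (21 devices for the
default matrix).

Only the addressing logic and the step-motion kinematics are modelled; the
spatial field profile is abstracted to "the motor relocates to the energised
cell".  Speed control is realised through the dwell time per step:
``v = pitch / dwell``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import ActuationFault, AddressingError, ConfigError, LayoutError

#: Default matrix dimensions: 11 x 15 = 165 coils.
DEFAULT_ROWS = 11
DEFAULT_COLS = 15
DEFAULT_SIDE_MM = 2.0
DEFAULT_GAP_MM = 0.1
DEFAULT_PITCH_MM = DEFAULT_SIDE_MM + DEFAULT_GAP_MM
DEFAULT_CURRENT_A = 0.4
DEFAULT_PORTS_PER_DEVICE = 8


@dataclass(frozen=True)
class CoilElement:
    """One addressable coil.

    ``center`` is the coil centre in mm on the board plane; centres lie on
    the pitch lattice ``(col * pitch, row * pitch)``.
    """

    id: int
    row: int
    col: int
    center: tuple[float, float]
    side: float = DEFAULT_SIDE_MM
    state: bool = False
    current: float = DEFAULT_CURRENT_A

    def __post_init__(self) -> None:
        if self.current < 0:
            raise ConfigError(f"coil {self.id}: drive current must be >= 0")
        if self.side <= 0:
            raise ConfigError(f"coil {self.id}: side length must be > 0")


@dataclass
class CoilGrid:
    """A lattice of coils plus the set of currently energised ids."""

    elements: list[CoilElement]
    pitch: float = DEFAULT_PITCH_MM
    shape: tuple[int, int] = (DEFAULT_ROWS, DEFAULT_COLS)
    active_set: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.elements]
        if len(ids) != len(set(ids)):
            raise LayoutError("coil ids must be unique")
        cells = [(e.row, e.col) for e in self.elements]
        if len(cells) != len(set(cells)):
            raise LayoutError("overlapping coil elements")
        for e in self.elements:
            expect = (e.col * self.pitch, e.row * self.pitch)
            if not math.isclose(e.center[0], expect[0], abs_tol=1e-9) or not math.isclose(
                e.center[1], expect[1], abs_tol=1e-9
            ):
                raise LayoutError(f"coil {e.id} centre {e.center} off the pitch lattice")
        self._by_id = {e.id: e for e in self.elements}
        self._by_cell = {(e.row, e.col): e for e in self.elements}

    def __len__(self) -> int:
        return len(self.elements)

    def coil(self, coil_id: int) -> CoilElement:
        try:
            return self._by_id[coil_id]
        except KeyError:
            raise AddressingError(f"unknown coil id {coil_id}") from None

    def coil_at(self, cell: tuple[int, int]) -> CoilElement | None:
        return self._by_cell.get(tuple(cell))

    def has_cell(self, cell: tuple[int, int]) -> bool:
        return tuple(cell) in self._by_cell

    def cell_center(self, cell: tuple[int, int]) -> tuple[float, float]:
        row, col = cell
        return (col * self.pitch, row * self.pitch)


@dataclass(frozen=True)
class AddressMap:
    """Switch-device fan-out: each coil id maps to one (device, port)."""

    ports_per_device: int
    assignments: dict[int, tuple[int, int]]

    @property
    def n_devices(self) -> int:
        return 1 + max(dev for dev, _ in self.assignments.values())


@dataclass(frozen=True)
class MotorState:
    """Magnet-motor pose: continuous position plus its lattice cell."""

    position: tuple[float, float]
    current_cell: tuple[int, int]
    time: float = 0.0


def build_default_grid(config: dict | None = None) -> CoilGrid:
    """Build a coil grid from a layout description.

    ``config`` may give ``rows``/``cols`` (lattice fill) or an explicit
    ``elements`` list of (row, col) cells; omitted keys fall back to the
    packaged default (11 x 15 = 165 coils, 2.1 mm pitch, 0.4 A).
    All coils start de-energised.
    """
    cfg = dict(config or {})
    pitch = float(cfg.get("pitch_mm", DEFAULT_PITCH_MM))
    side = float(cfg.get("side_mm", DEFAULT_SIDE_MM))
    current = float(cfg.get("current_a", DEFAULT_CURRENT_A))
    if pitch < side:
        raise LayoutError(f"pitch {pitch} mm smaller than coil side {side} mm")

    if "elements" in cfg:
        cells = [tuple(map(int, c)) for c in cfg["elements"]]
        if not cells:
            raise LayoutError("empty element list")
        rows = 1 + max(r for r, _ in cells)
        cols = 1 + max(c for _, c in cells)
    else:
        rows = int(cfg.get("rows", DEFAULT_ROWS))
        cols = int(cfg.get("cols", DEFAULT_COLS))
        if rows < 1 or cols < 1:
            raise LayoutError("grid must have at least one row and column")
        cells = [(r, c) for r in range(rows) for c in range(cols)]

    elements = [
        CoilElement(
            id=i,
            row=r,
            col=c,
            center=(c * pitch, r * pitch),
            side=side,
            current=current,
        )
        for i, (r, c) in enumerate(cells)
    ]
    return CoilGrid(elements=elements, pitch=pitch, shape=(rows, cols))


def build_address_map(
    n_coils: int, ports_per_device: int = DEFAULT_PORTS_PER_DEVICE
) -> AddressMap:
    """Assign coil ids to switch-device ports, filling devices in order.

    The device count is minimal: ``ceil(n_coils / ports_per_device)``
    (165 coils at 8 ports per device -> 21 devices).
    """
    if n_coils < 1:
        raise ConfigError("n_coils must be >= 1")
    if ports_per_device < 1:
        raise ConfigError("ports_per_device must be >= 1")
    assignments = {
        i: (i // ports_per_device, i % ports_per_device) for i in range(n_coils)
    }
    return AddressMap(ports_per_device=ports_per_device, assignments=assignments)


def activate(grid: CoilGrid, coil_id: int, exclusive: bool = True) -> CoilGrid:
    """Energise one coil (in place; the grid is returned for chaining).

    In the default single-active mode any previously energised coil is
    switched off first; ``exclusive=False`` allows multi-coil activation.
    """
    grid.coil(coil_id)  # raises AddressingError on unknown id
    if exclusive:
        grid.active_set.clear()
    grid.active_set.add(coil_id)
    return grid


def deactivate_all(grid: CoilGrid) -> CoilGrid:
    grid.active_set.clear()
    return grid


def _adjacent(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1


def step_motor(motor: MotorState, grid: CoilGrid, dwell: float) -> MotorState:
    """Advance the motor by one dwell interval.

    The motor relocates to the single energised coil's cell, which must be
    the current cell or a 4-neighbour of it — the step-motion mechanism
    cannot jump cells.  With no energised coil the motor holds position and
    time still advances.  An adjacent move at dwell ``tau`` implies a speed
    of ``pitch / tau``.
    """
    if dwell <= 0:
        raise ConfigError("dwell must be > 0")
    if not grid.active_set:
        return replace(motor, time=motor.time + dwell)
    if len(grid.active_set) != 1:
        raise ActuationFault(
            f"motor stepping requires exactly one energised coil, got {sorted(grid.active_set)}"
        )
    coil = grid.coil(next(iter(grid.active_set)))
    target = (coil.row, coil.col)
    if target != motor.current_cell and not _adjacent(target, motor.current_cell):
        raise ActuationFault(
            f"energised coil {coil.id} at {target} is not adjacent to motor cell "
            f"{motor.current_cell}; the motor cannot jump cells"
        )
    return MotorState(
        position=grid.cell_center(target),
        current_cell=target,
        time=motor.time + dwell,
    )


def motor_at(grid: CoilGrid, cell: tuple[int, int], time: float = 0.0) -> MotorState:
    """Place a motor at a lattice cell of the grid."""
    if not grid.has_cell(cell):
        raise AddressingError(f"cell {cell} not on grid")
    return MotorState(position=grid.cell_center(cell), current_cell=tuple(cell), time=time)
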