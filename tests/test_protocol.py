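"""Protocol DSL, path-finding, schedule compilation and execution."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beadops import emgrid, fixtures, protocol
from beadops.errors import ActuationFault, CompilationError, ConfigError, RoutingError
from beadops.mechanics import (
    ForceParams,
    OperationPoint,
    ZoneLabel,
    classify,
    droplet_speed_limit,
)


@pytest.fixture
def grid():
    return emgrid.build_default_grid()


class TestFindPath:
    def test_start_equals_goal(self, grid):
        assert protocol.find_path(grid, (2, 2), (2, 2)) == [(2, 2)]

    def test_straight_row(self):
        g = emgrid.build_default_grid({"rows": 1, "cols": 5})
        path = protocol.find_path(g, (0, 0), (0, 3))
        assert path == [(0, 0), (0, 1), (0, 2), (0, 3)]
        assert len(path) - 1 == 3

    def test_row_major_tie_break(self, grid):
        # of the two shortest L-paths to the diagonal cell, BFS with
        # row-major neighbour order goes right first, then down
        assert protocol.find_path(grid, (0, 0), (1, 1)) == [(0, 0), (0, 1), (1, 1)]

    def test_enclosed_goal_unroutable(self, grid):
        blocked = {(4, 5), (6, 5), (5, 4), (5, 6)}
        with pytest.raises(RoutingError):
            protocol.find_path(grid, (0, 0), (5, 5), blocked)

    def test_blocked_goal_rejected(self, grid):
        with pytest.raises(RoutingError):
            protocol.find_path(grid, (0, 0), (1, 1), {(1, 1)})

    def test_detour_around_obstacle(self, grid):
        path = protocol.find_path(grid, (5, 0), (5, 4), {(5, 2)})
        assert path[0] == (5, 0) and path[-1] == (5, 4)
        assert (5, 2) not in path
        assert len(path) - 1 == 6  # manhattan 4 + 2-cell detour

    @given(
        st.tuples(st.integers(0, 10), st.integers(0, 14)),
        st.tuples(st.integers(0, 10), st.integers(0, 14)),
    )
    def test_path_length_equals_manhattan_when_unobstructed(self, start, goal):
        g = emgrid.build_default_grid()
        path = protocol.find_path(g, start, goal)
        manhattan = abs(start[0] - goal[0]) + abs(start[1] - goal[1])
        assert len(path) - 1 == manhattan
        for a, b in zip(path, path[1:]):
            assert abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1


class TestSpeedSelection:
    def test_droplet_speed_below_boundary(self):
        p = ForceParams()
        mass = 1.1  # just above m* = 1
        v = protocol.select_droplet_speed(mass, p)
        assert v < droplet_speed_limit(mass, p)
        assert classify(OperationPoint(mass, v), p) is ZoneLabel.DROPLET_OP

    def test_bead_speed_inside_zone(self):
        p = ForceParams()
        v = protocol.select_bead_speed(2.0, p)
        assert classify(OperationPoint(2.0, v), p) is ZoneLabel.BEAD_OP

    def test_subcritical_mass_extraction_infeasible(self):
        with pytest.raises(CompilationError, match="critical mass"):
            protocol.select_bead_speed(0.5, ForceParams())

    def test_geometric_midpoint_maximises_margin(self):
        p = ForceParams()
        v = protocol.select_droplet_speed(4.0, p, floor=0.1)
        hi = min(droplet_speed_limit(4.0, p), protocol.DEFAULT_SPEED_CAP)
        assert v == pytest.approx(np.sqrt(0.1 * hi))


class TestDefaultProgram:
    def test_three_washes_between_labelling_and_delivery(self, default_program):
        cmds = default_program.commands
        label_mix = max(
            i for i, c in enumerate(cmds) if c.verb == "MIX" and c.args.get("droplet") == "label"
        )
        delivery = next(
            i
            for i, c in enumerate(cmds)
            if c.verb == "INSERT_BEADS" and c.args.get("droplet") == "chamber"
        )
        washes = [
            c
            for c in cmds[label_mix:delivery]
            if c.verb == "MOVE_BEADS" and c.args["dest"].startswith("wash")
        ]
        assert len(washes) == 3

    def test_exactly_one_merge(self, default_program):
        assert sum(c.verb == "MERGE" for c in default_program.commands) == 1

    def test_ends_with_bead_removal_then_read(self, default_program):
        verbs = [c.verb for c in default_program.commands]
        assert verbs[-1] == "READ"
        assert verbs[-3:-1] == ["MOVE_BEADS", "MOVE_BEADS"]

    def test_layout_without_washes_rejected(self, default_layout):
        layout = fixtures.default_layout()
        for w in list(layout.reservoirs):
            if w.startswith("wash"):
                del layout.reservoirs[w]
        with pytest.raises(CompilationError):
            protocol.default_ime_program(layout)

    def test_dsl_roundtrip(self, default_program):
        text = protocol.format_program(default_program)
        parsed = protocol.parse_program(text, name=default_program.name)
        assert [c.verb for c in parsed.commands] == [c.verb for c in default_program.commands]
        assert [c.args for c in parsed.commands] == [c.args for c in default_program.commands]

    def test_unknown_verb_rejected(self):
        with pytest.raises(ConfigError):
            protocol.parse_program("TELEPORT droplet=sample dest=0,0")

    def test_missing_argument_rejected(self):
        with pytest.raises(ConfigError):
            protocol.parse_program("MIX droplet=sample")  # no duration


class TestCompile:
    def test_empty_program_empty_schedule(self, default_layout):
        sched = protocol.compile(protocol.Program([], name="empty"), default_layout, ForceParams())
        assert sched.events == []
        assert sched.runtime_s == 0.0

    def test_schedule_is_single_active_and_contiguous(self, default_layout, default_program):
        grid = emgrid.build_default_grid()
        sched = protocol.compile(default_program, default_layout, ForceParams(), grid=grid)
        assert sched.events, "default program should produce coil activity"
        active = set()
        last_cell = None
        for ev in sched.events:
            if ev.action == "on":
                assert not active, "two coils energised at once"
                active.add(ev.coil_id)
                coil = grid.coil(ev.coil_id)
                cell = (coil.row, coil.col)
                if last_cell is not None:
                    dist = abs(cell[0] - last_cell[0]) + abs(cell[1] - last_cell[1])
                    assert dist <= 1, "consecutive energised coils must be adjacent"
                last_cell = cell
            else:
                active.discard(ev.coil_id)
        times = [ev.time_s for ev in sched.events]
        assert times == sorted(times)

    def test_compiled_speeds_respect_zones(self, default_layout, default_program):
        # re-derive the zone for every motion segment from the dwell times
        grid = emgrid.build_default_grid()
        p = ForceParams()
        record = protocol.execute(default_program, default_layout, p, grid=grid, seed=0)
        moves = [e for e in record.events if e["event"] in ("move_droplet", "extract_beads")]
        assert moves
        for e in moves:
            if e["event"] == "move_droplet":
                mass = 2.0  # transport beads ride inside the stop droplet
                assert classify(OperationPoint(mass, e["speed"]), p) is ZoneLabel.DROPLET_OP
            else:
                assert classify(OperationPoint(2.0, e["speed"]), p) is ZoneLabel.BEAD_OP

    def test_infeasible_bead_mass_fails_compilation(self, default_layout, default_program):
        with pytest.raises(CompilationError):
            protocol.execute(
                default_program, default_layout, ForceParams(), seed=0, bead_mass_mg=0.5
            )


class TestExecute:
    SAMPLE = {"exo_ab42": 2.0, "cd63_exo": 50.0, "free_ab42": 1.0}

    def test_default_run_completes_all_steps(self, default_layout, default_program):
        record = protocol.execute(
            default_program, default_layout, sample=self.SAMPLE, seed=11
        )
        events = [e["event"] for e in record.events]
        assert "mix" in events
        assert "extract_beads" in events
        assert "merge" in events
        assert "stop_reaction" in events
        assert events[-1] == "read"
        assert record.readout is not None
        assert record.signal is not None and record.signal > 0

    def test_read_only_program(self, default_layout):
        record = protocol.execute(
            protocol.Program([protocol.Command("READ")], name="read-only"), default_layout
        )
        motion = [e for e in record.events if e["event"] in ("move_droplet", "extract_beads")]
        assert motion == []
        assert record.readout is not None

    def test_replay_is_bit_identical(self, default_layout, default_program):
        a = protocol.execute(default_program, default_layout, sample=self.SAMPLE, seed=42)
        b = protocol.execute(default_program, default_layout, sample=self.SAMPLE, seed=42)
        assert a.to_json() == b.to_json()

    def test_different_seed_changes_noise(self, default_layout, default_program):
        a = protocol.execute(default_program, default_layout, sample=self.SAMPLE, seed=1)
        b = protocol.execute(default_program, default_layout, sample=self.SAMPLE, seed=2)
        assert a.readout.i_readout != b.readout.i_readout

    def test_runtime_zone_violation_names_step(self, default_layout):
        # forcing a droplet-zone speed onto an extraction faults at runtime
        prog = protocol.Program(
            [
                protocol.Command(
                    "MOVE_BEADS",
                    {"cluster": "ime_beads", "src": "beads", "dest": "sample", "speed": "0.2"},
                )
            ],
            name="bad",
        )
        with pytest.raises(ActuationFault, match="step 0"):
            protocol.execute(prog, default_layout, seed=0)
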