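"""Biochip fluidics: conservation, carryover, merging, mixing."""

import numpy as np
import pytest

from beadops import assay, biochip, fixtures
from beadops.errors import ActuationFault, ConfigError, StateError
from beadops.mechanics import ForceParams

PARAMS = ForceParams()  # unit coefficients, m* = 1 mg; default clusters are 2 mg

DROPLET_SPEED = 0.3  # inside droplet-operation for 2 mg beads (limit 1.26)
BEAD_SPEED = 5.0  # inside bead-operation for 2 mg beads (threshold 1.26)


@pytest.fixture
def state(default_layout):
    st = biochip.initial_state(default_layout)
    sample = st.droplets["sample"]
    sample.composition = {"exo_ab42": 10.0, "free_ab42": 4.0, "bsa": 2.0}
    return st


class TestDefaultLayout:
    def test_reagent_inventory(self, default_layout):
        vols = {n: r.volume_ul for n, r in default_layout.reservoirs.items()}
        assert vols["beads"] == 8.0
        assert [vols[w] for w in default_layout.wash_names] == [50.0] * 4
        assert vols["label"] == vols["chamber"] == vols["stop"] == 50.0
        reagents = {n: v for n, v in vols.items() if n != "sample"}
        assert len(reagents) == 8
        assert sum(reagents.values()) == pytest.approx(358.0)

    def test_stop_droplet_ships_transport_beads(self, state):
        assert state.droplets["stop"].beads_present
        assert state.clusters["stop_beads"].carrier == "stop"

    def test_overlapping_reservoirs_rejected(self):
        res = {
            "a": biochip.Reservoir("a", (0, 0), 10.0),
            "b": biochip.Reservoir("b", (0, 0), 10.0),
        }
        with pytest.raises(Exception):
            biochip.ChipLayout(reservoirs=res, detection_chamber=(1, 1))


class TestMoveDroplet:
    def test_compliant_move_conserves_volume(self, state):
        before = state.droplets["stop"].volume_ul
        biochip.move_droplet(state, "stop", (6, 11), DROPLET_SPEED, PARAMS)
        assert state.droplets["stop"].cell == (6, 11)
        assert state.droplets["stop"].volume_ul == before

    def test_overspeed_names_computed_zone(self, state):
        with pytest.raises(ActuationFault, match="BEAD_OP"):
            biochip.move_droplet(state, "stop", (6, 11), BEAD_SPEED, PARAMS)

    def test_beadless_droplet_cannot_be_towed(self, state):
        with pytest.raises(ActuationFault, match="NO_ENGAGEMENT"):
            biochip.move_droplet(state, "wash1", (2, 3), DROPLET_SPEED, PARAMS)

    def test_zero_distance_move_is_identity(self, state):
        cell = state.droplets["stop"].cell
        before = state.copy()
        biochip.move_droplet(state, "stop", cell, DROPLET_SPEED, PARAMS)
        assert state.droplets["stop"].cell == cell
        assert state.species_totals() == before.species_totals()


class TestExtractInsert:
    def test_extraction_moves_cluster_to_oil(self, state):
        state.clusters["ime_beads"].carrier = "sample"
        state.droplets["sample"].beads_present = True
        vol = state.droplets["sample"].volume_ul
        biochip.extract_beads(state, "sample", BEAD_SPEED, PARAMS)
        assert state.clusters["ime_beads"].carrier == biochip.OIL
        assert not state.droplets["sample"].beads_present
        assert state.droplets["sample"].volume_ul == vol

    def test_extraction_in_droplet_zone_faults(self, state):
        state.clusters["ime_beads"].carrier = "sample"
        with pytest.raises(ActuationFault, match="DROPLET_OP"):
            biochip.extract_beads(state, "sample", DROPLET_SPEED, PARAMS)

    def test_carryover_arithmetic(self, default_layout):
        layout = fixtures.default_layout()
        layout.carryover = 0.1
        st = biochip.initial_state(layout)
        st.droplets["sample"].composition = {"free_ab42": 40.0}
        st.clusters["ime_beads"].carrier = "sample"
        biochip.extract_beads(st, "sample", BEAD_SPEED, PARAMS)
        assert st.clusters["ime_beads"].carried_free["free_ab42"] == pytest.approx(4.0)
        assert st.droplets["sample"].composition["free_ab42"] == pytest.approx(36.0)

    def test_zero_carryover_roundtrip_is_identity(self, default_layout):
        layout = fixtures.default_layout()
        layout.carryover = 0.0
        st = biochip.initial_state(layout)
        st.droplets["sample"].composition = {"free_ab42": 40.0, "bsa": 1.0}
        st.clusters["ime_beads"].carrier = "sample"
        before = {k: dict(d.composition) for k, d in st.droplets.items()}
        biochip.extract_beads(st, "sample", BEAD_SPEED, PARAMS)
        assert st.clusters["ime_beads"].carried_free == {}
        biochip.insert_beads(st, "ime_beads", "sample")
        after = {k: dict(d.composition) for k, d in st.droplets.items()}
        assert after == before

    def test_three_wash_residual_is_carryover_cubed(self, default_layout):
        f = 0.05
        layout = fixtures.default_layout()
        layout.carryover = f
        st = biochip.initial_state(layout)
        contaminant = 100.0
        st.droplets["label"].composition = {"hrp_ab": contaminant}
        st.clusters["ime_beads"].carrier = "label"
        src = "label"
        for wash in ("wash2", "wash3", "wash4"):
            biochip.extract_beads(st, src, BEAD_SPEED, PARAMS)
            biochip.insert_beads(st, "ime_beads", wash)
            src = wash
        biochip.extract_beads(st, src, BEAD_SPEED, PARAMS)
        carried = st.clusters["ime_beads"].carried_free["hrp_ab"]
        # each wash attenuates the carried contaminant by f: the amount
        # leaving wash 3 is f^3 times the amount that left the label droplet
        assert carried == pytest.approx(f**3 * (f * contaminant), rel=1e-9)

    def test_double_insert_rejected(self, state):
        state.clusters["ime_beads"].carrier = "sample"
        with pytest.raises(StateError):
            biochip.insert_beads(state, "ime_beads", "wash1")


class TestMerge:
    def test_volumes_and_amounts_add(self, state):
        biochip.move_droplet(state, "stop", (6, 11), DROPLET_SPEED, PARAMS)
        biochip.merge(state, "chamber", "stop")
        chamber = state.droplets["chamber"]
        assert chamber.volume_ul == pytest.approx(100.0)
        assert chamber.composition["stop"] == pytest.approx(50000.0)
        assert "stop" not in state.droplets

    def test_dilution_by_volume_ratio(self, state):
        chamber = state.droplets["chamber"]
        conc_before = chamber.concentration_pg_ml("tmb")
        biochip.move_droplet(state, "stop", (6, 11), DROPLET_SPEED, PARAMS)
        state.droplets["stop"].composition = {}
        biochip.merge(state, "chamber", "stop")
        assert state.droplets["chamber"].concentration_pg_ml("tmb") == pytest.approx(
            conc_before / 2.0
        )

    def test_merge_conserves_species(self, state):
        totals = state.species_totals()
        biochip.move_droplet(state, "stop", (6, 11), DROPLET_SPEED, PARAMS)
        biochip.merge(state, "chamber", "stop")
        after = state.species_totals()
        for sp, amt in totals.items():
            assert after[sp] == pytest.approx(amt, rel=1e-12)

    def test_self_merge_rejected(self, state):
        with pytest.raises(ConfigError):
            biochip.merge(state, "chamber", "chamber")

    def test_distant_droplets_cannot_merge(self, state):
        with pytest.raises(StateError):
            biochip.merge(state, "chamber", "sample")

    def test_merged_droplet_inherits_beads(self, state):
        biochip.move_droplet(state, "stop", (6, 11), DROPLET_SPEED, PARAMS)
        biochip.merge(state, "chamber", "stop")
        assert state.droplets["chamber"].beads_present
        assert state.clusters["stop_beads"].carrier == "chamber"


class TestMix:
    def test_mix_without_beads_rejected(self, state):
        with pytest.raises(StateError):
            biochip.mix(state, "wash1", 5.0, assay.AssayParams())

    def test_zero_duration_no_progress(self, state):
        state.clusters["ime_beads"].carrier = "sample"
        biochip.mix(state, "sample", 0.0, assay.AssayParams())
        assert state.clusters["ime_beads"].surface.total_captured == 0.0

    def test_mix_additivity(self, default_layout):
        ap = assay.AssayParams()

        def run(durations):
            st = biochip.initial_state(fixtures.default_layout(), ap)
            st.droplets["sample"].composition = {"exo_ab42": 10.0, "cd63_exo": 30.0}
            st.clusters["ime_beads"].carrier = "sample"
            for d in durations:
                biochip.mix(st, "sample", d, ap)
            return st.clusters["ime_beads"].surface

    # two mixes of t/2 produce the same binding state as one mix of t
        one = run([20.0])
        two = run([10.0, 10.0])
        assert two.total_captured == pytest.approx(one.total_captured, abs=1e-9)
        assert two.bound_hrp == pytest.approx(one.bound_hrp, abs=1e-9)

    def test_mix_without_target_leaves_surface_unchanged(self, state):
        state.clusters["ime_beads"].carrier = "wash1"
        state.droplets["wash1"].beads_present = True
        biochip.mix(state, "wash1", 10.0, assay.AssayParams())
        assert state.clusters["ime_beads"].surface.total_captured == 0.0


class TestConservationSuite:
    def test_random_event_sequences_conserve(self, default_layout, rng):
        # volumes + species totals invariant across random reaction-free events
        for trial in range(50):
            st = biochip.initial_state(fixtures.default_layout())
            st.droplets["sample"].composition = {
                "exo_ab42": float(rng.uniform(1, 20)),
                "free_ab42": float(rng.uniform(1, 20)),
            }
            st.clusters["ime_beads"].carrier = "sample"
            st.droplets["sample"].beads_present = True
            totals = st.species_totals()
            volume = sum(d.volume_ul for d in st.droplets.values())
            droplet_names = [n for n in st.droplets if n != "stop"]
            for _ in range(10):
                ev = rng.integers(0, 2)
                cluster = st.clusters["ime_beads"]
                if ev == 0 and cluster.carrier != biochip.OIL:
                    biochip.extract_beads(st, cluster.carrier, BEAD_SPEED, PARAMS)
                elif ev == 1 and cluster.carrier == biochip.OIL:
                    dest = droplet_names[rng.integers(len(droplet_names))]
                    biochip.insert_beads(st, "ime_beads", dest)
            after = st.species_totals()
            assert set(after) == set(totals)
            for sp in totals:
                assert after[sp] == pytest.approx(totals[sp], rel=1e-12)
            assert sum(d.volume_ul for d in st.droplets.values()) == pytest.approx(
                volume, rel=1e-12
            )
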