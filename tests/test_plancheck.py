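import numpy as np
import pytest

from gantryclear.fixtures import SITE_PRESETS, make_phantom, _build_context, _machine_for
from gantryclear.kinematics import BeamConfig
from gantryclear.machine import attach_range_shifter
from gantryclear.plancheck import (
    ConfigurationError,
    Thresholds,
    check_beam,
    check_kv_obstruction,
    check_plan,
    sweep_feasibility,
)


def gi_ctx(beams):
    return _build_context("gi", beams, SITE_PRESETS["gi"].jct_mean)


class TestThresholds:
    def test_defaults_encode_the_buffer_margin(self):
        t = Thresholds()
        assert t.warn_below == 30.0
        assert t.fail_at == 0.0

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            Thresholds(fail_at=40.0, warn_below=30.0)


class TestCheckBeam:
    def test_staged_clearances_map_to_statuses(self, staged_triple):
        assert staged_triple[50.0].expected_outcome == "clear"
        assert staged_triple[25.0].expected_outcome == "warn"
        assert staged_triple[0.0].expected_outcome == "collide"
        for sc in staged_triple.values():
            r = check_beam(sc.machine, sc.structures, sc.ctx, sc.ctx.beams[0])
            expect = {"clear": "pass", "warn": "warn", "collide": "fail"}[sc.expected_outcome]
            assert r.status == expect

    def test_status_monotone_in_clearance(self, staged_triple):
        severity = {"pass": 0, "warn": 1, "fail": 2}
        results = [
            check_beam(sc.machine, sc.structures, sc.ctx, sc.ctx.beams[0])
            for sc in (staged_triple[50.0], staged_triple[25.0], staged_triple[0.0])
        ]
        clearances = [r.min_clearance for r in results]
        assert clearances == sorted(clearances, reverse=True)
        sev = [severity[r.status] for r in results]
        assert sev == sorted(sev)

    def test_low_jct_posterior_oblique_hits_the_robotic_arm(self):
        """Posterior beams with a pelvic-range junction value endanger the arm."""
        structures = make_phantom("gi", 1)
        machine = _machine_for("gi")
        beam = BeamConfig("post", 160.0, 180.0, (0.0, -80.0, 0.0))
        r = check_beam(machine, structures, gi_ctx((beam,)), beam)
        assert r.worst_pair.type.name == "type3_gantry_vs_pps_arm"
        assert r.worst_pair.component_b.startswith("pps_")

    def test_disallowed_gantry_angle_is_a_status_not_an_exception(self, gu_setup):
        machine, phantom, ctx, _ = gu_setup
        bad = BeamConfig("bad", 270.0, 0.0, (0.0, -60.0, 0.0))
        ctx_bad = _build_context("gu", (bad,), ctx.jct_cm)
        r = check_beam(machine, phantom, ctx_bad, bad)
        assert r.status == "invalid_gantry_angle"
        assert r.min_clearance is None

    def test_ers_required_but_absent_is_a_configuration_error(self, gu_setup):
        machine, phantom, ctx, _ = gu_setup
        assert not machine.ers_attached
        beam = BeamConfig("e", 50.0, 0.0, (0.0, -60.0, 0.0), ers_required=True)
        with pytest.raises(ConfigurationError, match="range shifter"):
            check_beam(machine, phantom, _build_context("gu", (beam,), ctx.jct_cm), beam)

    def test_deterministic_for_fixed_inputs(self, gu_setup):
        machine, phantom, ctx, beam = gu_setup
        r1 = check_beam(machine, phantom, ctx, beam)
        r2 = check_beam(machine, phantom, ctx, beam)
        assert r1.to_dict() == r2.to_dict()

    def test_attaching_the_range_shifter_never_increases_clearance(self, gu_setup):
        machine, phantom, ctx, beam = gu_setup
        with_ers = attach_range_shifter(machine)
        d_without = check_beam(machine, phantom, ctx, beam).min_clearance
        d_with = check_beam(with_ers, phantom, ctx, beam).min_clearance
        assert d_with <= d_without + 1e-9


class TestCheckPlan:
    def test_warn_beam_lands_on_the_angle_check_list(self):
        structures = make_phantom("gi", 1)
        machine = _machine_for("gi")
        ok = BeamConfig("ok", 150.0, 0.0, (0.0, 40.0, 0.0))
        tight = BeamConfig("tight", 150.0, 0.0, (0.0, -60.0, 0.0))
        report = check_plan(machine, structures, gi_ctx((ok, tight)))
        by_id = {r.beam_id: r.status for r in report.beam_results}
        assert by_id["ok"] == "pass"
        assert by_id["tight"] == "warn"
        assert report.angle_check_beams == ("tight",)
        assert report.verdict == "warn"

    def test_one_failing_beam_dominates_the_verdict(self):
        structures = make_phantom("gi", 1)
        machine = _machine_for("gi")
        ok = BeamConfig("ok", 150.0, 0.0, (0.0, 40.0, 0.0))
        bad = BeamConfig("bad", 165.0, 180.0, (0.0, -115.0, 0.0))
        report = check_plan(machine, structures, gi_ctx((ok, bad)))
        assert report.verdict == "fail"

    def test_per_beam_errors_do_not_abort_the_remaining_beams(self):
        structures = make_phantom("gi", 1)
        machine = _machine_for("gi")  # no ERS for GI
        needs_ers = BeamConfig("ers", 150.0, 0.0, (0.0, 40.0, 0.0), ers_required=True)
        ok = BeamConfig("ok", 150.0, 0.0, (0.0, 40.0, 0.0))
        report = check_plan(machine, structures, gi_ctx((needs_ers, ok)))
        assert len(report.errors) == 1 and report.errors[0][0] == "ers"
        assert [r.beam_id for r in report.beam_results] == ["ok"]

    def test_report_json_round_trips(self, gu_setup):
        import json

        machine, phantom, ctx, _ = gu_setup
        report = check_plan(machine, phantom, ctx)
        text = report.to_json()
        assert json.dumps(json.loads(text), indent=2, sort_keys=True) == text


class TestSweep:
    def test_grid_excludes_disallowed_gantry_angles(self, gu_setup):
        machine, phantom, ctx, _ = gu_setup
        fmap = sweep_feasibility(
            machine, phantom, ctx, couch_grid=[0.0], gantry_grid=[0.0, 90.0, 200.0, 270.0, 355.0]
        )
        assert set(fmap.gantry_grid) == {0.0, 90.0, 355.0}
        assert all(g in (0.0, 90.0, 355.0) for g, _ in fmap.cells)

    def test_refining_the_grid_preserves_existing_cells(self, gu_setup):
        machine, phantom, ctx, _ = gu_setup
        coarse = sweep_feasibility(machine, phantom, ctx, [0.0], [0.0, 30.0])
        fine = sweep_feasibility(machine, phantom, ctx, [0.0], [0.0, 15.0, 30.0])
        for key, cell in coarse.cells.items():
            assert fine.cells[key] == cell

    def test_distant_phantom_clears_the_anterior_arc(self, gu_setup):
        from gantryclear.patient import transform_structures
        from gantryclear.transforms import RigidTransform

        machine, phantom, ctx, _ = gu_setup
        far = transform_structures(phantom, RigidTransform.from_translation([0.0, -5000.0, 0.0]))
        fmap = sweep_feasibility(machine, far, ctx, [0.0], [0.0, 15.0, 30.0, 45.0, 60.0])
        assert all(c["status"] == "pass" for c in fmap.cells.values())

    def test_high_jct_site_laterals_are_the_hazardous_arc(self):
        """Brain (high JCT): T=270 lateral/oblique beams collide more than
        near-vertical ones (couch tip and helmet near the snout)."""
        structures = make_phantom("brain", 1)
        machine = _machine_for("brain")
        beam = BeamConfig("s", 0.0, 0.0, (0.0, -10.0, 0.0))
        ctx = _build_context("brain", (beam,), SITE_PRESETS["brain"].jct_mean)
        fmap = sweep_feasibility(
            machine, structures, ctx, [270.0], [0.0, 10.0, 20.0, 30.0, 80.0, 90.0, 100.0, 110.0]
        )
        vertical = [fmap.cells[(g, 270.0)]["status"] for g in (0.0, 10.0, 20.0, 30.0)]
        lateral = [fmap.cells[(g, 270.0)]["status"] for g in (80.0, 90.0, 100.0, 110.0)]
        n_vert = sum(1 for s in vertical if s != "pass")
        n_lat = sum(1 for s in lateral if s != "pass")
        assert n_lat > n_vert

    def test_low_jct_site_posteriors_are_the_hazardous_arc(self):
        """Pelvis (low JCT): posterior-oblique beams clear less than anterior
        ones, with the robotic arm as the nearest hazard."""
        structures = make_phantom("gi", 1)
        machine = _machine_for("gi")
        beam = BeamConfig("s", 0.0, 0.0, (0.0, -60.0, 0.0))
        ctx = _build_context("gi", (beam,), SITE_PRESETS["gi"].jct_mean)
        fmap = sweep_feasibility(
            machine, structures, ctx, [180.0], [0.0, 15.0, 30.0, 150.0, 165.0, 180.0]
        )
        anterior = min(
            fmap.cells[(g, 180.0)]["min_clearance_mm"] for g in (0.0, 15.0, 30.0)
        )
        posterior = min(
            fmap.cells[(g, 180.0)]["min_clearance_mm"] for g in (150.0, 165.0, 180.0)
        )
        assert posterior < anterior
        post_beam = BeamConfig("p", 165.0, 180.0, (0.0, -60.0, 0.0))
        post_ctx = _build_context("gi", (post_beam,), SITE_PRESETS["gi"].jct_mean)
        worst = check_beam(machine, structures, post_ctx, post_beam)
        assert worst.worst_pair.type.name in (
            "type3_gantry_vs_pps_arm", "type1_gantry_vs_couch"
        )

    def test_csv_export_contains_every_cell(self, gu_setup):
        machine, phantom, ctx, _ = gu_setup
        fmap = sweep_feasibility(machine, phantom, ctx, [0.0], [0.0, 90.0])
        csv = fmap.to_csv()
        assert csv.splitlines()[0] == "gantry_deg,couch_deg,status,clearance_mm"
        assert len(csv.strip().splitlines()) == 1 + len(fmap.cells)


class TestKvObstruction:
    def test_oblique_gantry_blocks_a_cone(self, gu_setup):
        machine, phantom, ctx, _ = gu_setup
        beam = BeamConfig("b", 40.0, 0.0, (0.0, -60.0, 0.0))
        hits = check_kv_obstruction(machine, _build_context("gu", (beam,), ctx.jct_cm), beam)
        assert any(comp == "gantry_head" for _, comp in hits)

    def test_parked_gantry_leaves_cones_clear(self, gu_setup):
        machine, phantom, ctx, _ = gu_setup
        beam = BeamConfig("b", 0.0, 0.0, (0.0, -60.0, 0.0))
        assert check_kv_obstruction(machine, _build_context("gu", (beam,), ctx.jct_cm), beam) == []

    def test_obstruction_never_alters_the_plan_verdict(self, gu_setup):
        machine, phantom, ctx, _ = gu_setup
        plain = check_plan(machine, phantom, ctx, with_kv=False)
        with_kv = check_plan(machine, phantom, ctx, with_kv=True)
        assert plain.verdict == with_kv.verdict
        assert [r.status for r in plain.beam_results] == [
            r.status for r in with_kv.beam_results
        ]
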