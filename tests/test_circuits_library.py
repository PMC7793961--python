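"""Behavior of the prebuilt circuits under their canonical scenarios."""

import pytest

from conftest import check_invariants, vehicle_run
from mesovm.circuit_lang import compile_circuit
from mesovm.circuits_library import (DetectorMode, build_classical_conditioning,
                                     build_deterministic_detector,
                                     build_operant_conditioning,
                                     build_random_detector,
                                     build_transmission)
from mesovm.plasticity import Link, LinkTable
from mesovm.terms import Term, parse_term
from mesovm.vm_core import ModelState, ScriptedEnvironment, run


def scripted_run(circuit, schedule, *, table=None):
    model = ModelState.from_circuit(circuit, links=table)
    env = ScriptedEnvironment({cyc: [parse_term(s) for s in stims]
                               for cyc, stims in schedule.items()})
    trace = run(model, env)
    check_invariants(model)
    return trace


class TestTransmission:
    def test_one_stimulus_fires_q_once(self):
        trace = scripted_run(build_transmission(), {0: ["p"]})
        assert [(e.thread, e.stimulus) for e in trace] == [("q", "excite")]

    def test_no_stimulus_empty_trace(self):
        assert len(scripted_run(build_transmission(), {})) == 0

    def test_zero_weight_gates_q_off(self):
        c = build_transmission()
        c.links = [Link(Term("p"), Term("q"), weight=0.0)]
        trace = scripted_run(c, {0: ["p"]})
        assert all(e.stimulus != "excite" for e in trace)


class TestClassicalConditioning:
    def test_us_alone_drives_unconditioned_reflex(self, classical_circuit):
        trace = scripted_run(classical_circuit, {0: ["sense(us)"]})
        assert ("motor(us)", "excite") in [(e.thread, e.stimulus)
                                           for e in trace]

    def test_cs_alone_before_pairing_gives_no_enhanced_reflex(
            self, classical_circuit):
        trace = scripted_run(classical_circuit, {0: ["sense(cs)"]})
        assert ("motor(cs)", "excite") not in [(e.thread, e.stimulus)
                                               for e in trace]

    def test_one_pairing_then_cs_alone_triggers_reflex(self,
                                                       classical_circuit):
        table = LinkTable(classical_circuit.links)
        # cs slightly precedes us within one capture
        scripted_run(classical_circuit, {0: ["sense(cs)", "sense(us)"]},
                     table=table)
        trace = scripted_run(classical_circuit, {0: ["sense(cs)"]},
                             table=table)
        assert ("motor(cs)", "excite") in [(e.thread, e.stimulus)
                                           for e in trace]


class TestOperantConditioning:
    def test_positive_stimulus_opens_accept_and_closes_learn(
            self, operant_circuit):
        table = LinkTable(operant_circuit.links)
        scripted_run(operant_circuit,
                     {0: ["sense(item)"], 3: ["positive"]}, table=table)
        accept, ia = table.resolve(parse_term("sense(item)"),
                                   parse_term("accept(item)"))
        learn, il = table.resolve(parse_term("sense(item)"),
                                  parse_term("learn(item)"))
        assert table.is_open(accept, ia)
        assert not table.is_open(learn, il)
        # a repeated sense now routes to accept, with no learning event
        trace = scripted_run(operant_circuit, {0: ["sense(item)"]},
                             table=table)
        assert ("accept(item)", "excite") in [(e.thread, e.stimulus)
                                              for e in trace]
        assert not [e for e in trace if e.thread.startswith("learn")
                    and e.stimulus in ("positive", "negative")]

    def test_negative_stimulus_opens_reject_instead(self, operant_circuit):
        table = LinkTable(operant_circuit.links)
        scripted_run(operant_circuit,
                     {0: ["sense(item)"], 3: ["negative"]}, table=table)
        reject, ir = table.resolve(parse_term("sense(item)"),
                                   parse_term("reject(item)"))
        accept, ia = table.resolve(parse_term("sense(item)"),
                                   parse_term("accept(item)"))
        assert table.is_open(reject, ir)
        assert not table.is_open(accept, ia)

    def test_no_outcome_stimulus_leaves_weights_unchanged(self,
                                                          operant_circuit):
        table = LinkTable(operant_circuit.links)
        before = table.snapshot()
        scripted_run(operant_circuit, {0: ["sense(item)"]}, table=table)
        assert table.snapshot() == before


class TestRandomDetector:
    def test_correct_direction_synchronizes_then_clears(self):
        trace, world, _ = vehicle_run(build_random_detector(),
                                      fire="right(3)", choice="forward")
        assert world.outcome == "cleared"
        at4 = [(e.thread, e.stimulus) for e in trace.at_seq(4)]
        assert ("detect(right(3))", "excite") in at4
        assert ("move(forward)", "excite") in at4
        assert ("detect(right(3))", "clear") in at4  # clear is simultaneous
        assert sum(1 for e in trace if e.stimulus == "clear") == 1

    def test_wrong_direction_reaches_track_limit_and_stops(self):
        trace, world, _ = vehicle_run(build_random_detector(),
                                      fire="right(3)", choice="backward")
        assert world.outcome == "missed"
        assert world.vehicle.moves == 8  # 7 coordinates plus the overrun step
        move_inhibits = [e.seq for e in trace.of_thread("move(")
                         if e.stimulus == "inhibit"]
        assert move_inhibits == [9]

    def test_gear_choice_is_calibrated_to_a_fair_coin(self,
                                                      random_detector_code):
        # binomial oracle: n=2000 at p=0.5 -> the forward fraction falls
        # within 50% +/- 3% (about 2.7 sigma)
        n, forward = 2000, 0
        for i in range(n):
            model = ModelState(random_detector_code, links=LinkTable([]),
                               seed=50_000 + i)
            from mesovm.vehicle_world import Track, World
            world = World(Track(7, parse_term("right(3)"), "right"))
            trace = run(model, world)
            fetch = next(e.stimulus for e in trace
                         if e.stimulus.startswith("fetch"))
            forward += fetch == "fetch(forward)"
        assert 0.47 <= forward / n <= 0.53

    def test_non_plastic_circuit_never_changes_weights(self):
        circuit = build_random_detector()
        table = LinkTable(circuit.links)
        before = table.snapshot()
        for choice in ("forward", "backward"):
            vehicle_run(circuit, fire="right(3)", choice=choice, table=table)
        assert table.snapshot() == before


class TestDeterministicDetectorInstantiated:
    def test_successful_episode_opens_recall_and_closes_learn(
            self, instantiated_detector):
        code, table = instantiated_detector
        trace, world, _ = vehicle_run(code, fire="right(3)",
                                      choice="forward", table=table)
        assert world.outcome == "cleared"
        recall, ir = table.resolve(parse_term("sense(right(3))"),
                                   parse_term("recall(forward)"))
        learn, il = table.resolve(parse_term("sense(right(3))"),
                                  parse_term("learn(right)"))
        assert table.is_open(recall, ir)
        assert not table.is_open(learn, il)

    def test_replay_is_deterministic_with_repeated_inhibit_at_one(
            self, instantiated_detector):
        code, table = instantiated_detector
        vehicle_run(code, fire="right(3)", choice="forward", table=table)
        trace, world, _ = vehicle_run(code, fire="right(3)", table=table)
        assert world.outcome == "cleared"
        assert trace.fetch_count() == 0  # deduction routed through recall
        blocked = [e for e in trace
                   if e.stimulus == "inhibit" and e.seq == 1
                   and (e.thread.startswith("learn")
                        or e.thread.startswith("recall"))]
        assert len(blocked) == 2  # the repeated inhibit of the closed paths
        assert any(e.thread == "learn(right)" for e in blocked)

    def test_new_coordinate_falls_back_to_random_choice(
            self, instantiated_detector):
        code, table = instantiated_detector
        vehicle_run(code, fire="right(3)", choice="forward", table=table)
        trace, world, _ = vehicle_run(code, fire="right(2)",
                                      choice="backward", table=table)
        assert trace.fetch_count() == 1  # the rule did not transfer
        assert world.outcome == "missed"

    def test_failed_run_applies_no_weight_change(self, instantiated_detector):
        code, table = instantiated_detector
        before = table.snapshot()
        vehicle_run(code, fire="right(3)", choice="backward", table=table)
        assert table.snapshot() == before


class TestDeterministicDetectorGeneral:
    def test_one_episode_transfers_to_every_coordinate(self,
                                                       general_detector):
        # the headline equivalence-relation property: one successful
        # episode in a direction makes every fire in that direction
        # deterministic, while the opposite direction stays unlearned
        code, table = general_detector
        vehicle_run(code, fire="right(3)", choice="forward", table=table)
        for x in range(1, 8):
            trace, world, _ = vehicle_run(code, fire=f"right({x})",
                                          table=table)
            assert world.outcome == "cleared"
            assert trace.fetch_count() == 0
        trace, _, _ = vehicle_run(code, fire="left(2)", choice="backward",
                                  table=table)
        assert trace.fetch_count() == 1

    def test_learning_updates_the_wildcard_entries(self, general_detector):
        code, table = general_detector
        vehicle_run(code, fire="right(3)", choice="forward", table=table)
        snap = table.snapshot()
        assert snap["sense(right(_))->recall(forward)"] > 0.5
        assert snap["sense(right(_))->learn(right)"] <= 0.5
        assert snap["sense(left(_))->learn(left)"] > 0.5  # untouched

    def test_mode_validation(self):
        with pytest.raises(ValueError):
            DetectorMode("other")
        assert DetectorMode("general").general
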