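import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracle_vm

from mesovm.circuit_lang import compile_circuit
from mesovm.circuits_library import (build_classical_conditioning,
                                     build_deterministic_detector,
                                     build_operant_conditioning,
                                     build_random_detector)
from mesovm.plasticity import LinkTable
from mesovm.terms import parse_term
from mesovm.vehicle_world import Track, World
from mesovm.vm_core import ModelState, run


def check_invariants(model):
    """Machine-state invariants that must hold after any run.

    Queues never go negative (receives consume only posted signals),
    thread clocks advance by exactly one per successful instruction, and
    every consummated receive crossed an open gate.
    """
    for key, q in model.queues.items():
        assert q >= 0, f"negative queue on {key}"
    for key, received in model.audit_receives.items():
        assert received <= model.audit_sends.get(key, 0), \
            f"more receives than sends on {key}"
    for aid, hist in model.audit_clocks.items():
        assert all(b - a == 1 for a, b in zip(hist, hist[1:])), \
            f"clock of activation {aid} did not advance monotonically by 1"
    for key, weight, threshold in model.audit_gates:
        assert weight > threshold, f"receive crossed closed gate {key}"


def vehicle_run(circuit, *, fire, choice=None, seed=0, table=None,
                track_length=7, max_cycles=500):
    """Run a vehicle circuit against a fresh world; returns (trace, world, model)."""
    code = compile_circuit(circuit) if not hasattr(circuit, "candidates") \
        else circuit
    table = table if table is not None else LinkTable(code.links)
    forced = parse_term(choice) if choice else None
    model = ModelState(code, links=table, seed=seed, forced_choice=forced)
    fire_term = parse_term(fire)
    world = World(Track(track_length, fire_term, fire_term.functor))
    trace = run(model, world, max_cycles)
    check_invariants(model)
    return trace, world, model


@pytest.fixture(scope="session")
def random_detector_code():
    return compile_circuit(build_random_detector())


@pytest.fixture()
def instantiated_detector():
    circuit = build_deterministic_detector(7, "instantiated")
    return compile_circuit(circuit), LinkTable(circuit.links)


@pytest.fixture()
def general_detector():
    circuit = build_deterministic_detector(7, "general")
    return compile_circuit(circuit), LinkTable(circuit.links)


@pytest.fixture()
def classical_circuit():
    return build_classical_conditioning()


@pytest.fixture()
def operant_circuit():
    return build_operant_conditioning()
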