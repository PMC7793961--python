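"""The virtual-machine kernel.

Executes compiled circuits through a sense-act-reflect cycle.  Two time
scales coexist: each thread activation carries a local clock ``T`` (the
micro scale — advanced by one after every successfully executed
instruction, and *not* advanced on failure, so a failing instruction is
retried until it succeeds), while each stream carries a sequence number
``I`` (the meso scale — a global time within one activation episode,
advanced when the body acts, i.e. engages a gear or performs a move).
Events reported by the reflect step are triples ``(I, thread, stimulus)``;
two events are synchronized exactly when they share ``I``.

There is no central clock: threads are logically concurrent.  For
reproducibility the scheduler is a deterministic round-robin over runnable
activations in creation order, one instruction per activation per pass.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import plasticity
from .circuit_lang import (Circuit, CodeRepository, CompiledThread, Node,
                           compile_circuit)
from .plasticity import LinkTable
from .terms import Term, match, parse_term, substitute

logger = logging.getLogger(__name__)

__all__ = [
    "TraceEvent", "Trace", "ModelState", "Environment", "ScriptedEnvironment",
    "CodeIntegrityError", "run", "sense", "react", "reflect",
    "deduce_instruction",
]

DEFAULT_MAX_CYCLES = 500

#: external stimuli that are buffered for ``wait`` rather than firing a thread
OUTCOME_STIMULI = ("positive", "negative")


class CodeIntegrityError(RuntimeError):
    """Compiled code is malformed or inconsistent with the machine state."""


@dataclass(frozen=True)
class TraceEvent:
    """A synchronized event: stream sequence number, thread, stimulus."""

    seq: int
    thread: str
    stimulus: str

    def as_text(self) -> str:
        return f"{self.seq}: {self.thread}:{self.stimulus}"

    def as_json(self) -> str:
        return json.dumps({"seq": self.seq, "thread": self.thread,
                           "stimulus": self.stimulus})


@dataclass
class Trace:
    events: list[TraceEvent] = field(default_factory=list)
    status: str = "quiescent"  # "quiescent" | "stopped" | "truncated"

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def to_text(self) -> str:
        return "\n".join(e.as_text() for e in self.events) + (
            "\n" if self.events else "")

    def to_jsonl(self) -> str:
        return "\n".join(e.as_json() for e in self.events) + (
            "\n" if self.events else "")

    def fetch_count(self) -> int:
        return sum(1 for e in self.events if e.stimulus.startswith("fetch"))

    def at_seq(self, seq: int) -> list[TraceEvent]:
        return [e for e in self.events if e.seq == seq]

    def of_thread(self, prefix: str) -> list[TraceEvent]:
        return [e for e in self.events if e.thread.startswith(prefix)]


@dataclass
class Activation:
    """One running instance of a thread pattern."""

    aid: int
    head: Term
    bindings: dict[str, Term]
    node: Node | None
    compiled: CompiledThread
    stream: str
    done: bool = False

    @property
    def name(self) -> str:
        return str(self.head)


class Environment:
    """What the machine senses and acts upon."""

    def poll(self) -> list[Term]:
        """Pending external stimuli, in arrival order (consumed)."""
        return []

    def exhausted(self) -> bool:
        """True when no further external stimulus will ever arrive."""
        return True

    def eval_check(self, cond: Term) -> str:
        raise NotImplementedError

    def do_act(self, action: Term) -> bool:
        """Perform a motor action; returns True if the stream tick advances."""
        raise NotImplementedError

    def do_clear(self) -> bool:
        """Clear action; returns True if the run should halt."""
        raise NotImplementedError

    def do_stop(self) -> None:
        raise NotImplementedError


class ScriptedEnvironment(Environment):
    """A minimal environment for micro-circuit runs and tests.

    ``schedule`` maps cycle number -> stimuli delivered on that cycle;
    ``checks`` maps the text of a check condition to its outcome.
    """

    def __init__(self, schedule: dict[int, list[Term]] | None = None,
                 checks: dict[str, str] | None = None) -> None:
        self.schedule = {k: list(v) for k, v in (schedule or {}).items()}
        self.checks = dict(checks or {})
        self.cycle = 0
        self.actions: list[str] = []
        self.outcome: str | None = None

    def poll(self) -> list[Term]:
        out = self.schedule.pop(self.cycle, [])
        self.cycle += 1
        return out

    def exhausted(self) -> bool:
        return not self.schedule

    def eval_check(self, cond: Term) -> str:
        return self.checks.get(str(cond), "inhibit")

    def do_act(self, action: Term) -> bool:
        self.actions.append(str(action))
        return False

    def do_clear(self) -> bool:
        self.outcome = "cleared"
        return True

    def do_stop(self) -> None:
        if self.outcome is None:
            self.outcome = "stopped"


class ModelState:
    """The machine state: code, clocks, stream counters, queues, weights."""

    def __init__(self, code: CodeRepository,
                 links: LinkTable | None = None,
                 seed: int | None = None,
                 forced_choice: Term | None = None) -> None:
        self.code = code
        self.links = links if links is not None else LinkTable(code.links)
        self.clocks: dict[int, int] = {}
        self.seq: dict[str, int] = {}
        self.queues: dict[tuple[str, str], int] = {}
        self.blocked_reported: dict[tuple[str, str], int] = {}
        self.merges: list[tuple[Term, int]] = []
        self.pending_stimuli: deque[Term] = deque()
        self.rng = np.random.default_rng(seed)
        self.forced_choice = forced_choice
        self.activations: list[Activation] = []
        self.trace: list[TraceEvent] = []
        self._cycle_events: list[TraceEvent] = []
        self._emitted_checks: set[tuple[str, str, int]] = set()
        self._next_aid = 0
        self._exec_stream = "s0"
        self._next_stream = 0
        self.halting = False
        self._pending_halt = False
        # audit counters for invariant checking
        self.audit_sends: dict[tuple[str, str], int] = {}
        self.audit_receives: dict[tuple[str, str], int] = {}
        self.audit_gates: list[tuple[tuple[str, str], float, float]] = []
        self.audit_clocks: dict[int, list[int]] = {}

    @classmethod
    def from_circuit(cls, circuit: Circuit, *, links: LinkTable | None = None,
                     seed: int | None = None,
                     forced_choice: Term | str | None = None) -> "ModelState":
        if isinstance(forced_choice, str):
            forced_choice = parse_term(forced_choice)
        return cls(compile_circuit(circuit), links=links, seed=seed,
                   forced_choice=forced_choice)

    # -- thread management -------------------------------------------------

    def new_stream(self) -> str:
        sid = f"s{self._next_stream}"
        self._next_stream += 1
        self.seq[sid] = 0
        return sid

    def fire_thread(self, head: Term, stream: str | None = None) -> Activation | None:
        """Instantiate the most specific compiled pattern matching *head*."""
        candidates = self.code.candidates(head)
        if not candidates:
            raise CodeIntegrityError(f"fire of unknown thread {head}")
        ct = candidates[0]
        bindings = match(ct.head, head) or {}
        act = Activation(self._next_aid, head, bindings, ct.root, ct, stream
                         or self._exec_stream)
        self._next_aid += 1
        self.clocks[act.aid] = 0
        self.audit_clocks[act.aid] = [0]
        self.activations.append(act)
        return act

    def record_event(self, seq: int, thread: Term | str, stimulus: str) -> None:
        self._cycle_events.append(TraceEvent(seq, str(thread), stimulus))

    def weight_snapshot(self) -> dict[str, float]:
        return self.links.snapshot()


# ---------------------------------------------------------------------------
# the sense-act-reflect cycle
# ---------------------------------------------------------------------------

def sense(model: ModelState, env: Environment) -> ModelState:
    """Capture pending external stimuli and make sense threads runnable."""
    for stim in env.poll():
        if stim.functor in OUTCOME_STIMULI:
            model.pending_stimuli.append(stim)
            continue
        matched = False
        for entry in model.code.entries:
            if match(entry, stim) is not None:
                stream = model.new_stream()
                model.fire_thread(stim, stream)
                matched = True
                break
        if not matched:
            logger.warning("dropping external stimulus %s: no declared sense "
                           "thread", stim)
    return model


def deduce_instruction(model: ModelState, thread: Term | str, T: int):
    """Contextual deduction: the instruction indexed by ``(thread, T)``.

    A live activation supplies the context (its branch path and parameter
    bindings); otherwise the most specific compiled variant is consulted —
    ground code is preferred over wildcard code.  Returns ``None`` when the
    instruction tree is exhausted at ``T``.
    """
    name = str(thread)
    for act in model.activations:
        if act.name == name and not act.done and model.clocks[act.aid] == T:
            return act.node.instr if act.node is not None else None
    head = thread if isinstance(thread, Term) else parse_term(name)
    candidates = model.code.candidates(head)
    if not candidates:
        raise CodeIntegrityError(f"no compiled code for thread {head}")
    nodes = [n for n in candidates[0].nodes if n.T == T]
    if not nodes:
        return None
    return nodes[0].instr


def react(model: ModelState, env: Environment) -> bool:
    """One scheduler pass over runnable activations in canonical order.

    Each activation attempts its next deduced instruction; success advances
    its clock by exactly 1, failure leaves the clock unchanged (the
    instruction is retried on a later pass).  Returns whether any
    instruction succeeded.
    """
    progress = False
    for act in list(model.activations):
        if act.done:
            continue
        if act.node is None:
            act.done = True  # instruction tree exhausted: quiescent thread
            continue
        if act.node.T != model.clocks[act.aid]:
            raise CodeIntegrityError(
                f"thread {act.name}: node index T={act.node.T} does not match "
                f"clock {model.clocks[act.aid]}")
        model._exec_stream = act.stream
        ok, label = _execute(model, env, act)
        if ok:
            progress = True
            model.clocks[act.aid] += 1
            model.audit_clocks[act.aid].append(model.clocks[act.aid])
            if label is not None and label in act.node.branches:
                act.node = act.node.branches[label]
            else:
                act.node = act.node.next
            if act.node is None:
                act.done = True
    if model._pending_halt:
        # a stop/clear halts the machine once the current pass completes,
        # so simultaneous events of the same stream tick are still reported
        # and in-flight plasticity (merge/join/ltp/ltd) can drain
        model.halting = True
        model._pending_halt = False
    model.activations = [a for a in model.activations if not a.done]
    return progress


def reflect(model: ModelState) -> list[TraceEvent]:
    """Report the synchronized events recorded during this cycle."""
    events = model._cycle_events
    model._cycle_events = []
    return events


def run(model: ModelState, env: Environment,
        max_cycles: int = DEFAULT_MAX_CYCLES) -> Trace:
    """Execute the sense-act-reflect loop to completion.

    Halts on an explicit stop/clear action ("stopped"), on quiescence — a
    pass in which no instruction succeeds and no further input can arrive
    ("quiescent") — or after *max_cycles* scheduler passes ("truncated").
    """
    if max_cycles <= 0:
        raise ValueError("max_cycles must be positive")
    status = "truncated"
    for _ in range(max_cycles):
        sense(model, env)
        progress = react(model, env)
        model.trace.extend(reflect(model))
        if not progress and env.exhausted() and not model.pending_stimuli:
            status = "stopped" if model.halting else "quiescent"
            break
    return Trace(list(model.trace), status)


# ---------------------------------------------------------------------------
# instruction execution
# ---------------------------------------------------------------------------

def _execute(model: ModelState, env: Environment,
             act: Activation) -> tuple[bool, str | None]:
    instr = act.node.instr
    op = instr.op
    b = act.bindings
    seq_now = model.seq[act.stream]

    if op == "send":
        target = substitute(instr.arg, b)
        key = (str(act.head), str(target))
        model.audit_sends[key] = model.audit_sends.get(key, 0) + 1
        plasticity.send(model, act.head, target)
        return True, None

    if op == "receive":
        pattern = substitute(instr.arg, b)
        status, src, extra = _receive_matching(model, act.head, pattern)
        if status == "success":
            b.update(extra)
            key = (str(src), str(act.head))
            model.audit_receives[key] = model.audit_receives.get(key, 0) + 1
            return True, None
        if status == "blocked":
            # a queued signal gated by a closed link surfaces as inhibition
            model.record_event(seq_now, act.head, "inhibit")
        return False, None

    if op == "merge":
        plasticity.merge(model, instr.arg, act.head, seq_now)
        return True, None

    if op == "join":
        pattern = substitute(instr.arg, b)
        poster = plasticity.coincide(model, pattern, seq_now)
        if poster is None:
            return False, None
        extra = match(pattern, poster)
        if extra:
            b.update(extra)
        return True, None

    if op == "fire":
        if not model.halting:
            model.fire_thread(substitute(instr.arg, b), act.stream)
        return True, None

    if op == "choice":
        if model.halting:
            return False, None
        alts = [substitute(a, b) for a in instr.alternatives]
        if model.forced_choice is not None:
            chosen = next((a for a in alts
                           if str(a) == str(model.forced_choice)), alts[0])
        else:
            chosen = alts[int(model.rng.integers(len(alts)))]
        if instr.var:
            b[instr.var] = chosen
        model.record_event(seq_now, act.head, f"fetch({chosen})")
        return True, None

    if op == "check":
        # checks stay live while the machine drains after a stop/clear: the
        # stream tick is frozen then, so the per-tick throttle still bounds
        # them, and the simultaneous percepts of the final tick get reported
        throttle = (act.name, act.stream, seq_now)
        if throttle in model._emitted_checks:
            return False, None  # one perceptual sample per stream tick
        outcome = env.eval_check(substitute(instr.arg, b))
        if outcome not in ("excite", "inhibit"):
            raise CodeIntegrityError(f"check outcome {outcome!r}")
        model._emitted_checks.add(throttle)
        model.record_event(seq_now, act.head, outcome)
        return True, outcome

    if op == "wait":
        wanted = {a.functor for a in instr.alternatives}
        for i, stim in enumerate(model.pending_stimuli):
            if stim.functor in wanted:
                del model.pending_stimuli[i]
                model.record_event(seq_now, act.head, stim.functor)
                return True, stim.functor
        return False, None

    if op == "emit":
        model.record_event(seq_now, act.head, str(substitute(instr.arg, b)))
        return True, None

    if op == "act":
        if model.halting:
            return False, None
        if env.do_act(substitute(instr.arg, b)):
            model.seq[act.stream] += 1
        return True, None

    if op == "clear":
        if model.halting:
            return False, None
        model.record_event(seq_now, act.head, "clear")
        if env.do_clear():
            model._pending_halt = True
        return True, None

    if op == "stop":
        if model.halting:
            return False, None
        model.record_event(seq_now, act.head, "stop")
        env.do_stop()
        model._pending_halt = True
        return True, None

    if op == "ltp":
        plasticity.ltp(model, substitute(instr.arg, b), substitute(instr.arg2, b))
        return True, None

    if op == "ltd":
        plasticity.ltd(model, substitute(instr.arg, b), substitute(instr.arg2, b))
        return True, None

    raise CodeIntegrityError(f"unknown opcode {op!r} in thread {act.name}")


def _receive_matching(model: ModelState, recipient: Term,
                      source_pattern: Term):
    """Find a queued signal whose source matches the receive pattern.

    Queues are scanned in insertion order; the first matching non-empty
    queue is attempted through the gated receive protocol.
    """
    for (src_s, dst_s), count in model.queues.items():
        if count <= 0 or dst_s != str(recipient):
            continue
        src = parse_term(src_s)
        extra = match(source_pattern, src)
        if extra is None:
            continue
        link, instance = model.links.resolve(src, recipient)
        status = plasticity.receive(model, recipient, src)
        if status == "success":
            model.audit_gates.append(
                ((src_s, dst_s), model.links.weight(link, instance),
                 link.threshold))
            return "success", src, extra
        return status, src, {}
    return "failure", None, {}
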