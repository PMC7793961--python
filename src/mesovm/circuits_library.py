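"""Prebuilt, tested circuit definitions.

Builders return :class:`~mesovm.circuit_lang.Circuit` objects for each of
the canonical micro- and meso-circuits:

* synaptic transmission (a ``send``/``receive`` pair over one gated link);
* classical conditioning (a facilitatory interneuron implementing
  coincidence-gated potentiation of the cs -> motor pathway);
* operant conditioning (an open ``learn`` fork that positive/negative
  outcomes convert, through ltp/ltd, into an open ``accept`` or ``reject``
  pathway — inhibition enabling disinhibition);
* the random fire detector (a wired, non-plastic stochastic decision
  tree driving the vehicle);
* the deterministic fire detector (the same tree with the operant fork
  embedded: ``recall`` pathways opened and the ``learn`` pathway closed by
  synchro threads that detect the coincidence of the two modalities).

Every builder's circuit round-trips through the shared text format
(:func:`~mesovm.circuit_lang.serialize`), so library circuits and
hand-written user circuits are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .circuit_lang import Circuit, Instruction, Node, ThreadPattern, branch, seq
from .plasticity import Link
from .terms import Term, parse_term

__all__ = [
    "DetectorMode",
    "build_transmission",
    "build_classical_conditioning",
    "build_operant_conditioning",
    "build_random_detector",
    "build_deterministic_detector",
]

OPEN, CLOSED = 1.0, 0.0  # initial weights around the default 0.5 threshold


@dataclass(frozen=True)
class DetectorMode:
    """Learning scope of the deterministic detector.

    ``instantiated`` — plastic links are ground: each coordinate learns its
    own rule.  ``general`` — plastic links carry wildcard coordinates: one
    successful episode transfers to every coordinate in the direction.
    """

    mode: str = "instantiated"

    def __post_init__(self) -> None:
        if self.mode not in ("instantiated", "general"):
            raise ValueError(f"mode must be instantiated|general, got {self.mode!r}")

    @property
    def general(self) -> bool:
        return self.mode == "general"


def _i(op: str, arg: str | None = None, **kw) -> Instruction:
    return Instruction(op, parse_term(arg) if arg else None, **kw)


def _choice(var: str, *alts: str) -> Instruction:
    return Instruction("choice", var=var,
                       alternatives=tuple(parse_term(a) for a in alts))


def _wait(*alts: str) -> Instruction:
    return Instruction("wait", alternatives=tuple(parse_term(a) for a in alts))


def _link_op(op: str, src: str, dst: str) -> Instruction:
    return Instruction(op, parse_term(src), parse_term(dst))


def build_transmission() -> Circuit:
    """Two threads, one synapse: p fires on a stimulus and signals q.

    (Identifiers are lower-case because capitalized names denote variables
    in the circuit language.)
    """
    c = Circuit("transmission")
    c.threads = [
        ThreadPattern(parse_term("p"), seq(_i("send", "q"))),
        ThreadPattern(parse_term("q"), seq(_i("receive", "p"),
                                           _i("emit", "excite"))),
    ]
    c.links = [Link(parse_term("p"), parse_term("q"), weight=OPEN)]
    c.entries = [parse_term("p")]
    return c


def build_classical_conditioning() -> Circuit:
    """The cs/us pairing circuit.

    The unconditioned pathway sense(us) -> motor(us) is open from the
    start; the conditioned pathway sense(cs) -> motor(cs) starts closed.
    sense(cs) fires the facilitatory interneuron ltp_unit(cs), which joins
    on a marker merged by sense(us): when cs and us arrive under the same
    stream tick (cs slightly preceding us), the coincidence potentiates the
    conditioned pathway, and cs alone thereafter drives motor(cs).
    """
    c = Circuit("classical_conditioning")
    c.threads = [
        ThreadPattern(parse_term("sense(cs)"),
                      seq(_i("fire", "ltp_unit(cs)"), _i("send", "motor(cs)"))),
        ThreadPattern(parse_term("sense(us)"),
                      seq(_i("merge", "ltp_unit(cs)"), _i("send", "motor(us)"))),
        ThreadPattern(parse_term("ltp_unit(cs)"),
                      seq(_i("join", "sense(us)"),
                          _link_op("ltp", "sense(cs)", "motor(cs)"))),
        ThreadPattern(parse_term("motor(X)"),
                      seq(_i("receive", "sense(X)"), _i("emit", "excite"))),
    ]
    c.links = [
        Link(parse_term("sense(cs)"), parse_term("motor(cs)"), weight=CLOSED),
        Link(parse_term("sense(us)"), parse_term("motor(us)"), weight=OPEN),
    ]
    c.entries = [parse_term("sense(cs)"), parse_term("sense(us)")]
    return c


def build_operant_conditioning() -> Circuit:
    """The learn/accept/reject fork.

    Initially the pathway sense -> learn is open while accept and reject
    are closed.  learn discriminates a positive from a negative external
    stimulus and directs plasticity accordingly: ltp opens the rewarded
    pathway while ltd closes learn itself, so the next sense event routes
    straight through the disinhibited pathway.
    """
    c = Circuit("operant_conditioning")
    c.threads = [
        ThreadPattern(parse_term("sense(S)"),
                      seq(_i("send", "learn(S)"), _i("send", "accept(S)"),
                          _i("send", "reject(S)"))),
        ThreadPattern(parse_term("learn(S)"),
                      seq(_i("receive", "sense(S)"),
                          branch(_wait("positive", "negative"),
                                 positive=seq(
                                     _link_op("ltp", "sense(S)", "accept(S)"),
                                     _link_op("ltd", "sense(S)", "learn(S)")),
                                 negative=seq(
                                     _link_op("ltp", "sense(S)", "reject(S)"),
                                     _link_op("ltd", "sense(S)", "learn(S)"))))),
        ThreadPattern(parse_term("accept(S)"),
                      seq(_i("receive", "sense(S)"), _i("emit", "excite"))),
        ThreadPattern(parse_term("reject(S)"),
                      seq(_i("receive", "sense(S)"), _i("emit", "excite"))),
    ]
    c.links = [
        Link(parse_term("sense(S)"), parse_term("learn(S)"), weight=OPEN),
        Link(parse_term("sense(S)"), parse_term("accept(S)"), weight=CLOSED),
        Link(parse_term("sense(S)"), parse_term("reject(S)"), weight=CLOSED),
    ]
    c.entries = [parse_term("sense(S)")]
    return c


def _detect_thread(excite_branch: Node) -> ThreadPattern:
    # detect(F(X)): sample the fire percept once per stream tick; on
    # inhibit resume detecting, on excite take the given branch
    return ThreadPattern(
        parse_term("detect(F(X))"),
        seq(branch(_i("check", "on(F(X))"),
                   excite=excite_branch,
                   inhibit=seq(_i("fire", "detect(F(X))")))))


def _move_thread(excite_prefix: list[Instruction]) -> ThreadPattern:
    # move(Y): validate the current coordinate; while on the track keep
    # stepping (the stream tick advances after each step), past the limit
    # stop
    return ThreadPattern(
        parse_term("move(Y)"),
        seq(branch(_i("check", "at(_)"),
                   excite=seq(*excite_prefix, _i("act", "step"),
                              _i("fire", "move(Y)")),
                   inhibit=seq(_i("stop")))))


def build_random_detector(track_length: int = 7) -> Circuit:
    """The wired stochastic decision tree of the searching vehicle.

    sense(F(X)) draws a gear at random (the fetch stimulus), engages it,
    and spawns the concurrent detect/move loops.  Nothing in the circuit
    relates the right/left percepts to the forward/backward gears, and
    nothing is plastic: the behavior can never change.
    """
    c = Circuit("random_detector")
    c.threads = [
        ThreadPattern(parse_term("sense(F(X))"),
                      seq(_choice("Y", "forward", "backward"),
                          _i("act", "engage(Y)"),
                          _i("fire", "detect(F(X))"),
                          _i("fire", "move(Y)"))),
        _detect_thread(seq(_i("clear"))),
        _move_thread([]),
    ]
    c.links = []
    c.entries = [parse_term("sense(F(X))")]
    return c


def build_deterministic_detector(track_length: int = 7,
                                 mode: DetectorMode | str = "instantiated"
                                 ) -> Circuit:
    """The plastic detector: the operant fork embedded in the decision tree.

    sense(F(X)) broadcasts to two recall pathways (one per gear, both
    initially closed) and to the learn pathway (initially open).  learn
    draws a random gear exactly as the random detector does; recall(Y)
    engages its gear directly, with no fetch.  When the two modalities
    synchronize — check(on(F(X))) in detect and check(at(...)) in move
    both excite under one stream tick — the synchro thread fires and
    directs plasticity: ltp opens (sense(F(X)), recall(Y)) and ltd closes
    (sense(F(X)), learn(F)).  In ``general`` mode the links carry wildcard
    coordinates, so one successful episode in a direction opens recall for
    every coordinate of that direction.
    """
    if isinstance(mode, str):
        mode = DetectorMode(mode)
    c = Circuit(f"deterministic_detector_{mode.mode}")

    wild = mode.general
    ltp_src = "sense(F(_))" if wild else "sense(F(X))"

    c.threads = [
        ThreadPattern(parse_term("sense(F(X))"),
                      seq(_i("send", "recall(forward)"),
                          _i("send", "recall(backward)"),
                          _i("send", "learn(F)"))),
        ThreadPattern(parse_term("recall(Y)"),
                      seq(_i("receive", "sense(F(X))"),
                          _i("act", "engage(Y)"),
                          _i("fire", "detect(F(X))"),
                          _i("fire", "move(Y)"))),
        ThreadPattern(parse_term("learn(F)"),
                      seq(_i("receive", "sense(F(X))"),
                          _choice("Y", "forward", "backward"),
                          _i("act", "engage(Y)"),
                          _i("fire", "detect(F(X))"),
                          _i("fire", "move(Y)"))),
        _detect_thread(seq(_i("fire", "synchro(F(X))"), _i("clear"))),
        _move_thread([_i("merge", "synchro")]),
        ThreadPattern(parse_term("synchro(F(X))"),
                      seq(_i("join", "move(Y)"),
                          _link_op("ltp", ltp_src, "recall(Y)"),
                          _link_op("ltd", ltp_src, "learn(F)"))),
    ]
    if wild:
        c.links = []
        for d in ("right", "left"):
            c.links.append(Link(parse_term(f"sense({d}(_))"),
                                parse_term(f"learn({d})"),
                                weight=OPEN, scope="wildcard"))
            for y in ("forward", "backward"):
                c.links.append(Link(parse_term(f"sense({d}(_))"),
                                    parse_term(f"recall({y})"),
                                    weight=CLOSED, scope="wildcard"))
    else:
        c.links = [
            Link(parse_term("sense(F(X))"), parse_term("learn(F)"),
                 weight=OPEN, scope="ground"),
            Link(parse_term("sense(F(X))"), parse_term("recall(forward)"),
                 weight=CLOSED, scope="ground"),
            Link(parse_term("sense(F(X))"), parse_term("recall(backward)"),
                 weight=CLOSED, scope="ground"),
        ]
    c.entries = [parse_term("sense(F(X))")]
    return c
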