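"""The thought-experiment environment.

A finite bidirectional one-dimensional track with discrete coordinates
``F(X)``, ``F in {right, left}``, ``X = 1..length`` (default 7); the
coordinate ``_(0)`` is the vehicle's home station.  The vehicle carries a
forward and a backward gear; the hidden environmental ground truth — which
the circuits must *learn*, and never encode — is that the forward gear
moves right and the backward gear moves left, one coordinate per step.

Percepts are binary internal stimuli:

``check_on(F(X))``
    excite iff the vehicle stands on the fire position;
``check_at(F(X))``
    excite iff the queried coordinate is defined on the track (bounds
    inclusive), inhibit past the limit.

The move thread validates the coordinate it currently occupies (it checks
*where it stands*, not where it is going), so the vehicle discovers the
track limit one step after leaving the last defined coordinate; that
overrun step is represented by the pseudo-coordinate ``F(length+1)``.
The stream sequence number advances when the vehicle acts: once when a
gear engages and once per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .terms import Term, parse_term
from .vm_core import Environment

__all__ = ["Track", "VehicleState", "World", "ContractViolation",
           "check_on", "check_at", "move_step", "clear_fire", "stop"]

DEFAULT_TRACK_LENGTH = 7

GEAR_DIRECTION = {"forward": "right", "backward": "left"}  # hidden ground truth

HOME = Term("home")


class ContractViolation(RuntimeError):
    """A circuit drove the world outside its contract (a circuit bug)."""


def coord(direction: str, x: int) -> Term:
    return Term(direction, (Term(str(x)),))


@dataclass
class Track:
    length: int = DEFAULT_TRACK_LENGTH
    fire: Term | None = None        # e.g. right(3)
    smoke: str | None = None        # "right" | "left"

    def __post_init__(self) -> None:
        if isinstance(self.fire, str):
            self.fire = parse_term(self.fire)
        if self.fire is not None:
            d, x = _split(self.fire)
            if d not in ("right", "left") or not (1 <= x <= self.length):
                raise ValueError(f"fire {self.fire} outside track bounds")
            if self.smoke is not None and self.smoke != d:
                raise ValueError("smoke direction must equal fire direction")


@dataclass
class VehicleState:
    # signed offset: 0 = home, +x = right(x), -x = left(x);
    # |offset| = length+1 marks the overrun step past the track limit
    offset: int = 0
    gear: str | None = None         # "forward" | "backward" | None
    detector_on: bool = True
    moves: int = 0

    def position(self) -> Term:
        if self.offset == 0:
            return HOME
        d = "right" if self.offset > 0 else "left"
        return coord(d, abs(self.offset))


def _split(c: Term) -> tuple[str, int]:
    if c.functor == "home" or not c.args:
        return ("home", 0)
    return c.functor, int(c.args[0].functor)


# ---------------------------------------------------------------------------
# percepts and actions (module-level operations on a world)
# ---------------------------------------------------------------------------

def check_on(world: "World", c: Term) -> str:
    """Fire percept: excite iff the vehicle stands on the fire at *c*."""
    if not world.vehicle.detector_on:
        raise ContractViolation("check_on with detector off")
    on_fire = (world.track.fire is not None
               and world.vehicle.position() == c == world.track.fire)
    return "excite" if on_fire else "inhibit"


def check_at(world: "World", c: Term) -> str:
    """Track-bounds percept: excite iff coordinate *c* is defined."""
    d, x = _split(c)
    if d == "home":
        return "excite"
    return "excite" if 1 <= x <= world.track.length else "inhibit"


def move_step(world: "World", gear: str) -> VehicleState:
    """One step in the gear's direction; home -> F(1) -> ... -> F(length).

    A step taken from ``F(length)`` is the overrun step onto the undefined
    coordinate ``F(length+1)``; stepping again from there is a circuit bug.
    """
    if gear not in GEAR_DIRECTION:
        raise ContractViolation(f"move with no valid gear: {gear!r}")
    v = world.vehicle
    if abs(v.offset) > world.track.length:
        raise ContractViolation("move beyond the overrun coordinate")
    delta = 1 if GEAR_DIRECTION[gear] == "right" else -1
    v.offset += delta
    v.moves += 1
    return v


def clear_fire(world: "World") -> "World":
    if world.track.fire is None or world.vehicle.position() != world.track.fire:
        raise ContractViolation("clear with no fire at the vehicle position")
    world.track.fire = None
    world.outcome = "cleared"
    return world


def stop(world: "World") -> "World":
    if world.outcome is None:
        if world.vehicle.moves == 0:
            world.outcome = "idle"
        else:
            world.outcome = "missed" if world.track.fire is not None else "cleared"
    world.stopped = True
    return world


# ---------------------------------------------------------------------------
# the Environment adapter driven by the virtual machine
# ---------------------------------------------------------------------------

@dataclass
class World(Environment):
    track: Track = field(default_factory=Track)
    stop_after_clear: bool = True
    vehicle: VehicleState = field(default_factory=VehicleState)
    outcome: str | None = None
    stopped: bool = False
    _smoke_delivered: bool = False

    def poll(self):
        # the smoke of the fire triggers the run: it activates the sense
        # thread instantiated at the fire coordinate (but carries nothing
        # about gears)
        if (not self._smoke_delivered and self.track.smoke is not None
                and self.track.fire is not None):
            self._smoke_delivered = True
            return [Term("sense", (self.track.fire,))]
        return []

    def exhausted(self) -> bool:
        return self._smoke_delivered or self.track.smoke is None

    def eval_check(self, cond: Term) -> str:
        if cond.functor == "on":
            return check_on(self, cond.args[0])
        if cond.functor == "at":
            # the move thread validates its current coordinate
            return check_at(self, self.vehicle.position())
        raise ContractViolation(f"unknown environment predicate {cond}")

    def do_act(self, action: Term) -> bool:
        if action.functor == "engage":
            gear = action.args[0].functor
            if gear not in GEAR_DIRECTION:
                raise ContractViolation(f"unknown gear {gear}")
            self.vehicle.gear = gear
            return True  # engaging concludes the choice step: tick
        if action.functor == "step":
            move_step(self, self.vehicle.gear)
            return True  # the stream sequence advances after a move
        raise ContractViolation(f"unknown action {action}")

    def do_clear(self) -> bool:
        clear_fire(self)
        return self.stop_after_clear

    def do_stop(self) -> None:
        stop(self)

    def snapshot(self) -> dict:
        return {
            "position": str(self.vehicle.position()),
            "gear": self.vehicle.gear,
            "fire": str(self.track.fire) if self.track.fire else None,
            "smoke": self.track.smoke,
            "outcome": self.outcome,
            "moves": self.vehicle.moves,
        }
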