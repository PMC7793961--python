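"""Synaptic-plasticity protocols.

A :class:`Link` is a directed, weighted, threshold-gated connection between
two thread patterns.  A link is OPEN when ``weight > threshold`` and CLOSED
otherwise; signals queued on a closed link are retained but cannot be
received, which is how inhibition gates whole pathways.  Long-term
potentiation (``ltp``) and depression (``ltd``) move weights across the
threshold and so switch pathways open or closed — the inhibition /
disinhibition mechanism that all learning in this package reduces to.

Weight bookkeeping supports two scopes:

``ground``
    each ground instantiation of the link pattern (e.g. the coordinate in
    ``sense(right(3))``) carries its own weight — instantiated rule learning.
``wildcard``
    one shared weight for every instantiation matched by the pattern
    (e.g. ``sense(right(_))``) — generalized rule learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .terms import Term, is_ground, match, specificity

__all__ = ["Link", "LinkTable", "send", "receive", "coincide", "ltp", "ltd"]

#: weights below/at this default threshold block transmission
DEFAULT_THRESHOLD = 0.5
DEFAULT_DELTA_PLUS = 1.0
DEFAULT_DELTA_MINUS = 1.0


@dataclass
class Link:
    """A directed source -> recipient connection with a gated weight."""

    source: Term
    recipient: Term
    weight: float = 0.0
    threshold: float = DEFAULT_THRESHOLD
    scope: str = "ground"  # "ground" | "wildcard"

    def __post_init__(self) -> None:
        if self.scope not in ("ground", "wildcard"):
            raise ValueError(f"link scope must be ground|wildcard, got {self.scope!r}")

    @property
    def pattern_key(self) -> tuple[str, str]:
        return (str(self.source), str(self.recipient))


class LinkResolutionError(LookupError):
    pass


class LinkTable:
    """Declared links plus their mutable weight entries.

    The table owns all plastic state and survives across runs (a learning
    episode changes weights that later runs observe).
    """

    def __init__(self, links: list[Link] | None = None,
                 delta_plus: float = DEFAULT_DELTA_PLUS,
                 delta_minus: float = DEFAULT_DELTA_MINUS) -> None:
        self.links: list[Link] = []
        self.delta_plus = delta_plus
        self.delta_minus = delta_minus
        self._weights: dict[tuple[int, str], float] = {}
        for link in links or []:
            self.declare(link)

    def declare(self, link: Link) -> None:
        self.links.append(link)

    # -- resolution -------------------------------------------------------

    def _instance_key(self, link: Link, src: Term, dst: Term) -> str:
        if link.scope == "wildcard":
            return "*"
        return f"{src}->{dst}"

    def resolve(self, src: Term, dst: Term) -> tuple[Link, str]:
        """Find the declared link governing the ground pair ``src -> dst``.

        The most specific (most ground) matching declaration wins.
        """
        best: tuple[int, Link] | None = None
        for link in self.links:
            b = match(link.source, src)
            if b is None:
                continue
            if match(link.recipient, dst, b) is None:
                continue
            spec = specificity(link.source) + specificity(link.recipient)
            if best is None or spec < best[0]:
                best = (spec, link)
        if best is None:
            raise LinkResolutionError(f"no declared link {src} -> {dst}")
        link = best[1]
        return link, self._instance_key(link, src, dst)

    def resolve_for_update(self, src: Term, dst: Term) -> tuple[Link, str]:
        """Resolve an ltp/ltd target, which may itself be a wildcard pattern."""
        if is_ground(src) and is_ground(dst):
            return self.resolve(src, dst)
        for link in self.links:
            if str(link.source) == str(src) and str(link.recipient) == str(dst):
                if link.scope != "wildcard":
                    raise LinkResolutionError(
                        f"non-ground update target {src} -> {dst} on a ground-scope link")
                return link, "*"
        raise LinkResolutionError(f"no declared link pattern {src} -> {dst}")

    # -- weights ----------------------------------------------------------

    def weight(self, link: Link, instance: str) -> float:
        return self._weights.get((id(link), instance), link.weight)

    def set_weight(self, link: Link, instance: str, value: float) -> None:
        self._weights[(id(link), instance)] = value

    def is_open(self, link: Link, instance: str) -> bool:
        return self.weight(link, instance) > link.threshold

    def snapshot(self) -> dict[str, float]:
        """All current weights (declared defaults plus touched instances)."""
        out: dict[str, float] = {}
        for link in self.links:
            key = "->".join(link.pattern_key)
            out[key] = link.weight
        for (lid, instance), w in self._weights.items():
            link = next(l for l in self.links if id(l) == lid)
            key = "->".join(link.pattern_key)
            out[f"{key}[{instance}]" if instance != "*" else key] = w
        return out


# ---------------------------------------------------------------------------
# protocol operations; ``model`` is the machine state (see vm_core.ModelState)
# ---------------------------------------------------------------------------

def _queue_key(src: Term, dst: Term) -> tuple[str, str]:
    return (str(src), str(dst))


def send(model, source: Term, recipient: Term) -> None:
    """Post one signal on source -> recipient and fire the recipient.

    Sending is non-blocking: the sender proceeds regardless of the link
    state; gating applies on the receiving side only.
    """
    key = _queue_key(source, recipient)
    model.queues[key] = model.queues.get(key, 0) + 1
    fire = getattr(model, "fire_thread", None)
    if fire is not None:
        fire(recipient)


def receive(model, recipient: Term, source: Term) -> str:
    """Attempt to consume one signal from source on an open link.

    Returns ``"success"`` (signal consumed), ``"failure"`` (nothing queued),
    ``"blocked"`` (a queued signal is gated by a closed link — reported the
    first time only) or ``"blocked_silent"`` (same, already reported).
    The queue is never decremented on a closed link.
    """
    key = _queue_key(source, recipient)
    queued = model.queues.get(key, 0)
    if queued <= 0:
        return "failure"
    link, instance = model.links.resolve(source, recipient)
    if model.links.is_open(link, instance):
        model.queues[key] = queued - 1
        return "success"
    reported = model.blocked_reported.get(key, 0)
    if reported < queued:
        model.blocked_reported[key] = reported + 1
        return "blocked"
    return "blocked_silent"


def merge(model, addressee: Term, poster: Term, seq: int) -> None:
    """Post a coincidence marker: *poster* signalled at stream time *seq*.

    *addressee* names the joining thread for documentation/validation; the
    marker itself is matched by the join side against the poster.
    """
    model.merges.append((poster, seq))


def coincide(model, poster_pattern: Term, seq: int) -> Term | None:
    """Join half of the coincidence detector.

    Succeeds iff a merge whose poster matches *poster_pattern* was posted
    under the same stream sequence number *seq* (the synchronization
    window); the marker is consumed and the posting thread returned.
    Returns ``None`` when no synchronized marker exists — normal failure,
    no weight change enabled.
    """
    for i, (poster, s) in enumerate(model.merges):
        if s == seq and match(poster_pattern, poster) is not None:
            del model.merges[i]
            return poster
    return None


def ltp(model, src: Term, dst: Term) -> None:
    """Potentiate: strictly increase the targeted weight entry."""
    table: LinkTable = model.links
    link, instance = table.resolve_for_update(src, dst)
    table.set_weight(link, instance, table.weight(link, instance) + table.delta_plus)


def ltd(model, src: Term, dst: Term) -> None:
    """Depress: strictly decrease the targeted weight entry."""
    table: LinkTable = model.links
    link, instance = table.resolve_for_update(src, dst)
    table.set_weight(link, instance, table.weight(link, instance) - table.delta_minus)
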