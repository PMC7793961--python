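"""Symbolic terms for circuit patterns.

Thread identifiers, link endpoints and stimuli are small first-order terms
such as ``detect(right(3))`` or ``sense(right(_))``.  An identifier starting
with an upper-case letter is a variable (``F``, ``X``, ``Y``); ``_`` is the
anonymous wildcard and matches exactly one term.  A variable may appear in
functor position (``F(X)``), in which case binding it to ``right`` turns the
term into ``right(X)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "Term",
    "parse_term",
    "match",
    "substitute",
    "is_ground",
    "specificity",
]


@dataclass(frozen=True)
class Term:
    functor: str
    args: tuple["Term", ...] = ()

    def __str__(self) -> str:
        if not self.args:
            return self.functor
        return f"{self.functor}({', '.join(str(a) for a in self.args)})"

    @property
    def is_var(self) -> bool:
        return self.functor[0].isupper()

    @property
    def is_wildcard(self) -> bool:
        return self.functor == "_"


def atom(name: str) -> Term:
    return Term(name)


class TermSyntaxError(ValueError):
    pass


def parse_term(text: str) -> Term:
    term, rest = _parse(text.strip(), 0)
    if rest != len(text.strip()):
        raise TermSyntaxError(f"trailing input in term: {text!r}")
    return term


def _parse(s: str, i: int) -> tuple[Term, int]:
    j = i
    while j < len(s) and (s[j].isalnum() or s[j] == "_"):
        j += 1
    if j == i:
        raise TermSyntaxError(f"expected identifier at {i} in {s!r}")
    name = s[i:j]
    if j < len(s) and s[j] == "(":
        args = []
        j += 1
        while True:
            arg, j = _parse(s, j)
            args.append(arg)
            if j >= len(s):
                raise TermSyntaxError(f"unterminated term in {s!r}")
            if s[j] == ",":
                j += 1
                while j < len(s) and s[j] == " ":
                    j += 1
                continue
            if s[j] == ")":
                j += 1
                break
            raise TermSyntaxError(f"unexpected {s[j]!r} at {j} in {s!r}")
        return Term(name, tuple(args)), j
    return Term(name), j


def substitute(term: Term, bindings: dict[str, Term]) -> Term:
    """Apply *bindings* to *term*, including functor-position variables."""
    args = tuple(substitute(a, bindings) for a in term.args)
    if term.is_var and not term.is_wildcard and term.functor in bindings:
        base = bindings[term.functor]
        # F bound to right: F(X) -> right(X); F bound to right(3): F -> right(3)
        return Term(base.functor, base.args + args)
    return Term(term.functor, args)


def match(pattern: Term, ground: Term,
          bindings: dict[str, Term] | None = None) -> dict[str, Term] | None:
    """Match *pattern* against a ground *ground* term.

    Returns the (extended) binding map on success, ``None`` on failure.
    A wildcard matches one whole term without binding anything.
    """
    b = dict(bindings) if bindings else {}
    if _match(pattern, ground, b):
        return b
    return None


def _match(p: Term, g: Term, b: dict[str, Term]) -> bool:
    if p.is_wildcard:
        return not p.args  # bare "_" matches any single term
    if p.is_var:
        if p.functor in b:
            return _match(substitute(p, {p.functor: b[p.functor]}), g, b)
        if not p.args:
            b[p.functor] = g
            return True
        # variable functor: bind to the functor shell, match args
        if len(p.args) != len(g.args):
            return False
        b[p.functor] = Term(g.functor)
        return all(_match(pa, ga, b) for pa, ga in zip(p.args, g.args))
    if p.functor != g.functor or len(p.args) != len(g.args):
        return False
    return all(_match(pa, ga, b) for pa, ga in zip(p.args, g.args))


def _walk(term: Term) -> Iterator[Term]:
    yield term
    for a in term.args:
        yield from _walk(a)


def is_ground(term: Term) -> bool:
    return all(not t.is_var and not t.is_wildcard for t in _walk(term))


def specificity(term: Term) -> int:
    """Number of non-ground positions; lower is more specific (ground = 0)."""
    return sum(1 for t in _walk(term) if t.is_var or t.is_wildcard)


def variables(term: Term) -> set[str]:
    return {t.functor for t in _walk(term) if t.is_var and not t.is_wildcard}
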