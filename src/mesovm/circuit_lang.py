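"""Symbolic circuit language.

A circuit is a set of *thread patterns* — named, possibly parameterized
threads each enclosing a finite tree of instructions — plus a set of
weighted links and the entry (sense) patterns that external stimuli may
activate.  Circuits have three interchangeable representations: the Python
object graph built here, a structured text format (one block per thread,
an explicit links section) and, for execution, a compiled repository of
``(thread, T)``-indexed instructions that the virtual machine deduces from.

Branching combinators: the conjunction of converging signals ("*" in the
graphical form) is expressed with a ``join``/``merge`` pair; the divergence
of a signal ("+") is a sequence of ``send``/``fire`` broadcasts, while "+"
over converging inputs is first-arrival choice on the receiving side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .plasticity import Link
from .terms import Term, is_ground, parse_term, specificity, variables

__all__ = [
    "Instruction", "Node", "ThreadPattern", "Circuit",
    "CompiledThread", "CodeRepository", "CompileError",
    "compile_circuit", "decompile", "validate", "render",
    "parse_circuit", "serialize",
    "seq", "branch",
]

#: opcodes taking a single term operand
_TERM_OPS = {"send", "receive", "join", "merge", "fire", "check", "emit", "act"}
#: opcodes taking no operand
_NULLARY_OPS = {"clear", "stop"}
#: opcodes taking a (source, recipient) link operand
_LINK_OPS = {"ltp", "ltd"}
#: environment predicates a check condition may name
_ENV_PREDICATES = {"on", "at"}

OPCODES = _TERM_OPS | _NULLARY_OPS | _LINK_OPS | {"choice", "wait"}


@dataclass(frozen=True)
class Instruction:
    """One virtual-machine instruction.

    ``op`` is the opcode; operands live in ``arg`` (a term), ``arg2``
    (second term of an ltp/ltd link target), ``var`` (the variable a
    ``choice`` binds) and ``alternatives`` (choice / wait alternatives).
    """

    op: str
    arg: Term | None = None
    arg2: Term | None = None
    var: str | None = None
    alternatives: tuple[Term, ...] = ()

    def __str__(self) -> str:
        if self.op in _NULLARY_OPS:
            return self.op
        if self.op in _LINK_OPS:
            return f"{self.op}({self.arg}, {self.arg2})"
        if self.op == "choice":
            alts = ", ".join(str(a) for a in self.alternatives)
            return f"choice({self.var}, [{alts}])"
        if self.op == "wait":
            alts = ", ".join(str(a) for a in self.alternatives)
            return f"wait([{alts}])"
        return f"{self.op}({self.arg})"


@dataclass
class Node:
    """An instruction-tree node; ``T`` is assigned at compile time."""

    instr: Instruction
    next: "Node | None" = None
    branches: dict[str, "Node | None"] = field(default_factory=dict)
    T: int = -1

    def __eq__(self, other: object) -> bool:  # structural, T-insensitive
        if not isinstance(other, Node):
            return NotImplemented
        return (self.instr == other.instr and self.next == other.next
                and self.branches == other.branches)


def seq(*instrs: Instruction | Node) -> Node | None:
    """Chain instructions/subtrees into a linear sequence."""
    head: Node | None = None
    tail: Node | None = None
    for item in instrs:
        node = item if isinstance(item, Node) else Node(item)
        if head is None:
            head = tail = node
        else:
            assert tail is not None
            tail.next = node
            tail = node
        while tail.next is not None:
            tail = tail.next
    return head


def branch(instr: Instruction, **branches: Node | None) -> Node:
    """Attach outcome-labelled subtrees to a branching instruction."""
    return Node(instr, branches=dict(branches))


@dataclass
class ThreadPattern:
    head: Term
    body: Node | None

    @property
    def name(self) -> str:
        return str(self.head)


@dataclass
class Circuit:
    name: str
    threads: list[ThreadPattern] = field(default_factory=list)
    links: list[Link] = field(default_factory=list)
    entries: list[Term] = field(default_factory=list)


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

class CompileError(ValueError):
    pass


@dataclass
class CompiledThread:
    head: Term
    root: Node | None
    nodes: list[Node]
    specificity: int

    @property
    def name(self) -> str:
        return str(self.head)


@dataclass
class CodeRepository:
    circuit_name: str
    threads: list[CompiledThread]
    links: list[Link]
    entries: list[Term]

    def candidates(self, head: Term) -> list[CompiledThread]:
        """Compiled variants matching *head*, most specific (ground) first."""
        from .terms import match
        out = [ct for ct in self.threads if match(ct.head, head) is not None]
        out.sort(key=lambda ct: ct.specificity)
        return out


def _walk_nodes(node: Node | None, depth: int, acc: list[Node]) -> None:
    if node is None:
        return
    node.T = depth
    acc.append(node)
    _walk_nodes(node.next, depth + 1, acc)
    for child in node.branches.values():
        _walk_nodes(child, depth + 1, acc)


def compile_circuit(circuit: Circuit) -> CodeRepository:
    """Compile a circuit into the repository of contextual implications.

    Every instruction node receives its ``(thread, T)`` index, where ``T``
    is the local time at which the node executes along its branch; ground
    and wildcard thread variants are tagged with their specificity so that
    deduction can prefer ground code.
    """
    diagnostics = validate(circuit)
    if diagnostics:
        raise CompileError("; ".join(diagnostics))
    compiled: list[CompiledThread] = []
    for tp in circuit.threads:
        nodes: list[Node] = []
        _walk_nodes(tp.body, 0, nodes)
        # overlapping equally specific patterns (which would make some
        # (thread, T) index ambiguous) were rejected by validate() above
        compiled.append(CompiledThread(tp.head, tp.body, nodes,
                                       specificity(tp.head)))
    return CodeRepository(circuit.name, compiled, list(circuit.links),
                          list(circuit.entries))


def decompile(code: CodeRepository) -> Circuit:
    """Reconstruct an equivalent circuit from compiled code."""
    return Circuit(
        code.circuit_name,
        threads=[ThreadPattern(ct.head, ct.root) for ct in code.threads],
        links=list(code.links),
        entries=list(code.entries),
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _iter_instrs(node: Node | None):
    if node is None:
        return
    yield node.instr
    yield from _iter_instrs(node.next)
    for child in node.branches.values():
        yield from _iter_instrs(child)


def validate(circuit: Circuit) -> list[str]:
    """Structural diagnostics; an empty list means compile will succeed."""
    from .terms import match

    diags: list[str] = []
    heads = [tp.head for tp in circuit.threads]
    sigs: dict[tuple[str, int], list[ThreadPattern]] = {}
    for tp in circuit.threads:
        sigs.setdefault((tp.head.functor, len(tp.head.args)), []).append(tp)
    for (fn, ar), tps in sigs.items():
        for i, a in enumerate(tps):
            for b in tps[i + 1:]:
                if specificity(a.head) != specificity(b.head):
                    continue  # ground/wildcard variants are ordered, not dups
                if (match(a.head, b.head) is not None
                        or match(b.head, a.head) is not None):
                    diags.append(
                        f"equally specific overlapping thread patterns "
                        f"{a.name} and {b.name}")

    def declared(pattern: Term) -> bool:
        return any(match(h, pattern) is not None or match(pattern, h) is not None
                   for h in heads)

    sends: list[Term] = []
    merge_posters: list[Term] = []  # heads of threads that post a merge
    for tp in circuit.threads:
        for ins in _iter_instrs(tp.body):
            if ins.op == "send":
                sends.append(ins.arg)
            elif ins.op == "merge":
                merge_posters.append(tp.head)

    for tp in circuit.threads:
        bound = variables(tp.head)
        for ins in _iter_instrs(tp.body):
            if ins.op == "choice":
                if not ins.alternatives:
                    diags.append(f"{tp.name}: choice with empty alternatives")
                if ins.var:
                    bound.add(ins.var)
            if ins.op == "check" and ins.arg is not None \
                    and ins.arg.functor not in _ENV_PREDICATES:
                diags.append(f"{tp.name}: check names undeclared predicate "
                             f"{ins.arg.functor}")
            if ins.op in ("receive", "join") and ins.arg is not None:
                # receive/join patterns are binding occurrences
                bound |= variables(ins.arg)
            if ins.op == "receive":
                has_link = any(
                    match(l.source, ins.arg) is not None
                    or match(ins.arg, l.source) is not None
                    for l in circuit.links)
                has_send = any(match(s, tp.head) is not None
                               or match(tp.head, s) is not None for s in sends)
                if not (has_link and has_send):
                    diags.append(f"{tp.name}: receive({ins.arg}) has no matching "
                                 f"send/link ending at this thread")
            if ins.op == "join":
                if not any(match(ins.arg, m) is not None
                           or match(m, ins.arg) is not None
                           for m in merge_posters):
                    diags.append(f"{tp.name}: join({ins.arg}) has no matching merge")
            for operand in (ins.arg, ins.arg2):
                if operand is not None:
                    for v in variables(operand) - bound:
                        diags.append(f"{tp.name}: unbound variable {v} in {ins}")
                        bound.add(v)  # report once

    for link in circuit.links:
        for endpoint in (link.source, link.recipient):
            if not declared(endpoint):
                diags.append(f"link endpoint {endpoint} names no declared thread")
    return diags


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render(circuit: Circuit) -> str:
    """Emit a DOT directed graph of the circuit.

    Synaptic links become edges labelled ``->=>-``; an ltp/ltd instruction
    modulating a link becomes an edge labelled ``/|\\`` into a small node
    standing for the modulated synapse.
    """
    lines = [f'digraph "{circuit.name}" {{']
    for tp in circuit.threads:
        lines.append(f'  "{tp.name}";')
    link_nodes: dict[tuple[str, str], str] = {}
    for link in circuit.links:
        key = link.pattern_key
        state = "open" if link.weight > link.threshold else "closed"
        mid = f"syn:{key[0]}->{key[1]}"
        link_nodes[key] = mid
        lines.append(f'  "{mid}" [shape=point, label="", comment="{state}"];')
        lines.append(f'  "{key[0]}" -> "{mid}" [label="->=>-"];')
        lines.append(f'  "{mid}" -> "{key[1]}";')
    for tp in circuit.threads:
        for ins in _iter_instrs(tp.body):
            if ins.op in _LINK_OPS:
                key = (str(ins.arg), str(ins.arg2))
                mid = link_nodes.get(key)
                if mid is None:
                    mid = f"syn:{key[0]}->{key[1]}"
                    link_nodes[key] = mid
                    lines.append(f'  "{mid}" [shape=point, label=""];')
                lines.append(f'  "{tp.name}" -> "{mid}" [label="/|\\\\", '
                             f'style=dashed];')
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------

class CircuitSyntaxError(ValueError):
    pass


def serialize(circuit: Circuit) -> str:
    out: list[str] = [f"circuit {circuit.name}", ""]

    def emit_block(node: Node | None, indent: int) -> None:
        pad = "  " * indent
        while node is not None:
            if node.branches:
                out.append(f"{pad}{node.instr} {{")
                for label, child in node.branches.items():
                    out.append(f"{pad}  {label}: {{")
                    emit_block(child, indent + 2)
                    out.append(f"{pad}  }}")
                out.append(f"{pad}}}")
            else:
                out.append(f"{pad}{node.instr}")
            node = node.next

    for tp in circuit.threads:
        out.append(f"thread {tp.head} {{")
        emit_block(tp.body, 1)
        out.append("}")
        out.append("")
    for link in circuit.links:
        out.append(f"link {link.source} -> {link.recipient} "
                   f"weight={link.weight} threshold={link.threshold} "
                   f"scope={link.scope}")
    if circuit.links:
        out.append("")
    for entry in circuit.entries:
        out.append(f"entry {entry}")
    return "\n".join(out).rstrip() + "\n"


def _parse_instruction(text: str) -> Instruction:
    text = text.strip()
    if text in _NULLARY_OPS:
        return Instruction(text)
    i = text.find("(")
    if i < 0 or not text.endswith(")"):
        raise CircuitSyntaxError(f"cannot parse instruction {text!r}")
    op, inner = text[:i], text[i + 1:-1].strip()
    if op not in OPCODES:
        raise CircuitSyntaxError(f"unknown opcode {op!r}")
    if op in _TERM_OPS:
        return Instruction(op, parse_term(inner))
    if op in _LINK_OPS:
        src, dst = _split_top(inner)
        return Instruction(op, parse_term(src), parse_term(dst))
    if op == "choice":
        var, rest = _split_top(inner)
        alts = _parse_list(rest)
        return Instruction(op, var=var.strip(), alternatives=alts)
    if op == "wait":
        return Instruction(op, alternatives=_parse_list(inner))
    raise CircuitSyntaxError(f"unhandled opcode {op!r}")


def _split_top(text: str) -> tuple[str, str]:
    depth = 0
    for i, ch in enumerate(text):
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
        elif ch == "," and depth == 0:
            return text[:i].strip(), text[i + 1:].strip()
    raise CircuitSyntaxError(f"expected two comma-separated operands in {text!r}")


def _parse_list(text: str) -> tuple[Term, ...]:
    text = text.strip()
    if not (text.startswith("[") and text.endswith("]")):
        raise CircuitSyntaxError(f"expected [..] list, got {text!r}")
    inner = text[1:-1].strip()
    if not inner:
        return ()
    parts: list[str] = []
    depth = 0
    start = 0
    for i, ch in enumerate(inner):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == "," and depth == 0:
            parts.append(inner[start:i])
            start = i + 1
    parts.append(inner[start:])
    return tuple(parse_term(p.strip()) for p in parts)


def parse_circuit(text: str) -> Circuit:
    """Parse the structured text format produced by :func:`serialize`."""
    lines = [ln.split("#", 1)[0].rstrip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    pos = 0

    def peek() -> str:
        return lines[pos].strip() if pos < len(lines) else ""

    def take() -> str:
        nonlocal pos
        ln = lines[pos].strip()
        pos += 1
        return ln

    if not peek().startswith("circuit "):
        raise CircuitSyntaxError("circuit file must start with 'circuit <name>'")
    name = take().split(None, 1)[1]
    circuit = Circuit(name)

    def parse_block() -> Node | None:
        """Parse instructions until a lone '}' (consumed)."""
        head: Node | None = None
        tail: Node | None = None
        while True:
            ln = take()
            if ln == "}":
                return head
            if ln.endswith("{"):
                instr = _parse_instruction(ln[:-1].strip())
                branches: dict[str, Node | None] = {}
                while peek() != "}":
                    lbl_line = take()
                    if not lbl_line.endswith(": {"):
                        raise CircuitSyntaxError(
                            f"expected '<label>: {{' inside branch block, got {lbl_line!r}")
                    label = lbl_line[:-3].strip()
                    branches[label] = parse_block()
                take()  # closing '}' of the branch block
                node = Node(instr, branches=branches)
            else:
                node = Node(_parse_instruction(ln))
            if head is None:
                head = tail = node
            else:
                tail.next = node
                tail = node

    while pos < len(lines):
        ln = take()
        if ln.startswith("thread "):
            rest = ln[len("thread "):].strip()
            if not rest.endswith("{"):
                raise CircuitSyntaxError(f"thread header must end with '{{': {ln!r}")
            head_term = parse_term(rest[:-1].strip())
            body = parse_block()
            circuit.threads.append(ThreadPattern(head_term, body))
        elif ln.startswith("link "):
            rest = ln[len("link "):]
            lhs, rhs = rest.split("->", 1)
            fields = rhs.split()
            dst = parse_term(fields[0])
            kv = dict(f.split("=", 1) for f in fields[1:])
            circuit.links.append(Link(
                source=parse_term(lhs.strip()),
                recipient=dst,
                weight=float(kv.get("weight", 0.0)),
                threshold=float(kv.get("threshold", 0.5)),
                scope=kv.get("scope", "ground"),
            ))
        elif ln.startswith("entry "):
            circuit.entries.append(parse_term(ln[len("entry "):].strip()))
        else:
            raise CircuitSyntaxError(f"unexpected line {ln!r}")
    return circuit
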