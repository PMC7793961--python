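"""Seeded random generator of small, valid, linear-bodied circuits.

Used both for the compile/serialize round-trip properties and for the
equivalence check against the brute-force oracle interpreter.  Threads
form a forest rooted at the entry thread: every receive has a matching
send over a declared link (open or closed at random), and an optional
merge/join pair exercises the coincidence detector.
"""

from __future__ import annotations

import numpy as np

from mesovm.circuit_lang import Circuit, Instruction, Node, ThreadPattern, seq
from mesovm.plasticity import Link
from mesovm.terms import Term, parse_term


def random_linear_circuit(seed: int) -> Circuit:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 5))  # 2..4 threads
    names = [f"t{i}" for i in range(n)]
    c = Circuit(f"random_{seed}")

    bodies: dict[str, list[Instruction]] = {name: [] for name in names}
    parents = {}
    for j in range(1, n):
        i = int(rng.integers(0, j))
        parents[j] = i
        weight = float(rng.choice([0.0, 1.0]))
        c.links.append(Link(Term(names[i]), Term(names[j]), weight=weight))
        bodies[names[i]].append(Instruction("send", Term(names[j])))
        bodies[names[j]].append(Instruction("receive", Term(names[i])))

    use_join = bool(rng.integers(0, 2)) and n >= 2
    if use_join:
        # entry posts a marker; one child waits for it
        j = int(rng.integers(1, n))
        bodies[names[0]].insert(0, Instruction("merge", Term(names[j])))
        bodies[names[j]].append(Instruction("join", Term(names[0])))

    for name in names:
        for _ in range(int(rng.integers(0, 3))):
            stim = str(rng.choice(["excite", "inhibit"]))
            bodies[name].append(Instruction("emit", parse_term(stim)))

    for name in names:
        body = bodies[name][:6]  # at most 6 instructions per thread
        c.threads.append(ThreadPattern(Term(name), seq(*body) if body else None))
    c.entries = [Term(names[0])]
    return c
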