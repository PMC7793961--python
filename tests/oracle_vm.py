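"""An independent brute-force interpreter used as an oracle.

This interpreter executes small circuits by expanding the global machine
state directly — a flat list of thread instances, each holding its linear
instruction list and a cursor — under the same canonical scheduling rules
the kernel documents (round-robin in creation order, one instruction per
pass, retry on failure, halt on a no-progress pass).  It shares no code
with the kernel: circuits are consumed as plain object graphs, instruction
trees are flattened to lists, and gating/marker bookkeeping is
reimplemented from scratch.  It supports the messaging core only
(send / receive / emit / fire / merge / join) over static weights, which
is all the randomly generated equivalence circuits use.
"""

from __future__ import annotations

from mesovm.terms import match, parse_term, specificity, substitute


def _flatten(node):
    out = []
    while node is not None:
        if node.branches:
            raise ValueError("oracle supports linear bodies only")
        out.append(node.instr)
        node = node.next
    return out


class _Instance:
    def __init__(self, head, instrs, bindings):
        self.head = head
        self.instrs = instrs
        self.bindings = dict(bindings)
        self.pc = 0


def brute_force_trace(circuit, stimuli):
    """Run *circuit* on cycle-0 stimuli; return [(seq, thread, stimulus)]."""
    patterns = [(tp.head, _flatten(tp.body)) for tp in circuit.threads]
    links = [(l.source, l.recipient, l.weight, l.threshold)
             for l in circuit.links]

    instances: list[_Instance] = []
    queues: dict[tuple[str, str], int] = {}
    reported: dict[tuple[str, str], int] = {}
    markers: list[str] = []
    events: list[tuple[int, str, str]] = []

    def spawn(head):
        best = None
        for phead, instrs in patterns:
            b = match(phead, head)
            if b is None:
                continue
            s = specificity(phead)
            if best is None or s < best[0]:
                best = (s, instrs, b)
        if best is None:
            raise LookupError(f"no pattern for {head}")
        instances.append(_Instance(head, best[1], best[2]))

    def weight_for(src, dst):
        best = None
        for ls, lr, w, thr in links:
            b = match(ls, src)
            if b is None or match(lr, dst, b) is None:
                continue
            s = specificity(ls) + specificity(lr)
            if best is None or s < best[0]:
                best = (s, w, thr)
        if best is None:
            raise LookupError(f"no link {src} -> {dst}")
        return best[1], best[2]

    for stim in stimuli:
        for entry in circuit.entries:
            if match(entry, stim) is not None:
                spawn(stim)
                break

    for _ in range(10_000):
        progress = False
        for inst in list(instances):
            if inst.pc >= len(inst.instrs):
                continue
            ins = inst.instrs[inst.pc]
            ok = False
            if ins.op == "send":
                target = substitute(ins.arg, inst.bindings)
                key = (str(inst.head), str(target))
                queues[key] = queues.get(key, 0) + 1
                spawn(target)
                ok = True
            elif ins.op == "receive":
                pattern = substitute(ins.arg, inst.bindings)
                for (src_s, dst_s), count in queues.items():
                    if count <= 0 or dst_s != str(inst.head):
                        continue
                    src = parse_term(src_s)
                    extra = match(pattern, src)
                    if extra is None:
                        continue
                    w, thr = weight_for(src, inst.head)
                    if w > thr:
                        queues[(src_s, dst_s)] = count - 1
                        inst.bindings.update(extra)
                        ok = True
                    elif reported.get((src_s, dst_s), 0) < count:
                        reported[(src_s, dst_s)] = \
                            reported.get((src_s, dst_s), 0) + 1
                        events.append((0, str(inst.head), "inhibit"))
                    break
            elif ins.op == "emit":
                events.append((0, str(inst.head),
                               str(substitute(ins.arg, inst.bindings))))
                ok = True
            elif ins.op == "fire":
                spawn(substitute(ins.arg, inst.bindings))
                ok = True
            elif ins.op == "merge":
                markers.append(str(inst.head))
                ok = True
            elif ins.op == "join":
                pattern = substitute(ins.arg, inst.bindings)
                for i, poster in enumerate(markers):
                    extra = match(pattern, parse_term(poster))
                    if extra is not None:
                        del markers[i]
                        inst.bindings.update(extra)
                        ok = True
                        break
            else:
                raise ValueError(f"oracle does not implement {ins.op}")
            if ok:
                inst.pc += 1
                progress = True
        if not progress:
            break
    return events
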