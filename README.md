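# mesovm

A meso-scale virtual machine for asynchronous neural micro-circuits, and a
simulated thought experiment in which a vehicle driven by such a circuit
learns causality rules from synchronized multimodal percepts.

## The problem

How can a behavior that starts out random become deterministic through
learning, without the designer wiring the answer in?  `mesovm` models
neural assemblies as *threads* — concurrently executing instruction trees
that communicate over weighted, threshold-gated links.  A link is **open**
when its weight exceeds the threshold and **closed** otherwise; long-term
potentiation and depression (`ltp`/`ltd`) move weights across the gate,
so learning is pathway switching: *inhibition enabling disinhibition*.
Plasticity is triggered by a coincidence detector (a `join`/`merge`
protocol): two internal stimuli count as synchronized exactly when they
are emitted under the same stream sequence number `I` — the meso-scale
clock of one activation episode — while each thread advances its own local
clock `T` one tick per successfully executed instruction (failed
instructions are retried, not advanced).  The machine runs a
sense–act–reflect cycle: capture external stimuli, execute one deterministic
round-robin pass over runnable threads, report the synchronized events
`(I, thread, stimulus)` of the cycle.

The thought experiment: a vehicle on a bidirectional 7-position track
perceives the smoke of a fire at coordinate `F(X)` (`F` = right/left) and
must reach it using a forward or backward gear.  Spatial percepts and gear
choices are different modalities — nothing in the circuit says that
*forward goes right*.  A non-plastic stochastic decision tree searches at
random.  Embedding an operant-conditioning fork into it lets `synchro`
threads — fired when the fire percept `check(on(F(X)))` and the track
percept `check(at(...))` excite under the same `I` — potentiate a
`recall` pathway and depress the `learn` pathway, so the vehicle acquires
either instantiated rules ("if detect(right(3)) then move(forward)", one
coordinate at a time) or, with wildcard-scoped links, the general rule
("if detect(right(_)) then move(forward)") that transfers to every
coordinate of the direction.

## Worked example

The wrong-direction search: fire at right(3), gear forced to backward.

```sh
mesovm run --circuit random_detector --fire "right(3)" --choice backward
```

```
0: sense(right(3)):fetch(backward)
1: detect(right(3)):inhibit
1: move(backward):excite
2: detect(right(3)):inhibit
2: move(backward):excite
...
8: detect(right(3)):inhibit
8: move(backward):excite
9: detect(right(3)):inhibit
9: move(backward):inhibit
9: move(backward):stop
outcome: missed  fetch_count: 1  synchro: []
```

Tick 0 is the random gear fetch.  At each tick 1–8 the detect thread
inhibits (no fire on this side) while the move thread excites (the track
continues) and the vehicle steps left; at tick 9 the move thread's own
inhibit signals the track limit and stops the run.  The fire was missed and
no synchronized excite pair ever occurred.

The full learning program — random search both ways, instantiated learning
at right(3) with its replay and its failure at right(2), then generalized
learning with transfer to right(5):

```sh
mesovm figures
```

The replay run (`fig15`) prints `fetch=0` — the learned `recall` pathway
routes the gear choice deterministically — and opens with the repeated
inhibit of the two still-closed pathways at tick 1:

```
1: recall(backward):inhibit
1: learn(right):inhibit
1: detect(right(3)):inhibit
1: move(forward):excite
...
4: detect(right(3)):excite
4: detect(right(3)):clear
4: move(forward):excite
```

The two simultaneous excites at tick 4 are the synchronized multimodal
perception; `clear` removes the fire at the same tick.  In general mode
(`fig17`/`fig18`) the weight changes land on the wildcard links
`(sense(right(_)), recall(forward))` and `(sense(right(_)), learn(right))`,
after which a fire at *any* right coordinate is found without a fetch.

Circuits can also be written by hand in a small text format
(`mesovm export --circuit deterministic_detector --mode general` prints
one), rendered to DOT (`mesovm render ...`), and run from YAML scenario
files (`mesovm run --scenario scen.yaml`).

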