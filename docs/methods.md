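# Methods

## Model

`mesovm` simulates neural circuits at a deliberately abstracted meso
scale.  A *thread* stands for a neuron or a neural assembly; it is a named,
possibly parameterized pattern (`detect(F(X))`) enclosing a finite tree of
instructions.  Threads communicate asynchronously: `send` posts a signal
on a directed link and fires the recipient; `receive` consumes one queued
signal but only if the link is open (`weight > threshold`), otherwise it
fails and is retried.  There are no membrane equations, no spike timing
curves, and no summation of inputs — each input is processed individually,
and synaptic plasticity is reduced to a coincidence detector:

* `merge` posts a marker stamped with the current stream sequence number;
* `join` succeeds only against a marker with the *same* stream sequence
  number (the synchronization window), after which `ltp`/`ltd`
  instructions may add `delta_plus` to or subtract `delta_minus` from a
  weight.

Two clocks coexist.  Each thread activation owns a local clock `T`,
incremented by exactly 1 per successfully executed instruction; the
compiled code is indexed by `(thread, T)`, and execution is deduction of
the instruction at the current index, preferring ground (instantiated)
code over wildcard code.  Each stream — one activation episode rooted at a
sense thread — owns a sequence number `I`, advanced only when the body
acts on the world (gear engagement, one per movement step).  The reflect
step reports events `(I, thread, stimulus)`; equality of `I` *is* the
definition of simultaneity, which makes the plasticity trigger independent
of micro-scheduling detail.

## Scheduling and determinism

The threads are logically concurrent with no central clock.  For
reproducibility the kernel executes deterministic round-robin passes over
runnable activations in creation order, one instruction per activation per
pass.  Failed instructions stay put and are retried.  A run halts on an
explicit `stop`/`clear` (effective at the end of the pass, so simultaneous
percepts of the final tick are still reported, and with `fire`, `act`,
`choice` then disabled so in-flight `merge`/`join`/`ltp`/`ltd` chains can
drain to quiescence), on a pass that makes no progress with no input
pending (a sound fixed point: state changes only through successful
instructions or sensing), or at `max_cycles` passes, reported distinctly
as truncation.  The only randomness is the `choice` instruction, drawn
from one seedable generator; scenarios may force the outcome instead, and
with a fixed seed or forced choices a run is a pure function of (circuit,
scenario).

Perceptual checks are sampled once per stream tick: a `check` re-attempted
by the same thread name under an unchanged `I` fails until the tick
advances.  This keeps exactly one detect event and one move event per
tick, whatever the relative lengths of their instruction loops.

## Tick accounting on the track

The stream sequence calibration follows the printed traces of the runs the
package reproduces: the random/learned gear decision is tick 0; engaging
the gear advances to tick 1; every movement step advances the tick.  The
move thread validates the coordinate it currently occupies (not the one it
is heading to), so leaving the last defined coordinate is the overrun step
onto `F(length+1)`, discovered and reported one tick later.  On the
default 7-position track a wrong-direction run therefore shows
detect-inhibit/move-excite pairs at ticks 1–8 and the terminal move
inhibit at tick 9.  A consequence is that `move_step` permits exactly one
step beyond `F(length)`; a second one raises a contract violation.  A
signal arriving over a closed link surfaces as a single inhibit event per
queued signal (later retries are silent), which is how the replay run
shows the closed `learn` and `recall(backward)` pathways as a repeated
inhibit at tick 1.  The homeward return trip after a run consumes no
stream ticks and is not traced; each scenario starts with a fresh world.

## Parameters

| parameter | default | meaning |
|---|---|---|
| threshold | 0.5 | gate: link open iff weight > threshold (dimensionless) |
| closed / open initial weight | 0.0 / 1.0 | declared per link in the circuit file |
| `delta_plus`, `delta_minus` | 1.0 | ltp/ltd step; one coincidence flips a pathway |
| track length | 7 | coordinates per direction, `X = 1..7`, home at 0 |
| `max_cycles` | 500 | scheduler-pass bound; every library scenario ends well below it |

The binary open/closed regime with single-step flips reproduces one-shot
pathway switching; a slower acquisition (k pairings to learn) is expressed
by setting `delta_plus = 1/k` on the link table.

## The environment as synthetic data

The vehicle world is the package's data generator: it emulates the
configured study conditions — a 1-D track, a single fire with its smoke,
binary percepts, noiseless actuation — and nothing else.  The smoke
percept activates the sense thread instantiated at the fire's coordinate;
it carries no gear information, so the mapping forward→right /
backward→left remains hidden environmental ground truth that only the
synchronization of the two modalities can reveal.  Passing tests
therefore show that the learning mechanism is sound under these idealized
conditions; they say nothing about noisy sensors, continuous space,
multiple simultaneous stimuli per modality, or real-time actuation, none
of which are modelled.  The figure-replay driver forces the gear choices
to the outcomes the canonical runs drew, so the printed behavior is
replayed exactly; the fairness of the unforced choice is checked
separately over 2000 seeded runs against a binomial band (50% ± 3%).

## Design choices where the design was open

* **Unknown external stimuli** are logged and dropped rather than raised:
  sensors may fire with no listener in larger circuits.  The reserved
  outcome stimuli `positive`/`negative` are buffered for `wait` instead.
* **ltd trigger**: depression fires on the same coincidence event as
  potentiation, aimed at the complementary (learn) pathway.  A negative
  outcome stimulus drives the symmetric case (ltp of reject, ltd of
  learn).  No depression occurs on non-coincidence, and a failed search
  run changes no weight.
* **After clearing the fire** the run stops by default
  (`stop_after_clear=True`); continuing to the track limit is available
  per scenario.
* **Instruction trees are finite**; loops are expressed by a thread
  re-firing itself, which creates a fresh activation with a fresh local
  clock, keeping every activation's clock strictly monotone.
* **Opcode set**: the figures' protocols need `send`, `receive`, `join`,
  `merge`, `fire`, `choice`, `check`, `wait`, `emit`, `act`, `clear`,
  `stop`, `ltp`, `ltd`.  `act` covers motor actions (engage, step) and is
  the only place the stream tick advances; `wait` implements the operant
  fork's discrimination of outcome stimuli.

## Numerical and degenerate cases

Weights are plain floats; all comparisons are strict (`>` against the
threshold), so the default integer-valued steps never sit on the
boundary.  An empty circuit runs to an empty trace and a quiescent halt.
Equally specific overlapping thread patterns are a compile error (the
`(thread, T)` index would be ambiguous); ground and wildcard variants of
the same head are legal and ordered ground-first.  Queue counts are
conserved (receives never exceed sends) and audited at run time, as are
clock monotonicity and the openness of every gate actually crossed.

## Verification

The kernel is checked against an independent brute-force interpreter that
re-implements the documented scheduling rules from scratch and must match
the kernel trace event-for-event on randomly generated circuits of up to
4 threads and 6 instructions each.  The text circuit format round-trips
(`parse ∘ serialize = id`) over the library and random circuits, as does
compilation (`decompile ∘ compile`).  Problem sizes in the test suite —
the 7-position track, 2000 calibration runs, 40 random oracle circuits —
keep the full suite in the low seconds on one CPU.

## Known limitations

Space is one-dimensional and discrete; one fire and one vehicle; percepts
and actions are noiseless and binary; plasticity is a step function with
no eligibility traces, no reward-prediction error and no forgetting;
thread scheduling, though faithful to the asynchronous semantics, is a
fixed canonical order rather than a sampled interleaving.
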