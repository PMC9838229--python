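# Methods

`virtcog` simulates *symbolic neural dynamics*: micro-circuits whose
units are **threads** (a neuron or a cluster of neurons) grouped into
disjoint **streams** (neural assemblies), communicating asynchronously
through weight-gated signals. Circuits are compiled into guarded rules
("virtual code implications") that a deterministic sense–react virtual
machine uses just in time to deduce its next instructions (**contextual
deduction**, the `ist` predicate, `run : I × L → L × O`). There is no
designated final state: whatever state the machine reaches stands for
the simulated subject's current state of mind.

## The model

### Terms and variables

All content — stimuli, thread instances, actions, memories — is
first-order terms. Space is a one-dimensional integer axis; an object
percept is `obj(Image, Position)` and box contents are
`box(BoxId, Contents, Position)` (the applied-variable notation
"image at position" is deliberately encoded first-order to keep
unification standard and decidable). The only arithmetic is the
integer offset `X+k` (in practice `X+1`, the saccade-anticipation
convention), evaluated eagerly whenever the base is bound; an
unevaluable offset simply fails to match. There is no occurs-check:
circuit guards are shallow and the DSL cannot build cyclic terms.

Named variables (`X`, `P`) may be rebound per rule instance; anonymous
variables (`_`) may be matched but the binding is consumed and never
recorded — two `_` occurrences never co-refer. This distinction
carries the whole weak/strong plasticity contrast (below).

### Substrate

Weights are non-negative integers on (stream, sender, receiver) triples,
with one absorbing extra state `BLOCKED` that nothing restores. A
queued signal is delivered only when its pathway's weight reaches the
threshold θ. Direct signalling never crosses streams; only the
associative store does.

Coincidence detection is a join/merge rendezvous: a *join* registered
at cycle j pairs with a *merge* posted at cycle m iff
|j − m| ≤ window − 1, each merge consumed by at most one join, FIFO.

### Plasticity

| protocol | effect | timescale |
|---|---|---|
| STP | pathway reads θ for `duration` cycles, then closes | immediate, transient |
| LTP | +1 per detected coincidence | consolidated at end of cycle |
| LTD | −1 (floor 0) | consolidated at end of cycle |
| LTS | append a ground trace `{P}` to the associative store | immediate |
| LTR | newest-first retrieval; +1 on Q→R and fire R with the bindings | fire immediate, weight deferred |
| LTB | pathway → `BLOCKED`, permanently | end of cycle |
| STM | per-tag FIFO `<t>` of ground terms, popped oldest-first | until consumed |

**Weak vs strong LTP.** Strong mode keys the learned weight by receiver
template and rebinds on every activation — the same input can be
associated with successive different reactions. Weak mode freezes the
receiver's ground instance at first potentiation; thereafter any
delivery on that pathway re-produces the frozen instance, and an
attempted potentiation with a different instance is denied (the new
instance finds weight 0). This single mechanism, isolated in the
weight table's receiver key, is what produces the A-not-B error.

### Timing

One cycle = one sense–react step. All stimuli stamped for the cycle
fire their sensors; react then iterates passes (limit 8): deliver
queued signals, compute `ist` over the pre-pass snapshot, apply every
deduced instruction; a pass with no deliveries and no deductions is the
fixpoint. Within `ist`, rules are tried in rule-base order and facts
in arrival order; each consumable fact is consumed at most once; a
*choice group* admits one deduction per cycle, first declared wins.

Two deliberate timescale choices matter for the simulations:

* **Consolidation is deferred.** LTP/LTD/LTB take effect at end of
  cycle, while STP opens immediately. A pathway learned in cycle t
  gates deliveries only from t+1 on, which is why a first, unreinforced
  trial can never already exploit its own outcome.
* **Signals outlive one cycle.** An undelivered signal survives
  `signal_ttl = 1` extra cycle. The disappearance signal posted in the
  cycle of a first hiding is therefore still deliverable in the next
  cycle, after its pathway consolidated — producing the first
  successful search without any extra stimulus.

Conjunction (`*` connectors) requires all converging signals to have
been *posted* in the same cycle — temporal coincidence of the percepts
themselves, not of their (possibly delayed) deliveries.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` θ | 1 | minimum weight for delivery (per-edge override `theta=`) |
| `signal_ttl` | 1 | extra cycles an undelivered signal survives |
| `coincidence_window` | 1 | join/merge window; 1 = same cycle (per-annotation override) |
| `pass_limit` | 8 | react passes per cycle before flagged truncation |
| `plasticity` | strong | global weak/strong mode, fixed per run |
| `stp_duration` | 1 | cycles an STP opening lasts |
| `max_cycles` | 200 | run truncation guard |

"Open at start" pathways initialize at weight 1, "closed" at 0 — the
smallest integers realizing the operant circuit's baseline
(exploration open, both responses inhibited). LTP/LTD deltas are ±1.
The screen-search pathway learned in observation 55 carries `theta=2`:
with ±1 deltas, this is what makes the apprenticeship take the stated
two failed repetitions rather than one, and what makes a fresh model
given only the phase-III protocol fail the screen search.

## The synthetic world

The `world` module is the experimental chamber: a 1-D axis with movable
objects, occluding screens and lidded boxes. Scenario scripts emit the
stimulus vocabulary (`view/move/see/halt/stop/open/close/spot`) on a
fixed schedule and mutate the world. The experimenter's covert
manipulations (tipping the box out under a screen) are world mutations
*without* stimuli — the subject never senses them, which is precisely
what makes the displacement invisible. Effector actions convert back
into stimuli with a latency of exactly one cycle: `search` at a hiding
screen uncovers (`view`), at an empty one fails (`fail`); `open`
reveals box contents (`spot(box(F,C,X))`, `empty` when bare); `grasp`
takes a visible object into the hand.

Built-in scripts use 1-cycle inter-event spacing and +1 motion steps;
an object's visible vanishing is scripted as the co-occurrence of
`see(occluder)` and `stop(object)` in one cycle (one event, two
aspects). In the box observations, the `halt` stimulus — attention
settling on the resting scene — is scripted only when an episode ends
without the box re-emerging, or after a failed box search; when the box
comes back out, it captures attention instead. Observation 55 defaults
to 2 phase-I repetitions; observation-64 runs use strong plasticity
(the substage-6 subject has corrected the A-not-B error).

What the generator does *not* emulate: 2-D/3-D space, motion physics,
noisy or partial perception, multiple objects competing for attention,
reaction-time variability, and any stochasticity at all. Passing tests
therefore show that the circuit mechanisms *suffice to generate* the
qualitative behavioral signatures under idealized schedules — not that
they quantitatively fit infant data.

## Circuit realizations

The five substage circuits form a strict extension chain
(`substage3 ⊂ substage4 ⊂ substage5 ⊂ substage6`), each realized from
its narrative description; the concrete DSL syntax and the naming are
ours (see `docs/circuit-dsl.md`). Three realization choices were
genuinely open and are worth recording:

* **A-not-B potentiation pair.** The look-at-occluder event and the
  stop-out-of-sight event form the coincidence that potentiates
  look→search. The receiver instance frozen by weak mode is the search
  at the first hiding place, so the second hiding re-triggers exactly
  that search.
* **Observation 55's learned driver.** The learned edge is
  halt→search — the suspended-attention thread drives the search — with
  its binding popped from the FIFO `<look(Q,Y)>` memory, and the
  operant coincidence pair is (box-found-empty, remembered look) over
  an episode-length window (12 cycles). This keeps the prepotent box
  search intact through phase III (the infant still searches the box
  first) while the screen search is appended after failure.
* **Observation 64's retrieval drivers.** Box opening is driven by
  LTR(image, view-of-box-at-rest, open); renewed searches are driven by
  LTR through an evocation thread fed by `halt` and `fail`, with the
  search position popped from the FIFO. The retrieval-only search
  pathway carries a high gate (`theta=9`): it transmits through
  associative retrieval, not through plain accumulated weight, so each
  trigger event yields exactly one pop and the two-screen search stays
  sequential.

## Numerical/degenerate-input choices

* Unification failure is a value, never an exception (including arity
  clashes); unmatched stimuli are dropped and logged.
* Firing is idempotent within a cycle per (template, instance);
  non-ground activations are dropped with a trace note.
* Popping an empty FIFO returns an empty marker; storing a non-ground
  trace is a protocol error.
* Pass-limit and cycle-limit truncations are flagged in the trace, not
  raised.
* Trace canonicalization renames fresh variables `v1, v2, …` in first
  appearance order, so traces are byte-comparable across runs.

## Limitations

* The weak/strong distinction is binary and global per run; no gradual
  maturation is modeled.
* The associative store never decays and has no capacity limit; STM
  entries persist until consumed.
* Choice between converging alternatives is resolved by declaration
  order — deterministic, but a modeling convention, not a claim about
  neural arbitration.
* The world is single-agent and noiseless; scripts fully determine
  every run, which is what makes golden-trace regression possible but
  also means no variability statistics can be produced.
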