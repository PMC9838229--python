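# virtcog

Symbolic neural dynamics on a deterministic sense–react virtual
machine: a computational account of how the action schemas of early
sensory-motor development — up to object permanence and the first
mental representations — can be grounded in abstract neural circuits.

`virtcog` is for computational-cognition researchers and modelers who
want executable, inspectable versions of classic developmental
phenomena (the A-not-B error, invisible-displacement search) built
from a small set of neurally motivated primitives rather than fitted
parameters.

## The model in brief

The substrate is a set of **threads** (abstracted neurons/clusters)
partitioned into **streams** (assemblies), exchanging asynchronous
signals gated by integer weights: delivery requires
weight(P→Q) ≥ θ. Circuits wire threads with typed connectors —
synapse `->=>-`, modulation `/|\`, conjunction `*`, divergence/choice
`+` — and are compiled into guarded rules (*virtual code
implications*). The machine implements

    run : I × L → L × O

repeating a sense–react cycle: capture stimuli (language *I*), deduce
instructions from the compiled model (language *L*) by contextual
deduction (`ist`), apply them, emit effector actions (language *O*).

Synaptic change is abstracted by protocol threads: short-term
potentiation (transient opening), long-term potentiation/depression
(±1 per detected coincidence, via a join/merge rendezvous), long-term
storage/retrieval `{P}` (an associative memory relating threads of
separate streams), long-term blocking (absorbing closure), and a FIFO
short-term memory `<t>`. *Weak* LTP freezes a pathway on its first
ground instantiation (anonymous-variable semantics); *strong* LTP
rebinds per activation — that single distinction separates the
perseverative A-not-B error from correct sequential search.

## Worked example

```python
from virtcog import run_experiment, compare_traces

weak = run_experiment("anotb_weak")
strong = run_experiment("anotb_strong")
print([(a.cycle, str(a.term)) for a in weak.actions])
diff = compare_traces(weak.trace, strong.trace)
print(diff["left"], "|", diff["right"])
```

prints

```
[(3, 'look(obj(s1, 3))'), (4, 'search(obj(s1, 3))'), (5, 'grasp(obj(toy, 3))'),
 (9, 'look(obj(s2, 7))'), (9, 'search(obj(s1, 3))')]
9	fire	search search(obj(s1,3)) | 9	fire	search search(obj(s2,7))
```

Reading it: the toy is hidden under screen s1 at position 3; the
subject looks, searches there, and grasps it. After the second,
perfectly visible hiding under s2 at position 7, the weakly potentiated
model still searches position 3 — the A-not-B error — while the strong
model searches position 7. The two traces are byte-identical up to
exactly that search instantiation, the machine's rendering of "the
unfeasibility of binding a second pair of related inputs".

Ten experiments are registered (`virtcog list-experiments`): classical
conditioning, operant conditioning (both reinforcements), the grasping
reflex, visual tracking (halt and occlusion), the A-not-B pair, and
the two box-and-screen observations of partially/fully invisible
displacement. Each checks its behavioral assertions; `examples/` has
one narrative script per capability, and `docs/methods.md` /
`docs/circuit-dsl.md` document the model and the circuit language.

The command line mirrors the library:

```
virtcog run-experiment obs64                 # exit 0 iff assertions pass
virtcog run --circuit c.vcir --script s.yaml --plasticity weak
virtcog compile substage4                    # pretty-print the rule base
virtcog gen-scenario anotb                   # emit a scenario as YAML
virtcog regress goldens/                     # golden-trace regression
```

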