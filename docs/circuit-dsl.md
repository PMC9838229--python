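# The circuit DSL (`.vcir`)

Circuits are line-oriented text: one declaration per line, `#` starts a
comment, patterns are written without spaces. Declaration order is
semantic: compiled implications keep it, and choice groups resolve by
it (first declared, first matched).

```
circuit <name>
stream <id>
node <kind> <stream> <name> <pattern> [latch]
edge <type> <src>[,<src>...] <target> [opt=value ...]
stp  <from> <to> trigger=<node> [duration=N]
ltp  <from> <to> trigger=<node> partner=<node> [window=N] [mode=weak|strong]
ltd  <from> <to> trigger=<node> [partner=<node>] [window=N]
lts  <node>
ltr  <from> <to> trigger=<node> pattern=<term> [when=<term>] [stm=<tag> stmwhen=<term>]
ltb  <from> <to> trigger=<node>
stm-push <tag> <node>
```

## Nodes

`kind` is `sensor` (fired by matching stimuli), `internal`, or
`effector` (firing emits an action). The pattern is the thread's
template; variables shared between the patterns of an edge's endpoints
carry the data flow. `latch` makes an internal node stateful: its most
recent instance persists across cycles (used for the focus of
attention) and is read, not consumed, by guards.

## Connectors

* `edge synapse A B` — the synapse `A ->=>- B`. Weight-gated: the
  signal delivers when weight(A→B) ≥ θ.
* `edge conj A,B C` — convergence `*`: all sources must have posted in
  the same cycle with unifiable shared variables.
* Divergence `+` (splitting) is simply several edges sharing a source.
* A choice `+` between converging alternatives is a set of edges
  sharing `group=<g>`: per cycle at most one member fires, the first
  declared whose guard matches.
* Modulation `/|\` of a synapse is expressed by the plasticity
  annotation attached to it (`stp`/`ltp`/`ltd`/… with the edge as its
  target): the protocol thread acting on the pathway.

### Edge options

| option | meaning |
|---|---|
| `weight=1` or `weight=A:0,B:1` | initial weight(s); 1 = open, 0 = closed (default 1) |
| `theta=N` | per-edge delivery threshold (default: global θ) |
| `bind=X:cs` | constant bindings applied to the target pattern |
| `as=<term>` | target firing pattern override (e.g. `as=focus(obj(P,Y+1))`) |
| `when=<src>:<term>` | guard-pattern override for one source (repeatable) |
| `group=<g>` | choice group |
| `stm=<tag>` | the target's binding is popped from that FIFO memory |
| `stmwhen=<term>` | pattern the popped entry must match (defaults to the pushing node's pattern) |

## Plasticity annotations

All annotations name the pathway they act on as `<from> <to>` (it must
be a declared edge) and the node whose firing triggers them.

* `stp` opens the pathway to θ for `duration` cycles, immediately.
* `ltp`/`ltd` with a `partner=` are coincidence-gated: the trigger
  registers a join, the partner posts a merge; each pairing within the
  window adjusts the weight by ±1 at end of cycle. When the edge's own
  sender is one of the two participants, its bound instance is what a
  weak-mode potentiation freezes. `ltd` without a partner depresses on
  every trigger firing.
* `lts <node>` stores the node's fired (ground) instance as a trace
  `{...}` in the associative store.
* `ltr` is fired by its trigger, retrieves the newest stored trace
  unifying with `pattern=` (seeded by the trigger's bindings),
  potentiates the pathway and fires the target with the retrieval
  bindings — or, with `stm=`, with the head popped from that FIFO.
  Retrieval is non-destructive and refuses blocked pathways.
* `ltb` sets the pathway to `BLOCKED`, permanently.
* `stm-push <tag> <node>` appends the node's fired instance to the
  FIFO `<tag>`.

## Example

```
circuit relay
stream s
node sensor s cue cue(X)
node sensor s alert alert
node effector s act act(X)
edge synapse cue act weight=0
stp cue act trigger=alert duration=1
```

`cue(7)` alone does nothing (weight 0); `cue(9)` in the same cycle as
`alert` delivers and emits `act(9)`. The built-in circuits in
`virtcog.experiments.CIRCUITS` are the substantial reference examples;
`virtcog compile <name>` pretty-prints any of them as numbered
implications.
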