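"""The sense-react virtual machine.

``run : I x L -> L x O`` — the machine repeatedly captures stimuli
(language *I*) directed at sensor threads, uses the compiled rule base
(language *L*) to deduce instructions via contextual deduction (``ist``),
applies the state transitions, and emits effector actions (language
*O*).  There is no designated final state: whatever state the machine is
in represents the simulated subject's current state of mind.

Timing model (one *cycle* = one sense-react step):

* sense: all stimuli stamped for the cycle fire their matching sensors.
* react: up to ``pass_limit`` passes; each pass first attempts delivery
  of queued signals (weight-gated), then computes ``ist`` over the
  pre-pass snapshot and applies every deduced instruction.  A pass with
  no deliveries and no deductions is a fixpoint.
* end of cycle: coincidence (join/merge) pairs are resolved and LTP/LTD/
  LTB weight changes are **consolidated** — synaptic consolidation is
  slower than signal transmission, so a weight learned in a cycle gates
  deliveries only from the next cycle on.  STP, in contrast, opens
  pathways immediately (a transient effect).  Undelivered signals
  survive ``signal_ttl`` extra cycles, then expire.

Everything is deterministic: repeated runs of the same (circuit, script,
config) triple produce byte-identical canonical traces.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .compiler import (
    Annotation,
    DeliveredCond,
    Fact,
    FireOp,
    JoinOp,
    LtbOp,
    LtdOp,
    LtrOp,
    LtsOp,
    MergeOp,
    RuleBase,
    StmPopOp,
    StmPushOp,
    StpOp,
    ist,
)
from .plasticity import AssociativeStore, ProtocolError, ShortTermStore, StpOverlay
from .substrate import (
    BLOCKED,
    CoincidenceRegistry,
    Signal,
    SignalQueue,
    ThreadInstance,
    ThreadTemplate,
    WeightTable,
    instance_key,
)
from .terms import (
    EMPTY_SUBST,
    Substitution,
    Term,
    apply,
    format_term,
    is_ground,
    unify,
)

__all__ = [
    "RunConfig",
    "Stimulus",
    "Action",
    "TraceEvent",
    "Trace",
    "Model",
    "build_model",
    "run",
    "compare_traces",
]


@dataclass
class RunConfig:
    """Run configuration.

    threshold: default gate θ for every pathway (per-edge override via
        ``theta=``).
    signal_ttl: extra cycles an undelivered signal survives past its
        posting cycle.
    coincidence_window: default join/merge window in cycles (1 = same
        cycle).
    pass_limit: maximum react passes per cycle.
    plasticity: global mode, ``weak`` or ``strong`` (fixed per run).
    stp_duration: default cycles an STP opening lasts.
    """

    threshold: int = 1
    signal_ttl: int = 1
    coincidence_window: int = 1
    pass_limit: int = 8
    plasticity: str = "strong"
    stp_duration: int = 1
    max_cycles: int = 200


@dataclass(frozen=True)
class Stimulus:
    term: Term
    cycle: int


@dataclass(frozen=True)
class Action:
    term: Term
    cycle: int


@dataclass(frozen=True)
class TraceEvent:
    cycle: int
    kind: str  # stimulus|drop|fire|deliver|action|weight|stp|store|recall|stm|block|phase|note
    payload: str


_FRESH_RE = re.compile(r"\b[A-Z][A-Za-z0-9_]*\$\d+\b")


class Trace:
    """Ordered event log; canonical form renames fresh variables to
    v1, v2, ... in first-appearance order so traces are comparable."""

    def __init__(self) -> None:
        self.events: list[TraceEvent] = []

    def add(self, cycle: int, kind: str, payload: str) -> None:
        self.events.append(TraceEvent(cycle, kind, payload))

    def canonical_lines(self) -> list[str]:
        renames: dict[str, str] = {}

        def sub(m: re.Match) -> str:
            name = m.group(0)
            if name not in renames:
                renames[name] = f"v{len(renames) + 1}"
            return renames[name]

        return [
            f"{e.cycle}\t{e.kind}\t{_FRESH_RE.sub(sub, e.payload)}" for e in self.events
        ]

    def to_text(self) -> str:
        return "\n".join(self.canonical_lines()) + "\n"

    def to_jsonl(self) -> str:
        out = []
        for line in self.canonical_lines():
            cycle, kind, payload = line.split("\t", 2)
            out.append(json.dumps({"cycle": int(cycle), "kind": kind, "term": payload}))
        return "\n".join(out) + "\n"

    def __len__(self) -> int:
        return len(self.events)


def compare_traces(a: Trace, b: Trace) -> dict:
    """Structural diff: equality, or the first divergent event with
    context.  Fresh-variable names are canonicalized first."""
    la, lb = a.canonical_lines(), b.canonical_lines()
    for i, (x, y) in enumerate(zip(la, lb)):
        if x != y:
            return {
                "equal": False,
                "index": i,
                "left": x,
                "right": y,
                "context": la[max(0, i - 3): i],
            }
    if len(la) != len(lb):
        i = min(len(la), len(lb))
        return {
            "equal": False,
            "index": i,
            "left": la[i] if i < len(la) else None,
            "right": lb[i] if i < len(lb) else None,
            "context": la[max(0, i - 3): i],
        }
    return {"equal": True, "index": None, "left": None, "right": None, "context": []}


@dataclass
class Model:
    """The machine's full mutable state: rule base, weights, queues,
    stores and the cycle counter, plus the ordered trace."""

    rulebase: RuleBase
    config: RunConfig
    weights: WeightTable = field(default_factory=WeightTable)
    queue: SignalQueue = field(default_factory=SignalQueue)
    registry: CoincidenceRegistry = field(default_factory=CoincidenceRegistry)
    stp: StpOverlay = field(default_factory=StpOverlay)
    store: AssociativeStore = field(default_factory=AssociativeStore)
    stm: ShortTermStore = field(default_factory=ShortTermStore)
    trace: Trace = field(default_factory=Trace)
    facts: list = field(default_factory=list)
    latched: dict = field(default_factory=dict)
    frozen: dict = field(default_factory=dict)  # weak edges: slot -> ground Term
    actions: list = field(default_factory=list)
    instances: list = field(default_factory=list)
    cycle: int = 1
    _fact_counter: int = 0
    _fired_this_cycle: set = field(default_factory=set)
    _applied: set = field(default_factory=set)
    _fired_groups: set = field(default_factory=set)
    _deferred_weights: list = field(default_factory=list)
    _deferred_blocks: list = field(default_factory=list)
    _activity: bool = False

    # -- helpers -----------------------------------------------------------

    @property
    def circuit(self):
        return self.rulebase.circuit

    def _log(self, kind: str, payload: str) -> None:
        self.trace.add(self.cycle, kind, payload)
        if kind in ("fire", "deliver", "action", "stm", "store", "recall"):
            self._activity = True

    def _slot(self, source: str, target: str) -> tuple[str, str, str]:
        stream = self.circuit.nodes[source].stream
        return (stream, source, target)

    def _edge_theta(self, edge) -> int:
        return edge.theta if edge.theta is not None else self.config.threshold

    def _weak_annotation(self, edge, source: str) -> Optional[Annotation]:
        for ann in self.rulebase.annotations.values():
            if ann.kind == "ltp" and ann.source == source and ann.target == edge.target:
                mode = ann.mode or self.config.plasticity
                if mode == "weak":
                    return ann
        return None

    # -- spec-level operations --------------------------------------------

    def fire(self, node_name: str, term: Term, binding: Substitution = EMPTY_SUBST) -> None:
        """Activate a thread instance; idempotent within a cycle for an
        identical (template, instance) pair."""
        decl = self.circuit.nodes.get(node_name)
        if decl is None:
            raise KeyError(f"unknown thread template {node_name!r}")
        key = (node_name, format_term(term))
        if key in self._fired_this_cycle:
            return
        self._fired_this_cycle.add(key)
        self.instances.append(
            ThreadInstance(
                template=ThreadTemplate(decl.name, decl.pattern, decl.stream, decl.kind, decl.latch),
                binding=binding,
                term=term,
                status="active",
                activation_cycle=self.cycle,
            )
        )
        self._log("fire", f"{node_name} {format_term(term)}")
        if decl.latch:
            self.latched[node_name] = term
        else:
            self._fact_counter += 1
            self.facts.append(
                Fact(self._fact_counter, "fired", node_name, term, self.cycle, self.cycle)
            )
        if decl.kind == "effector":
            self.actions.append(Action(term, self.cycle))
            self._log("action", format_term(term))
        if not decl.latch:
            for edge in self.circuit.out_edges(node_name):
                self.send(edge, node_name, term)

    def send(self, edge, source: str, payload: Term) -> None:
        """Post a signal on an edge slot, stamped with the current cycle."""
        stream = self.circuit.nodes[source].stream
        self.queue.post(
            Signal(
                edge_id=edge.edge_id,
                stream=stream,
                sender=source,
                receiver=edge.target,
                payload=payload,
                binding=EMPTY_SUBST,
                posted_cycle=self.cycle,
            )
        )

    def deliver_pending(self) -> bool:
        """Attempt weight-gated delivery of every queued signal; returns
        True when anything was delivered.  Sub-threshold signals stay
        queued until expiry; blocked pathways never deliver."""
        delivered_any = False
        for sig in self.queue.pending():
            edge = next(e for e in self.circuit.edges if e.edge_id == sig.edge_id)
            stream, source, target = sig.stream, sig.sender, sig.receiver
            if self.weights.is_blocked(stream, source, target):
                continue
            theta = self._edge_theta(edge)
            weak_ann = self._weak_annotation(edge, source)
            slot = edge.slot_id(source)
            if weak_ann is not None and slot in self.frozen:
                frozen_term = self.frozen[slot]
                w = self.weights.get(stream, source, instance_key(target, frozen_term))
                if isinstance(w, int) and w >= theta:
                    self.queue.consume(sig)
                    delivered_any = True
                    self._log("deliver", f"{source}->{target} {format_term(sig.payload)}")
                    # the weakly bound pathway re-produces its frozen
                    # instance; the fresh payload cannot rebind it
                    self.fire(target, frozen_term)
                continue
            w = self.weights.get(stream, source, target)
            if self.stp.is_open(slot, self.cycle):
                w = max(w if isinstance(w, int) else 0, theta)
            if isinstance(w, int) and w >= theta:
                self.queue.consume(sig)
                delivered_any = True
                self._fact_counter += 1
                self.facts.append(
                    Fact(
                        self._fact_counter,
                        "delivered",
                        f"{sig.edge_id}|{source}",
                        sig.payload,
                        self.cycle,
                        posted_cycle=sig.posted_cycle,
                    )
                )
                self._log("deliver", f"{source}->{target} {format_term(sig.payload)}")
        return delivered_any

    def adjust_weight(self, stream: str, source: str, target, delta: int) -> None:
        new = self.weights.adjust(stream, source, target, delta)
        rk = target if isinstance(target, str) else f"{target[0]}[{target[1]}]"
        self._log("weight", f"w({source}->{rk})={new!r}")

    # -- the sense-react loop ---------------------------------------------

    def sense(self, stimulus: Term) -> None:
        """Fire every sensor template whose pattern unifies with the
        stimulus; unmatched stimuli are dropped and logged."""
        if not is_ground(stimulus):
            raise ProtocolError(f"stimuli must be ground: {format_term(stimulus)}")
        self._log("stimulus", format_term(stimulus))
        matched = False
        for sensor in self.circuit.sensors():
            s = unify(sensor.pattern, stimulus)
            if s is not None:
                matched = True
                self.fire(sensor.name, stimulus, s)
        if not matched:
            self._log("drop", format_term(stimulus))

    def react(self) -> None:
        """Deduce and apply instructions until fixpoint (or pass limit)."""
        for _ in range(self.config.pass_limit):
            delivered = self.deliver_pending()
            deductions = ist(
                list(self.facts),
                self.rulebase.implications,
                latched=self.latched,
                stm_peek=self.stm.peek,
                fired_groups=self._fired_groups,
                applied=self._applied,
            )
            if not deductions and not delivered:
                break
            for ded in deductions:
                if ded.implication.choice_group is not None:
                    self._fired_groups.add(ded.implication.choice_group)
                consumed = set(ded.consumed)
                self.facts = [f for f in self.facts if f.fid not in consumed]
                for op in ded.instructions:
                    self._apply(op, ded.binding)
        else:
            self._log("note", "pass limit reached; react truncated")

    def _apply(self, op, s: Substitution) -> None:
        if isinstance(op, FireOp):
            term = apply(s, op.pattern)
            if not is_ground(term):
                self._log("note", f"non-ground activation dropped: {format_term(term)}")
                return
            self.fire(op.node, term, s)
        elif isinstance(op, StpOp):
            duration = op.duration or self.config.stp_duration
            source, target = op.slot_id.split("->")
            if self.weights.is_blocked(*self._slot(source, target)):
                self._log("note", f"stp on blocked pathway {op.slot_id} ignored")
                return
            self.stp.open(op.slot_id, self.cycle, duration)
            self._log("stp", f"{op.slot_id} open d={duration}")
        elif isinstance(op, JoinOp):
            inst = apply(s, op.instance_pattern) if op.instance_pattern is not None else None
            self.registry.register_join(op.ann_id, self.cycle, inst)
        elif isinstance(op, MergeOp):
            inst = apply(s, op.instance_pattern) if op.instance_pattern is not None else None
            self.registry.post_merge(op.ann_id, self.cycle, inst)
        elif isinstance(op, LtsOp):
            term = apply(s, op.pattern)
            self.store.add(term, self.cycle)
            self._log("store", "{" + format_term(term) + "}")
        elif isinstance(op, LtdOp):
            self._deferred_weights.append((*self._slot(op.edge_source, op.edge_target), -1))
        elif isinstance(op, LtbOp):
            self._deferred_blocks.append(self._slot(op.edge_source, op.edge_target))
        elif isinstance(op, StmPushOp):
            term = apply(s, op.pattern)
            self.stm.push(op.tag, term)
            self._log("stm", f"push <{op.tag}> {format_term(term)}")
        elif isinstance(op, StmPopOp):
            term = self.stm.pop(op.tag)
            if term is not None:
                self._log("stm", f"pop <{op.tag}> {format_term(term)}")
        elif isinstance(op, LtrOp):
            self._apply_ltr(op, s)
        else:  # pragma: no cover
            raise TypeError(f"unknown instruction {op!r}")

    def _apply_ltr(self, op: LtrOp, s: Substitution) -> None:
        stream, source, target = self._slot(op.edge_source, op.edge_target)
        if self.weights.is_blocked(stream, source, target):
            return
        hit = self.store.retrieve(op.retrieve, s)
        if hit is None:
            return
        trace_term, s2 = hit
        if op.stm_tag is not None:
            head = self.stm.peek(op.stm_tag)
            if head is None:
                return
            s3 = unify(op.stm_pattern, head, s2)
            if s3 is None:
                return
            popped = self.stm.pop(op.stm_tag)
            self._log("stm", f"pop <{op.stm_tag}> {format_term(popped)}")
            s2 = s3
        self._log("recall", "{" + format_term(trace_term) + "}" + f" -> {source}->{target}")
        self._deferred_weights.append((stream, source, target, +1))
        term = apply(s2, op.fire_pattern)
        if not is_ground(term):
            self._log("note", f"non-ground recall activation dropped: {format_term(term)}")
            return
        self.fire(op.edge_target, term, s2)

    def consolidate(self) -> None:
        """End-of-cycle: resolve coincidences, apply deferred weight
        changes and blocks, expire transient state, advance the cycle."""
        for ann_id, ann in self.rulebase.annotations.items():
            if ann.kind not in ("ltp", "ltd") or ann.partner is None:
                continue
            window = ann.window or self.config.coincidence_window
            for join_payload, merge_payload in self.registry.resolve(ann_id, window):
                inst = join_payload if join_payload is not None else merge_payload
                delta = 1 if ann.kind == "ltp" else -1
                stream, source, target = self._slot(ann.source, ann.target)
                mode = (ann.mode or self.config.plasticity) if ann.kind == "ltp" else "strong"
                if mode == "weak":
                    self._consolidate_weak(ann, stream, source, target, inst, delta)
                else:
                    self.adjust_weight(stream, source, target, delta)
        for stream, source, target, delta in self._deferred_weights:
            self.adjust_weight(stream, source, target, delta)
        self._deferred_weights.clear()
        for stream, source, target in self._deferred_blocks:
            self.weights.block(stream, source, target)
            self._log("block", f"{source}->{target}")
        self._deferred_blocks.clear()

        max_window = max(
            [self.config.coincidence_window]
            + [a.window for a in self.rulebase.annotations.values() if a.window],
        )
        next_cycle = self.cycle + 1
        self.queue.expire(next_cycle, self.config.signal_ttl)
        self.registry.expire(next_cycle, max_window)
        self.stp.sweep(next_cycle)
        self.facts.clear()
        self._fired_this_cycle.clear()
        self._applied.clear()
        self._fired_groups.clear()
        self.instances = [i for i in self.instances if i.activation_cycle >= self.cycle]
        self.cycle = next_cycle

    def _consolidate_weak(self, ann, stream, source, target, inst, delta) -> None:
        edge = self.circuit.edge(ann.source, ann.target)
        slot = edge.slot_id(source)
        frozen = self.frozen.get(slot)
        if inst is None or not is_ground(inst):
            self.adjust_weight(stream, source, target, delta)
            return
        if frozen is None:
            self.frozen[slot] = inst
            new = self.weights.adjust(stream, source, instance_key(target, inst), delta)
            # rendered like a template-key change so weak and strong runs
            # stay comparable up to the behavioral divergence
            self._log("weight", f"w({source}->{target})={new!r}")
        elif format_term(frozen) == format_term(inst):
            new = self.weights.adjust(stream, source, instance_key(target, frozen), delta)
            self._log("weight", f"w({source}->{target})={new!r}")
        else:
            # §-weak semantics: once bound, the pathway cannot create a
            # successive association — the new instance finds weight 0.
            self._log("weight", f"w({source}->{target}) rebinding denied (weak)")

    def quiescent(self) -> bool:
        return (
            len(self.queue) == 0
            and not self.stp.any_active(self.cycle)
            and not self._activity
        )

    def step_cycle(self, stimuli: Sequence[Term]) -> None:
        self._activity = False
        for stim in stimuli:
            self.sense(stim)
        self.react()
        self.consolidate()


def build_model(rulebase: RuleBase, config: Optional[RunConfig] = None) -> Model:
    """Instantiate a runnable model: initial weights from edge
    declarations (open pathways at 1, closed at 0)."""
    config = config or RunConfig()
    model = Model(rulebase=rulebase, config=config)
    for edge in rulebase.circuit.edges:
        for source in edge.sources:
            if rulebase.circuit.nodes[source].latch:
                continue
            stream = rulebase.circuit.nodes[source].stream
            model.weights.set(stream, source, edge.target, edge.weights.get(source, 1))
    return model


def run(
    model: Model,
    stimuli: Sequence[Stimulus],
    max_cycles: Optional[int] = None,
) -> tuple[Model, list[Action], Trace]:
    """Execute the sense-react loop until the stimulus schedule is
    exhausted and the model is quiescent, or ``max_cycles`` elapse (the
    truncation is flagged in the trace, never raised)."""
    max_cycles = max_cycles or model.config.max_cycles
    schedule: dict[int, list[Term]] = {}
    for st in stimuli:
        schedule.setdefault(st.cycle, []).append(st.term)
    last_cycle = max(schedule) if schedule else 0
    start = model.cycle
    while model.cycle < start + max_cycles:
        cyc = model.cycle
        model.step_cycle(schedule.get(cyc, []))
        if cyc >= last_cycle and model.quiescent():
            break
    else:
        model.trace.add(model.cycle, "note", "cycle limit reached; run truncated")
    return model, list(model.actions), model.trace
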