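"""Circuit language and compiler.

A circuit (the symbolic language *S*) declares streams, typed nodes and
typed connectors, plus plasticity annotations.  Compilation turns it
into an ordered rule base of *virtual code implications* (the logical
language *L*): guarded rules ``facts => instruction`` that the virtual
machine uses just in time to deduce its next instructions (contextual
deduction, the ``ist`` predicate).

The concrete DSL is line-oriented (diffable, trivially parseable)::

    circuit <name>
    stream <id>
    node <kind> <stream> <name> <pattern> [latch]
    edge <type> <src>[,<src>...] <target> [opt=value ...]
    stp <from> <to> trigger=<node> [duration=N]
    ltp <from> <to> trigger=<node> partner=<node> [window=N] [mode=weak|strong]
    ltd <from> <to> trigger=<node> [partner=<node>] [window=N]
    lts <node>
    ltr <from> <to> trigger=<node> pattern=<term> [when=<term>]
    ltb <from> <to> trigger=<node>
    stm-push <tag> <node>

Node kinds: ``sensor`` | ``internal`` | ``effector``.  Edge types:
``synapse`` (one source) and ``conj`` (converging conjunction, all
sources required within one cycle).  Divergence is simply several edges
sharing a source; a *choice* between alternatives is a set of edges
sharing a ``group=`` label, resolved by declaration order, first match
wins.  Modulation of a synapse is expressed by the plasticity annotation
attached to it (the interneuron acting on the pathway).

Edge options: ``weight=`` initial weights (single int for all slots or
``src:w,src:w``), ``theta=`` per-edge threshold, ``bind=X:term`` extra
bindings, ``as=<term>`` target firing pattern override, ``when=<src>:<term>``
source guard-pattern override, ``group=`` choice group,
``stm=<tag>`` (the target's binding is popped from that FIFO memory)
and ``stmwhen=<term>`` the pattern the popped entry must match.

Patterns must be written without spaces.  ``#`` starts a comment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .terms import (
    EMPTY_SUBST,
    Anon,
    Substitution,
    Term,
    TermSyntaxError,
    apply,
    format_term,
    freshen,
    is_ground,
    parse_term,
    unify,
    variables,
)

__all__ = [
    "CircuitError",
    "CircuitSpec",
    "NodeDecl",
    "EdgeDecl",
    "Annotation",
    "Implication",
    "RuleBase",
    "Fact",
    "parse_circuit",
    "validate_circuit",
    "compile_circuit",
    "ist",
    "FiredCond",
    "DeliveredCond",
    "StmHeadCond",
    "FireOp",
    "StpOp",
    "JoinOp",
    "MergeOp",
    "LtsOp",
    "LtrOp",
    "LtdOp",
    "LtbOp",
    "StmPushOp",
    "StmPopOp",
]


class CircuitError(ValueError):
    """Syntax or validation error in a circuit source; carries line info."""


@dataclass(frozen=True)
class NodeDecl:
    name: str
    kind: str  # sensor | internal | effector
    stream: str
    pattern: Term
    latch: bool = False
    line: int = 0


@dataclass(frozen=True)
class EdgeDecl:
    edge_id: str
    kind: str  # synapse | conj
    sources: tuple[str, ...]
    target: str
    weights: dict  # source -> initial int weight
    theta: Optional[int] = None
    bind: dict = field(default_factory=dict)  # var name -> Term
    fire_as: Optional[Term] = None
    when: dict = field(default_factory=dict)  # source -> Term guard override
    group: Optional[str] = None
    stm: Optional[str] = None
    stm_when: Optional[Term] = None
    line: int = 0

    def slot_id(self, source: str) -> str:
        return f"{source}->{self.target}"


@dataclass(frozen=True)
class Annotation:
    ann_id: str
    kind: str  # stp | ltp | ltd | lts | ltr | ltb | stm_push
    source: Optional[str] = None  # edge sender (protocol target edge)
    target: Optional[str] = None  # edge receiver
    trigger: Optional[str] = None
    partner: Optional[str] = None
    window: int = 0  # 0 -> use config default
    duration: int = 0  # 0 -> use config default (stp)
    mode: Optional[str] = None  # ltp: weak | strong | None (config)
    pattern: Optional[Term] = None  # ltr retrieval pattern
    when: Optional[Term] = None  # trigger guard-pattern override
    tag: Optional[str] = None  # stm_push
    node: Optional[str] = None  # lts / stm_push subject node
    stm: Optional[str] = None  # ltr: FIFO tag supplying the firing binding
    stm_when: Optional[Term] = None  # ltr: pattern the popped entry must match
    line: int = 0


@dataclass
class CircuitSpec:
    name: str
    streams: list[str]
    nodes: dict[str, NodeDecl]
    node_order: list[str]
    edges: list[EdgeDecl]
    annotations: list[Annotation]
    source: str = ""

    def sensors(self) -> list[NodeDecl]:
        return [self.nodes[n] for n in self.node_order if self.nodes[n].kind == "sensor"]

    def edge(self, source: str, target: str) -> Optional[EdgeDecl]:
        for e in self.edges:
            if e.target == target and source in e.sources:
                return e
        return None

    def out_edges(self, node: str) -> list[EdgeDecl]:
        return [e for e in self.edges if node in e.sources]

    def contains(self, other: "CircuitSpec") -> bool:
        """True iff every node and edge of ``other`` appears here (the
        strict-extension relation between successive substage circuits)."""
        for name, decl in other.nodes.items():
            mine = self.nodes.get(name)
            if mine is None or format_term(mine.pattern) != format_term(decl.pattern):
                return False
        mine_edges = {(e.sources, e.target) for e in self.edges}
        return all((e.sources, e.target) in mine_edges for e in other.edges)


# ---------------------------------------------------------------------------
# parsing

def _parse_opts(parts: Sequence[str], line_no: int) -> dict[str, str]:
    opts: dict[str, str] = {}
    for p in parts:
        if "=" not in p:
            if p == "latch":
                opts["latch"] = "1"
                continue
            raise CircuitError(f"line {line_no}: malformed option {p!r}")
        k, v = p.split("=", 1)
        if k == "when":  # repeatable
            opts.setdefault("when", "")
            opts["when"] += ("|" if opts["when"] else "") + v
        else:
            opts[k] = v
    return opts


def _term(text: str, line_no: int) -> Term:
    try:
        return parse_term(text)
    except TermSyntaxError as exc:
        raise CircuitError(f"line {line_no}: bad term {text!r}: {exc}") from exc


def parse_circuit(text: str) -> CircuitSpec:
    """Parse circuit DSL source; raises :class:`CircuitError` with line
    numbers on malformed input."""
    name = ""
    streams: list[str] = []
    nodes: dict[str, NodeDecl] = {}
    node_order: list[str] = []
    edges: list[EdgeDecl] = []
    annotations: list[Annotation] = []
    ann_counter = itertools.count(1)
    edge_counter = itertools.count(1)

    for line_no, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        head = parts[0]
        if head == "circuit":
            if len(parts) != 2:
                raise CircuitError(f"line {line_no}: circuit takes one name")
            name = parts[1]
        elif head == "stream":
            if len(parts) != 2:
                raise CircuitError(f"line {line_no}: stream takes one id")
            if parts[1] not in streams:
                streams.append(parts[1])
        elif head == "node":
            if len(parts) < 4:
                raise CircuitError(f"line {line_no}: node needs kind, stream, name[, pattern]")
            kind, stream, node_name = parts[1], parts[2], parts[3]
            if kind not in ("sensor", "internal", "effector"):
                raise CircuitError(f"line {line_no}: unknown node kind {kind!r}")
            rest = parts[4:]
            latch = "latch" in rest
            rest = [p for p in rest if p != "latch"]
            pattern = _term(rest[0], line_no) if rest else _term(node_name, line_no)
            if node_name in nodes:
                raise CircuitError(f"line {line_no}: duplicate node {node_name!r}")
            nodes[node_name] = NodeDecl(node_name, kind, stream, pattern, latch, line_no)
            node_order.append(node_name)
        elif head == "edge":
            if len(parts) < 4:
                raise CircuitError(f"line {line_no}: edge needs type, source(s), target")
            etype = parts[1]
            if etype not in ("synapse", "conj"):
                raise CircuitError(f"line {line_no}: unknown connector type {etype!r}")
            sources = tuple(parts[2].split(","))
            target = parts[3]
            opts = _parse_opts(parts[4:], line_no)
            weights: dict[str, int] = {}
            wspec = opts.get("weight", "1")
            if ":" in wspec:
                for item in wspec.split(","):
                    src, w = item.split(":")
                    weights[src] = int(w)
                for src in sources:
                    weights.setdefault(src, 1)
            else:
                for src in sources:
                    weights[src] = int(wspec)
            bind: dict[str, Term] = {}
            if "bind" in opts:
                for item in opts["bind"].split(","):
                    var, val = item.split(":")
                    bind[var] = _term(val, line_no)
            when: dict[str, Term] = {}
            if "when" in opts:
                for item in opts["when"].split("|"):
                    src, pat = item.split(":", 1)
                    when[src] = _term(pat, line_no)
            edges.append(
                EdgeDecl(
                    edge_id=f"e{next(edge_counter)}:{'+'.join(sources)}->{target}",
                    kind=etype,
                    sources=sources,
                    target=target,
                    weights=weights,
                    theta=int(opts["theta"]) if "theta" in opts else None,
                    bind=bind,
                    fire_as=_term(opts["as"], line_no) if "as" in opts else None,
                    when=when,
                    group=opts.get("group"),
                    stm=opts.get("stm"),
                    stm_when=_term(opts["stmwhen"], line_no) if "stmwhen" in opts else None,
                    line=line_no,
                )
            )
        elif head in ("stp", "ltp", "ltd", "ltb", "ltr"):
            if len(parts) < 3:
                raise CircuitError(f"line {line_no}: {head} needs <from> <to>")
            opts = _parse_opts(parts[3:], line_no)
            annotations.append(
                Annotation(
                    ann_id=f"{head}{next(ann_counter)}",
                    kind=head,
                    source=parts[1],
                    target=parts[2],
                    trigger=opts.get("trigger"),
                    partner=opts.get("partner"),
                    window=int(opts.get("window", 0)),
                    duration=int(opts.get("duration", 0)),
                    mode=opts.get("mode"),
                    pattern=_term(opts["pattern"], line_no) if "pattern" in opts else None,
                    when=_term(opts["when"], line_no) if "when" in opts else None,
                    stm=opts.get("stm"),
                    stm_when=_term(opts["stmwhen"], line_no) if "stmwhen" in opts else None,
                    line=line_no,
                )
            )
        elif head == "lts":
            if len(parts) < 2:
                raise CircuitError(f"line {line_no}: lts needs a node")
            annotations.append(
                Annotation(ann_id=f"lts{next(ann_counter)}", kind="lts", node=parts[1], line=line_no)
            )
        elif head == "stm-push":
            if len(parts) < 3:
                raise CircuitError(f"line {line_no}: stm-push needs <tag> <node>")
            annotations.append(
                Annotation(
                    ann_id=f"stm{next(ann_counter)}",
                    kind="stm_push",
                    tag=parts[1],
                    node=parts[2],
                    line=line_no,
                )
            )
        else:
            raise CircuitError(f"line {line_no}: unknown declaration {head!r}")

    if not nodes:
        raise CircuitError("no nodes declared")
    return CircuitSpec(
        name=name or "unnamed",
        streams=streams,
        nodes=nodes,
        node_order=node_order,
        edges=edges,
        annotations=annotations,
        source=text,
    )


def validate_circuit(spec: CircuitSpec) -> list[str]:
    """Check structural invariants; returns a (possibly empty) report of
    violations rather than raising."""
    report: list[str] = []
    for e in spec.edges:
        for endpoint in (*e.sources, e.target):
            if endpoint not in spec.nodes:
                report.append(f"line {e.line}: edge endpoint {endpoint!r} is not a declared node")
        if e.kind == "conj" and len(e.sources) < 2:
            report.append(f"line {e.line}: conjunction requires >= 2 sources")
        if e.kind == "synapse" and len(e.sources) != 1:
            report.append(f"line {e.line}: synapse takes exactly one source")
        decl_streams = {
            spec.nodes[n].stream for n in (*e.sources, e.target) if n in spec.nodes
        }
        if len(decl_streams) > 1:
            report.append(
                f"line {e.line}: edge crosses streams {sorted(decl_streams)} — "
                "direct communication is confined to one stream"
            )
    for node in spec.nodes.values():
        if node.stream not in spec.streams:
            report.append(f"line {node.line}: node {node.name!r} uses undeclared stream {node.stream!r}")
    for ann in spec.annotations:
        if ann.kind in ("stp", "ltp", "ltd", "ltb", "ltr"):
            if spec.edge(ann.source, ann.target) is None:
                report.append(
                    f"line {ann.line}: {ann.kind} refers to missing pathway "
                    f"{ann.source}->{ann.target} (modulation must attach to an existing synapse)"
                )
            for ref in (ann.trigger, ann.partner):
                if ref is not None and ref not in spec.nodes:
                    report.append(f"line {ann.line}: unknown node {ref!r} in {ann.kind}")
        if ann.kind in ("lts", "stm_push") and ann.node not in spec.nodes:
            report.append(f"line {ann.line}: unknown node {ann.node!r} in {ann.kind}")
    return report


# ---------------------------------------------------------------------------
# compiled form

@dataclass(frozen=True)
class FiredCond:
    """Guard on an active thread instance.  Non-consuming conditions read
    events (or latched state) without using them up."""

    node: str
    pattern: Term
    consume: bool = True
    latched: bool = False


@dataclass(frozen=True)
class DeliveredCond:
    """Guard on a weight-gated signal delivered on an edge slot."""

    edge_id: str
    source: str
    pattern: Term


@dataclass(frozen=True)
class StmHeadCond:
    """Guard on the head of a FIFO short-term memory (peek; the matching
    instruction pops)."""

    tag: str
    pattern: Term


@dataclass(frozen=True)
class FireOp:
    node: str
    pattern: Term


@dataclass(frozen=True)
class StpOp:
    slot_id: str
    duration: int


@dataclass(frozen=True)
class JoinOp:
    ann_id: str
    instance_pattern: Optional[Term] = None


@dataclass(frozen=True)
class MergeOp:
    ann_id: str
    instance_pattern: Optional[Term] = None


@dataclass(frozen=True)
class LtsOp:
    pattern: Term


@dataclass(frozen=True)
class LtrOp:
    """Associative retrieval: fired by the trigger (Q), waits for a path
    from a stored trace matching ``retrieve``; on a hit, the Q->R
    pathway is potentiated and R fired with the retrieval bindings
    (optionally drawn from a FIFO short-term memory)."""

    ann_id: str
    retrieve: Term
    edge_source: str
    edge_target: str
    fire_pattern: Term
    stm_tag: Optional[str] = None
    stm_pattern: Optional[Term] = None


@dataclass(frozen=True)
class LtdOp:
    """Immediate (partner-less) long-term depression of a pathway."""

    edge_source: str
    edge_target: str


@dataclass(frozen=True)
class LtbOp:
    edge_source: str
    edge_target: str


@dataclass(frozen=True)
class StmPushOp:
    tag: str
    pattern: Term


@dataclass(frozen=True)
class StmPopOp:
    tag: str


Instruction = object
Condition = object


@dataclass(frozen=True)
class Implication:
    """One virtual code implication: guard patterns => one instruction
    bundle.  ``same_cycle`` requires all delivered-signal conditions to
    share a posting cycle (conjunction coincidence)."""

    index: int
    guard: tuple[Condition, ...]
    instructions: tuple[Instruction, ...]
    same_cycle: bool = False
    choice_group: Optional[str] = None
    provenance: str = ""

    def render(self) -> str:
        conds = []
        for c in self.guard:
            if isinstance(c, FiredCond):
                tag = "state" if c.latched else "fired"
                conds.append(f"{tag}({c.node}:{format_term(c.pattern)})")
            elif isinstance(c, DeliveredCond):
                conds.append(f"delivered({c.source}:{format_term(c.pattern)})")
            elif isinstance(c, StmHeadCond):
                conds.append(f"<{c.tag}>~{format_term(c.pattern)}")
        instrs = []
        for op in self.instructions:
            if isinstance(op, FireOp):
                instrs.append(f"fire {op.node} {format_term(op.pattern)}")
            elif isinstance(op, StpOp):
                instrs.append(f"stp {op.slot_id} d={op.duration}")
            elif isinstance(op, JoinOp):
                instrs.append(f"join {op.ann_id}")
            elif isinstance(op, MergeOp):
                instrs.append(f"merge {op.ann_id}")
            elif isinstance(op, LtsOp):
                instrs.append(f"lts {format_term(op.pattern)}")
            elif isinstance(op, LtrOp):
                instrs.append(f"ltr {op.edge_source}->{op.edge_target} ~{format_term(op.retrieve)}")
            elif isinstance(op, LtdOp):
                instrs.append(f"ltd {op.edge_source}->{op.edge_target}")
            elif isinstance(op, LtbOp):
                instrs.append(f"ltb {op.edge_source}->{op.edge_target}")
            elif isinstance(op, StmPushOp):
                instrs.append(f"push <{op.tag}> {format_term(op.pattern)}")
            elif isinstance(op, StmPopOp):
                instrs.append(f"pop <{op.tag}>")
        joiner = " & "
        return f"[{self.index}] {joiner.join(conds)} => {'; '.join(instrs)}  ({self.provenance})"


@dataclass
class RuleBase:
    """Ordered, stable sequence of implications plus the annotation and
    edge tables the machine needs at run time."""

    circuit: CircuitSpec
    implications: tuple[Implication, ...]
    annotations: dict[str, Annotation]

    def render(self) -> str:
        return "\n".join(imp.render() for imp in self.implications)


def _guard_pattern(spec: CircuitSpec, edge: EdgeDecl, source: str) -> Term:
    if source in edge.when:
        return edge.when[source]
    return spec.nodes[source].pattern


def _fire_pattern(spec: CircuitSpec, edge: EdgeDecl) -> Term:
    pattern = edge.fire_as if edge.fire_as is not None else spec.nodes[edge.target].pattern
    if edge.bind:
        pattern = apply(Substitution(edge.bind), pattern)
    return pattern


def _stm_head_pattern(spec: CircuitSpec, tag: str, override: Optional[Term]) -> Term:
    if override is not None:
        return override
    for ann in spec.annotations:
        if ann.kind == "stm_push" and ann.tag == tag:
            return spec.nodes[ann.node].pattern
    raise CircuitError(f"no stm-push declaration for tag {tag!r}")


def compile_circuit(spec: CircuitSpec) -> RuleBase:
    """Compile a validated circuit into its ordered rule base.

    Deterministic and pure: the same spec always yields an identical rule
    base.  Annotation (protocol-spawning) implications come first, then
    the connector implications in declaration order; choice groups keep
    declaration order so the first matching alternative wins.
    """
    problems = validate_circuit(spec)
    if problems:
        raise CircuitError("invalid circuit:\n" + "\n".join(problems))

    implications: list[Implication] = []
    annotations: dict[str, Annotation] = {}
    idx = itertools.count(1)

    def trig_pattern(ann: Annotation, node: str) -> Term:
        if ann.when is not None and node == ann.trigger:
            return ann.when
        return spec.nodes[node].pattern

    for ann in spec.annotations:
        annotations[ann.ann_id] = ann
        if ann.kind == "stp":
            edge = spec.edge(ann.source, ann.target)
            implications.append(
                Implication(
                    index=next(idx),
                    guard=(FiredCond(ann.trigger, trig_pattern(ann, ann.trigger), consume=False,
                                     latched=spec.nodes[ann.trigger].latch),),
                    instructions=(StpOp(edge.slot_id(ann.source), ann.duration),),
                    provenance=f"stp {ann.source}->{ann.target} (line {ann.line})",
                )
            )
        elif ann.kind == "ltd" and ann.partner is None:
            implications.append(
                Implication(
                    index=next(idx),
                    guard=(FiredCond(ann.trigger, trig_pattern(ann, ann.trigger), consume=False,
                                     latched=spec.nodes[ann.trigger].latch),),
                    instructions=(LtdOp(ann.source, ann.target),),
                    provenance=f"ltd {ann.source}->{ann.target} (line {ann.line})",
                )
            )
        elif ann.kind in ("ltp", "ltd"):
            edge = spec.edge(ann.source, ann.target)
            fire_pat = _fire_pattern(spec, edge)
            # the coincidence participant that *is* the pathway's sender
            # contributes the receiver's prospective ground instance
            # (needed to freeze weak pathways).
            trig_inst = fire_pat if ann.trigger == ann.source else None
            implications.append(
                Implication(
                    index=next(idx),
                    guard=(FiredCond(ann.trigger, trig_pattern(ann, ann.trigger), consume=False,
                                     latched=spec.nodes[ann.trigger].latch),),
                    instructions=(JoinOp(ann.ann_id, trig_inst),),
                    provenance=f"{ann.kind}-join {ann.source}->{ann.target} (line {ann.line})",
                )
            )
            if ann.partner is not None:
                part_inst = fire_pat if ann.partner == ann.source else None
                implications.append(
                    Implication(
                        index=next(idx),
                        guard=(FiredCond(ann.partner, spec.nodes[ann.partner].pattern,
                                         consume=False, latched=spec.nodes[ann.partner].latch),),
                        instructions=(MergeOp(ann.ann_id, part_inst),),
                        provenance=f"{ann.kind}-merge {ann.source}->{ann.target} (line {ann.line})",
                    )
                )
        elif ann.kind == "ltr":
            edge = spec.edge(ann.source, ann.target)
            target_pattern = spec.nodes[ann.target].pattern
            if edge.bind:
                target_pattern = apply(Substitution(edge.bind), target_pattern)
            if ann.pattern is None:
                raise CircuitError(f"line {ann.line}: ltr requires pattern=")
            stm_pat = None
            if ann.stm is not None:
                stm_pat = _stm_head_pattern(spec, ann.stm, ann.stm_when)
            implications.append(
                Implication(
                    index=next(idx),
                    guard=(FiredCond(ann.trigger, trig_pattern(ann, ann.trigger), consume=False,
                                     latched=spec.nodes[ann.trigger].latch),),
                    instructions=(
                        LtrOp(
                            ann_id=ann.ann_id,
                            retrieve=ann.pattern,
                            edge_source=ann.source,
                            edge_target=ann.target,
                            fire_pattern=target_pattern,
                            stm_tag=ann.stm,
                            stm_pattern=stm_pat,
                        ),
                    ),
                    provenance=f"ltr {ann.source}->{ann.target} (line {ann.line})",
                )
            )
        elif ann.kind == "ltb":
            implications.append(
                Implication(
                    index=next(idx),
                    guard=(FiredCond(ann.trigger, trig_pattern(ann, ann.trigger), consume=False,
                                     latched=spec.nodes[ann.trigger].latch),),
                    instructions=(LtbOp(ann.source, ann.target),),
                    provenance=f"ltb {ann.source}->{ann.target} (line {ann.line})",
                )
            )
        elif ann.kind == "lts":
            node = spec.nodes[ann.node]
            implications.append(
                Implication(
                    index=next(idx),
                    guard=(FiredCond(ann.node, node.pattern, consume=False, latched=node.latch),),
                    instructions=(LtsOp(node.pattern),),
                    provenance=f"lts {ann.node} (line {ann.line})",
                )
            )
        elif ann.kind == "stm_push":
            node = spec.nodes[ann.node]
            implications.append(
                Implication(
                    index=next(idx),
                    guard=(FiredCond(ann.node, node.pattern, consume=False, latched=node.latch),),
                    instructions=(StmPushOp(ann.tag, node.pattern),),
                    provenance=f"stm-push <{ann.tag}> {ann.node} (line {ann.line})",
                )
            )

    for edge in spec.edges:
        guard: list[Condition] = []
        for source in edge.sources:
            src_decl = spec.nodes[source]
            pat = _guard_pattern(spec, edge, source)
            if src_decl.latch:
                guard.append(FiredCond(source, pat, consume=False, latched=True))
            else:
                guard.append(DeliveredCond(edge.edge_id, source, pat))
        instructions: list[Instruction] = []
        fire_pat = _fire_pattern(spec, edge)
        if edge.stm is not None:
            head_pat = _stm_head_pattern(spec, edge.stm, edge.stm_when)
            guard.append(StmHeadCond(edge.stm, head_pat))
            instructions.append(StmPopOp(edge.stm))
        instructions.append(FireOp(edge.target, fire_pat))
        # range restriction: every named variable of the fired pattern must
        # be bound by the guard.
        guard_vars: set[str] = set()
        for cond in guard:
            guard_vars.update(variables(cond.pattern))
        unbound = [v for v in variables(fire_pat) if v not in guard_vars]
        if unbound:
            raise CircuitError(
                f"line {edge.line}: variables {unbound} of target pattern are not "
                f"bound by the guard (range restriction)"
            )
        implications.append(
            Implication(
                index=next(idx),
                guard=tuple(guard),
                instructions=tuple(instructions),
                same_cycle=edge.kind == "conj",
                choice_group=edge.group,
                provenance=f"{edge.kind} {'+'.join(edge.sources)}->{edge.target} (line {edge.line})",
            )
        )

    return RuleBase(circuit=spec, implications=tuple(implications), annotations=annotations)


# ---------------------------------------------------------------------------
# contextual deduction

@dataclass
class Fact:
    """One element of the machine's working context."""

    fid: int
    kind: str  # "fired" | "delivered"
    key: str  # node name, or edge slot id for delivered signals
    term: Term
    cycle: int
    posted_cycle: int = 0
    consumable: bool = True


@dataclass
class Deduction:
    implication: Implication
    binding: Substitution
    consumed: tuple[int, ...]  # fact ids
    instructions: tuple[Instruction, ...]  # freshened alongside the guard
    fact_ids: tuple[int, ...]  # all facts used (incl. non-consumed)


def _freshen_implication(imp: Implication) -> tuple[tuple[Condition, ...], tuple[Instruction, ...]]:
    mapping: dict[str, str] = {}
    guard = []
    for c in imp.guard:
        guard.append(replace(c, pattern=freshen(c.pattern, mapping)))
    instrs = []
    for op in imp.instructions:
        if isinstance(op, (FireOp, LtsOp, StmPushOp)):
            instrs.append(replace(op, pattern=freshen(op.pattern, mapping)))
        elif isinstance(op, (JoinOp, MergeOp)) and op.instance_pattern is not None:
            instrs.append(replace(op, instance_pattern=freshen(op.instance_pattern, mapping)))
        elif isinstance(op, LtrOp):
            instrs.append(
                replace(
                    op,
                    retrieve=freshen(op.retrieve, mapping),
                    fire_pattern=freshen(op.fire_pattern, mapping),
                    stm_pattern=freshen(op.stm_pattern, mapping) if op.stm_pattern is not None else None,
                )
            )
        else:
            instrs.append(op)
    return tuple(guard), tuple(instrs)


def ist(
    facts: Sequence[Fact],
    rules: Iterable[Implication],
    latched: Optional[dict[str, Term]] = None,
    stm_peek=None,
    fired_groups: Optional[set[str]] = None,
    applied: Optional[set] = None,
) -> list[Deduction]:
    """Contextual deduction: all (implication, binding) pairs whose
    freshened guards unify conjunctively with the current facts.

    Ordering is rule-base order, then fact arrival order (oldest first);
    each consumable fact is consumed by at most one deduction; an
    implication may fire several times on distinct facts.  Choice groups
    admit at most one deduction per group.  Non-consuming guards may be
    re-read, but a (rule, facts) combination already applied earlier in
    the same cycle (``applied``) is not deduced again.
    """
    latched = latched or {}
    fired_groups = set(fired_groups or ())
    applied = applied if applied is not None else set()
    consumed: set[int] = set()
    out: list[Deduction] = []

    for imp in rules:
        if imp.choice_group is not None and imp.choice_group in fired_groups:
            continue
        while True:
            ded = _match_once(imp, facts, latched, stm_peek, consumed, applied)
            if ded is None:
                break
            out.append(ded)
            consumed.update(ded.consumed)
            applied.add((imp.index, ded.fact_ids))
            if imp.choice_group is not None:
                fired_groups.add(imp.choice_group)
                break
    return out


def _match_once(imp, facts, latched, stm_peek, consumed, applied):
    guard, instrs = _freshen_implication(imp)

    def backtrack(i: int, s: Substitution, used: tuple[int, ...],
                  to_consume: tuple[int, ...], post_cycle: Optional[int]):
        if i == len(guard):
            key = (imp.index, used)
            if key in applied:
                return None
            return Deduction(imp, s, to_consume, instrs, used)
        cond = guard[i]
        if isinstance(cond, FiredCond) and cond.latched:
            term = latched.get(cond.node)
            if term is None:
                return None
            s2 = unify(cond.pattern, term, s)
            if s2 is None:
                return None
            return backtrack(i + 1, s2, used, to_consume, post_cycle)
        if isinstance(cond, StmHeadCond):
            if stm_peek is None:
                return None
            head = stm_peek(cond.tag)
            if head is None:
                return None
            s2 = unify(cond.pattern, head, s)
            if s2 is None:
                return None
            return backtrack(i + 1, s2, used, to_consume, post_cycle)
        for fact in facts:
            if fact.fid in consumed or fact.fid in used:
                continue
            if isinstance(cond, FiredCond):
                if fact.kind != "fired" or fact.key != cond.node:
                    continue
            elif isinstance(cond, DeliveredCond):
                if fact.kind != "delivered" or fact.key != f"{cond.edge_id}|{cond.source}":
                    continue
                if imp.same_cycle and post_cycle is not None and fact.posted_cycle != post_cycle:
                    continue
            else:
                continue
            s2 = unify(cond.pattern, fact.term, s)
            if s2 is None:
                continue
            new_post = post_cycle
            if isinstance(cond, DeliveredCond) and imp.same_cycle and post_cycle is None:
                new_post = fact.posted_cycle
            new_consume = to_consume + ((fact.fid,) if _consumes(cond) else ())
            res = backtrack(i + 1, s2, used + (fact.fid,), new_consume, new_post)
            if res is not None:
                return res
        return None

    return backtrack(0, EMPTY_SUBST, (), (), None)


def _consumes(cond) -> bool:
    if isinstance(cond, FiredCond):
        return cond.consume
    return isinstance(cond, DeliveredCond)
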