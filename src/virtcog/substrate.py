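"""The virtual neurological substrate.

Threads abstract neurons or neuron clusters.  They are grouped into
disjoint *streams* (neural assemblies); integer weights attach to
sender->receiver pairs within a stream and gate asynchronous
message-passing.  Contrary to integrate-and-fire neuron models, incoming
signals are processed individually, so a thread maintains parallel
asynchronous conversations.

Weights are non-negative integers or ``BLOCKED`` — an absorbing state
that no later operation can restore (long-term blocking of a futile
pathway).  Delivery of a queued signal proceeds only when the weight of
its sender->receiver pair stands at or above the threshold θ.

Coincidence detection is realized by a join/merge rendezvous: one side
registers a *join* (waits), the other posts a *merge*; the pair succeeds
when the two fall within the coincidence window, and each merge is
consumed by at most one join (FIFO priority).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

from .terms import Substitution, Term, format_term

logger = logging.getLogger(__name__)

__all__ = [
    "BLOCKED",
    "ThreadTemplate",
    "ThreadInstance",
    "WeightTable",
    "Signal",
    "SignalQueue",
    "CoincidenceRegistry",
    "ReceiverKey",
    "instance_key",
]


class _Blocked:
    """Absorbing weight state; singleton."""

    _instance: Optional["_Blocked"] = None

    def __new__(cls) -> "_Blocked":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "BLOCKED"


BLOCKED = _Blocked()

#: receiver side of a weight key: template name (strong pathways) or a
#: (template name, canonical ground instance) pair (weak pathways).
ReceiverKey = Union[str, tuple[str, str]]


def instance_key(receiver: str, instance: Term) -> ReceiverKey:
    """Weak-pathway receiver key: the ground instance frozen at first
    potentiation."""
    return (receiver, format_term(instance))


@dataclass(frozen=True)
class ThreadTemplate:
    """A micro-circuit node: (name, pattern, stream, kind).

    kind: ``sensor`` (fired by stimuli), ``effector`` (firing emits an
    action), ``internal``, or ``plasticity`` (protocol threads).  A
    *latched* internal thread keeps its most recent instance as
    persistent state (e.g. the focus of visual attention) instead of an
    expiring event.
    """

    name: str
    pattern: Term
    stream: str
    kind: str = "internal"
    latch: bool = False


@dataclass
class ThreadInstance:
    template: ThreadTemplate
    binding: Substitution
    term: Term  # pattern with binding applied
    status: str = "active"  # dormant | waiting | active
    activation_cycle: int = 0

    def __repr__(self) -> str:
        return f"<{self.template.name}:{format_term(self.term)}@{self.activation_cycle}>"


class WeightTable:
    """Integer weights on (stream, sender, receiver-key) triples.

    Missing entries read as 0.  Adjustments floor at 0.  ``BLOCKED`` is
    absorbing: adjusting or re-opening a blocked entry is a logged no-op.
    """

    def __init__(self) -> None:
        self._w: dict[tuple[str, str, ReceiverKey], Union[int, _Blocked]] = {}

    def key(self, stream: str, sender: str, receiver: ReceiverKey):
        return (stream, sender, receiver)

    def get(self, stream: str, sender: str, receiver: ReceiverKey) -> Union[int, _Blocked]:
        return self._w.get((stream, sender, receiver), 0)

    def set(self, stream: str, sender: str, receiver: ReceiverKey, value: int) -> None:
        k = (stream, sender, receiver)
        if self._w.get(k) is BLOCKED:
            logger.warning("ignoring set on BLOCKED edge %s", k)
            return
        self._w[k] = max(0, value)

    def adjust(self, stream: str, sender: str, receiver: ReceiverKey, delta: int) -> Union[int, _Blocked]:
        """weight <- max(0, weight + delta); no-op with warning on BLOCKED."""
        k = (stream, sender, receiver)
        cur = self._w.get(k, 0)
        if cur is BLOCKED:
            logger.warning("ignoring adjust on BLOCKED edge %s", k)
            return BLOCKED
        new = max(0, cur + delta)
        self._w[k] = new
        return new

    def block(self, stream: str, sender: str, receiver: ReceiverKey) -> None:
        self._w[(stream, sender, receiver)] = BLOCKED

    def is_blocked(self, stream: str, sender: str, receiver: ReceiverKey) -> bool:
        return self._w.get((stream, sender, receiver), 0) is BLOCKED

    def items(self):
        return self._w.items()

    def dump_tsv(self) -> str:
        """Debug dump: stream<TAB>sender<TAB>receiver<TAB>weight."""
        lines = []
        for (stream, sender, receiver), w in sorted(
            self._w.items(), key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]))
        ):
            rk = receiver if isinstance(receiver, str) else f"{receiver[0]}[{receiver[1]}]"
            lines.append(f"{stream}\t{sender}\t{rk}\t{w!r}")
        return "\n".join(lines)


@dataclass
class Signal:
    """One queued message: sender instance -> receiver, FIFO per pair."""

    edge_id: str
    stream: str
    sender: str
    receiver: str
    payload: Term
    binding: Substitution
    posted_cycle: int
    seq: int = 0


class SignalQueue:
    """FIFO queue of signals with a per-cycle time-to-live."""

    def __init__(self) -> None:
        self._items: list[Signal] = []
        self._seq = 0

    def post(self, signal: Signal) -> Signal:
        self._seq += 1
        signal.seq = self._seq
        self._items.append(signal)
        return signal

    def pending(self) -> list[Signal]:
        return list(self._items)

    def consume(self, signal: Signal) -> None:
        self._items.remove(signal)

    def expire(self, cycle: int, ttl: int) -> list[Signal]:
        """Drop signals that outlived their time-to-live: a signal posted
        at cycle t is deliverable during cycles t .. t+ttl (ttl=1: the
        posting cycle and the next)."""
        dead = [s for s in self._items if cycle - s.posted_cycle > ttl]
        for s in dead:
            self._items.remove(s)
        return dead

    def __len__(self) -> int:
        return len(self._items)


@dataclass
class _Rendezvous:
    key: str
    cycle: int
    binding: Substitution
    seq: int
    consumed: bool = False


class CoincidenceRegistry:
    """join/merge rendezvous for coincidence detection.

    A *join* waits for a *merge* with the same key; the pair succeeds iff
    their cycles fall within the coincidence window
    (|join - merge| <= window - 1, so window=1 means same cycle).  Each
    merge is consumed by exactly one join, FIFO.
    """

    def __init__(self) -> None:
        self._joins: list[_Rendezvous] = []
        self._merges: list[_Rendezvous] = []
        self._seq = 0

    def register_join(self, key: str, cycle: int, binding: Substitution) -> None:
        self._seq += 1
        self._joins.append(_Rendezvous(key, cycle, binding, self._seq))

    def post_merge(self, key: str, cycle: int, binding: Substitution) -> None:
        self._seq += 1
        self._merges.append(_Rendezvous(key, cycle, binding, self._seq))

    def resolve(self, key: str, window: int) -> list[tuple[Substitution, Substitution]]:
        """Match pending joins to merges for ``key`` (FIFO), returning the
        (join-binding, merge-binding) pair for each success and consuming
        both sides."""
        out: list[tuple[Substitution, Substitution]] = []
        for j in self._joins:
            if j.key != key or j.consumed:
                continue
            for m in self._merges:
                if m.key != key or m.consumed:
                    continue
                if abs(j.cycle - m.cycle) <= window - 1:
                    j.consumed = True
                    m.consumed = True
                    out.append((j.binding, m.binding))
                    break
        return out

    def expire(self, cycle: int, window: int) -> None:
        """Forget registrations that can no longer pair."""
        horizon = cycle - (window - 1)
        self._joins = [j for j in self._joins if not j.consumed and j.cycle >= horizon]
        self._merges = [m for m in self._merges if not m.consumed and m.cycle >= horizon]

    def join_merge(self, join_cycle: int, merge_cycle: int, window: int) -> bool:
        """Pure coincidence predicate used by the rendezvous above."""
        return abs(join_cycle - merge_cycle) <= window - 1
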