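"""Plasticity protocols: the threads that abstract synaptic change.

Six mechanisms, in increasing order of abstraction:

* **STP** — short-term potentiation: a pathway opens transiently for a
  fixed number of cycles, then closes again (no weight change persists).
* **LTP** — long-term potentiation: a coincidence detector (join/merge
  rendezvous) increments the weight of a sender->receiver pathway by +1
  per detected pairing, consolidated at end of cycle.
* **LTD** — long-term depression: the complementary -1 (floor 0).
* **LTS / LTR** — long-term storage/retrieval: an associative memory.
  ``lts`` appends a ground trace ``{P}`` to the store; ``ltr(P, Q, R)``
  is fired by Q, retrieves a stored trace unifying with P (newest first),
  increments weight(Q->R) and fires R with the retrieval bindings.
* **LTB** — long-term blocking: the pathway enters the absorbing BLOCKED
  state; nothing reopens it (extinction of a futile action).
* **STM** — a per-tag FIFO short-term memory ``<t>`` of ground terms
  (e.g. the remembered positions where an object disappeared, recalled
  in displacement order).

Weak vs strong plasticity: a *weak* LTP freezes the receiver's ground
instance at first potentiation — the pathway can only ever re-produce
that instance (anonymous-variable semantics).  A *strong* LTP keys the
weight by receiver template and rebinds per activation, allowing the
same input to be associated with successive different reactions.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

from .terms import (
    EMPTY_SUBST,
    Substitution,
    Term,
    format_term,
    freshen,
    is_ground,
    unify,
)

__all__ = [
    "ProtocolError",
    "PlasticityMode",
    "AssociativeStore",
    "ShortTermStore",
    "StpOverlay",
]


class ProtocolError(RuntimeError):
    """A plasticity protocol invariant was violated (e.g. storing a
    non-ground trace)."""


#: fixed per experiment run (global config): "weak" | "strong"
PlasticityMode = str


@dataclass
class _StoredTrace:
    term: Term
    cycle: int


class AssociativeStore:
    """Ordered set of ground traces ``{P}``; retrieval is newest-first
    and non-destructive (repeated image-driven retrieval is allowed)."""

    def __init__(self) -> None:
        self._traces: list[_StoredTrace] = []

    def add(self, trace: Term, cycle: int) -> None:
        if not is_ground(trace):
            raise ProtocolError(f"LTS trace must be ground: {format_term(trace)}")
        self._traces.append(_StoredTrace(trace, cycle))

    def retrieve(
        self, pattern: Term, seed: Substitution = EMPTY_SUBST
    ) -> Optional[tuple[Term, Substitution]]:
        """Newest trace unifying with ``pattern`` under ``seed``, with the
        extended substitution; ``None`` when nothing matches."""
        for stored in reversed(self._traces):
            s = unify(pattern, stored.term, seed)
            if s is not None:
                return stored.term, s
        return None

    def traces(self) -> list[Term]:
        return [t.term for t in self._traces]

    def __len__(self) -> int:
        return len(self._traces)

    def render(self) -> str:
        return " ".join("{" + format_term(t.term) + "}" for t in self._traces)


class ShortTermStore:
    """Per-tag FIFO queues of ground terms, rendered ``<t>``.

    Entries persist until consumed (no decay by default).  ``pop``
    returns the oldest entry; popping an empty queue returns ``None``
    (the empty marker), never an error.
    """

    def __init__(self) -> None:
        self._queues: dict[str, deque[Term]] = {}

    def push(self, tag: str, term: Term) -> None:
        if not is_ground(term):
            raise ProtocolError(f"STM entry must be ground: {format_term(term)}")
        self._queues.setdefault(tag, deque()).append(term)

    def pop(self, tag: str) -> Optional[Term]:
        q = self._queues.get(tag)
        if not q:
            return None
        return q.popleft()

    def peek(self, tag: str) -> Optional[Term]:
        q = self._queues.get(tag)
        if not q:
            return None
        return q[0]

    def depth(self, tag: str) -> int:
        return len(self._queues.get(tag, ()))

    def render(self, tag: str) -> str:
        q = self._queues.get(tag, ())
        return " ".join("<" + format_term(t) + ">" for t in q)


class StpOverlay:
    """Transient pathway openings.

    Rather than mutating the weight table and restoring it later, STP is
    an overlay: while active for an edge slot, the effective weight reads
    as the threshold θ.  ``duration`` counts cycles: duration 1 opens the
    pathway for the current cycle only.
    """

    def __init__(self) -> None:
        self._active: dict[str, int] = {}  # slot id -> last active cycle

    def open(self, slot_id: str, cycle: int, duration: int) -> None:
        expiry = cycle + max(1, duration) - 1
        # extensions accumulate: keep the later expiry
        if self._active.get(slot_id, -1) < expiry:
            self._active[slot_id] = expiry

    def is_open(self, slot_id: str, cycle: int) -> bool:
        return self._active.get(slot_id, -1) >= cycle

    def sweep(self, cycle: int) -> None:
        self._active = {k: v for k, v in self._active.items() if v >= cycle}

    def any_active(self, cycle: int) -> bool:
        return any(v >= cycle for v in self._active.values())
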