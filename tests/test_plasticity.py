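"""Plasticity protocols: stores, STP, coincidence-gated LTP, weak vs
strong divergence."""

import pytest
from hypothesis import given, settings, strategies as st

from virtcog.machine import RunConfig, Stimulus, build_model, run
from virtcog.plasticity import (
    AssociativeStore,
    ProtocolError,
    ShortTermStore,
    StpOverlay,
)
from virtcog.terms import Substitution, format_term, parse_term

T = parse_term


class TestAssociativeStore:
    def test_ground_traces_only(self):
        store = AssociativeStore()
        store.add(T("image(box(f,toy,3))"), cycle=1)
        with pytest.raises(ProtocolError):
            store.add(T("image(box(f,P,3))"), cycle=1)

    def test_retrieval_bindings(self):
        store = AssociativeStore()
        store.add(T("image(box(f,toy,3))"), cycle=1)
        hit = store.retrieve(T("image(box(f,I,X))"))
        assert hit is not None
        _, s = hit
        assert format_term(s["I"]) == "toy" and format_term(s["X"]) == "3"

    def test_newest_first_and_non_destructive(self):
        store = AssociativeStore()
        store.add(T("image(box(f,toy,3))"), cycle=1)
        store.add(T("image(box(f,ball,4))"), cycle=2)
        trace, _ = store.retrieve(T("image(box(f,I,X))"))
        assert format_term(trace) == "image(box(f,ball,4))"
        # retrieval consumes nothing
        assert len(store) == 2
        trace2, _ = store.retrieve(T("image(box(f,I,X))"))
        assert format_term(trace2) == "image(box(f,ball,4))"

    def test_empty_store_misses(self):
        assert AssociativeStore().retrieve(T("image(X)")) is None

    def test_render(self):
        store = AssociativeStore()
        store.add(T("image(box(f,toy,3))"), cycle=1)
        assert store.render() == "{image(box(f,toy,3))}"


class TestShortTermStore:
    def test_fifo(self):
        stm = ShortTermStore()
        stm.push("look", T("look(obj(s1,2))"))
        stm.push("look", T("look(obj(s2,4))"))
        assert format_term(stm.pop("look")) == "look(obj(s1,2))"
        assert format_term(stm.pop("look")) == "look(obj(s2,4))"

    def test_empty_pop_is_marker_not_error(self):
        assert ShortTermStore().pop("look") is None

    def test_non_ground_push_rejected(self):
        with pytest.raises(ProtocolError):
            ShortTermStore().push("look", T("look(obj(Q,2))"))

    def test_render(self):
        stm = ShortTermStore()
        stm.push("look", T("look(obj(s1,2))"))
        assert stm.render("look") == "<look(obj(s1,2))>"


class TestStpOverlay:
    def test_duration_window(self):
        stp = StpOverlay()
        stp.open("p->q", cycle=3, duration=1)
        assert stp.is_open("p->q", 3)
        assert not stp.is_open("p->q", 4)

    def test_sweep(self):
        stp = StpOverlay()
        stp.open("p->q", cycle=3, duration=2)
        stp.sweep(5)
        assert not stp.any_active(5)


def _run(rulebase, stimuli, mode="strong"):
    model = build_model(rulebase, RunConfig(plasticity=mode))
    return run(model, [Stimulus(T(t), c) for c, t in stimuli])


class TestCoincidenceGatedLtp:
    def test_pairing_potentiates(self, mini_ltp_circuit):
        # two pairings, then the conditioned stimulus alone
        _, actions, _ = _run(
            mini_ltp_circuit,
            [(1, "a(1)"), (1, "b(1)"), (3, "a(1)"), (3, "b(1)"), (6, "a(1)")],
        )
        assert any(format_term(a.term) == "r(1)" and a.cycle == 6 for a in actions)

    def test_no_pairing_no_potentiation(self, mini_ltp_circuit):
        _, actions, _ = _run(
            mini_ltp_circuit,
            [(1, "a(1)"), (3, "b(1)"), (5, "a(1)"), (7, "b(1)"), (9, "a(1)")],
        )
        assert actions == []

    def test_weak_freezes_first_instance(self, mini_ltp_circuit):
        """A weakly potentiated pathway binds its first ground reaction;
        later inputs re-produce it instead of rebinding."""
        stimuli = [(1, "a(1)"), (1, "b(1)"), (4, "a(2)"), (4, "b(2)"), (7, "a(3)")]
        _, weak_actions, _ = _run(mini_ltp_circuit, stimuli, mode="weak")
        _, strong_actions, _ = _run(mini_ltp_circuit, stimuli, mode="strong")
        weak_terms = [format_term(a.term) for a in weak_actions]
        strong_terms = [format_term(a.term) for a in strong_actions]
        assert weak_terms[-1] == "r(1)"  # bound to the first association
        assert strong_terms[-1] == "r(3)"  # rebinds per activation

    def test_single_instantiation_modes_agree(self, mini_ltp_circuit):
        stimuli = [(1, "a(5)"), (1, "b(5)"), (4, "a(5)")]
        _, _, weak_trace = _run(mini_ltp_circuit, stimuli, mode="weak")
        _, _, strong_trace = _run(mini_ltp_circuit, stimuli, mode="strong")
        assert weak_trace.to_text() == strong_trace.to_text()


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    st.lists(st.integers(1, 8), max_size=5),
    st.lists(st.integers(1, 8), max_size=5),
)
def test_coincidence_necessity(mini_ltp_circuit_factory, a_cycles, b_cycles):
    """Over randomized stimulus schedules the pathway weight changes iff
    a join/merge pair co-occurred within the window (brute-force
    schedule scanner as oracle).  Window 1: a pairing is a cycle where
    both stimuli appear."""
    rulebase = mini_ltp_circuit_factory()
    stimuli = [Stimulus(T("a(1)"), c) for c in sorted(set(a_cycles))]
    stimuli += [Stimulus(T("b(1)"), c) for c in sorted(set(b_cycles))]
    model = build_model(rulebase, RunConfig(plasticity="strong"))
    run(model, stimuli)
    expected_pairs = len(set(a_cycles) & set(b_cycles))
    assert model.weights.get("s", "a", "r") == expected_pairs


@pytest.fixture(scope="module")
def mini_ltp_circuit_factory():
    from virtcog.compiler import compile_circuit, parse_circuit

    src = """\
circuit mini
stream s
node sensor s a a(X)
node sensor s b b(X)
node effector s r r(X)
edge synapse a r weight=0
ltp a r trigger=a partner=b window=1
"""

    def factory():
        return compile_circuit(parse_circuit(src))

    return factory


def test_ltp_monotone_without_ltd(mini_ltp_circuit):
    """Absent LTD/LTB, pathway weights are non-decreasing over a run."""
    model = build_model(mini_ltp_circuit, RunConfig())
    stimuli = [Stimulus(T("a(1)"), c) for c in (1, 2, 4, 6)]
    stimuli += [Stimulus(T("b(1)"), c) for c in (2, 4, 7)]
    seen = [0]
    run(model, stimuli)
    values = [
        int(e.payload.rsplit("=", 1)[1])
        for e in model.trace.events
        if e.kind == "weight" and "a->r" in e.payload
    ]
    assert values == sorted(values)


def test_ltd_closes_and_floors():
    from virtcog.compiler import compile_circuit, parse_circuit

    src = """\
circuit depress
stream s
node sensor s a a(X)
node sensor s d down
node effector s r r(X)
edge synapse a r weight=1
ltd a r trigger=d
"""
    rulebase = compile_circuit(parse_circuit(src))
    model = build_model(rulebase, RunConfig())
    run(model, [Stimulus(T("down"), 1), Stimulus(T("down"), 2), Stimulus(T("a(1)"), 4)])
    assert model.weights.get("s", "a", "r") == 0  # floored, not negative
    assert not any(e.kind == "action" for e in model.trace.events)


def test_ltb_blocks_forever():
    from virtcog.compiler import compile_circuit, parse_circuit
    from virtcog.substrate import BLOCKED

    src = """\
circuit blocker
stream s
node sensor s a a(X)
node sensor s x shut
node sensor s b boost(X)
node effector s r r(X)
edge synapse a r weight=1
ltb a r trigger=x
ltp a r trigger=a partner=b window=1
"""
    rulebase = compile_circuit(parse_circuit(src))
    model = build_model(rulebase, RunConfig())
    run(
        model,
        [
            Stimulus(T("shut"), 1),
            Stimulus(T("a(1)"), 3),
            Stimulus(T("boost(1)"), 3),
            Stimulus(T("a(1)"), 5),
        ],
    )
    # blocked edge never delivers again, and later potentiation is a no-op
    assert model.weights.get("s", "a", "r") is BLOCKED
    assert not any(e.kind == "action" for e in model.trace.events)
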