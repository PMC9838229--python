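"""Term algebra: unification, application, grounding, freshening."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from virtcog.terms import (
    EMPTY_SUBST,
    Anon,
    Atom,
    Int,
    Struct,
    Substitution,
    Var,
    apply,
    format_term,
    freshen,
    is_ground,
    parse_term,
    unify,
    variables,
    TermSyntaxError,
)


T = parse_term


class TestUnify:
    @pytest.mark.parametrize(
        "a,b,subst,expected",
        [
            ("obj(P,X)", "obj(toy,3)", {}, {"P": "toy", "X": "3"}),
            ("see(obj(_,2))", "see(obj(ball,2))", {}, {}),
            ("obj(toy,X+1)", "obj(toy,3)", {"X": "2"}, {"X": "2"}),
            ("f(X,X)", "f(a,a)", {}, {"X": "a"}),
        ],
    )
    def test_success(self, a, b, subst, expected):
        seed = Substitution({k: T(v) for k, v in subst.items()})
        out = unify(T(a), T(b), seed)
        assert out is not None
        assert {k: format_term(v) for k, v in out.items()} == expected

    @pytest.mark.parametrize(
        "a,b",
        [
            ("obj(toy,2)", "obj(ball,2)"),  # clashing atoms
            ("f(a)", "f(a,b)"),  # arity mismatch: failure, not exception
            ("f(a)", "g(a)"),
            ("obj(toy,X+1)", "obj(toy,3)"),  # unevaluable arithmetic
        ],
    )
    def test_failure(self, a, b):
        assert unify(T(a), T(b)) is None

    def test_anonymous_bindings_are_discarded(self):
        # two anonymous occurrences never co-refer
        out = unify(T("f(_,_)"), T("f(a,b)"))
        assert out is not None and len(out) == 0

    def test_arithmetic_forces_value(self):
        out = unify(T("obj(toy,X+1)"), T("obj(toy,4)"), Substitution({"X": Int(3)}))
        assert out is not None
        out2 = unify(T("obj(toy,X+1)"), T("obj(toy,5)"), Substitution({"X": Int(3)}))
        assert out2 is None

    def test_symmetry_on_enumerated_pairs(self):
        """unify(a,b) succeeds iff unify(b,a) succeeds on all small term
        pairs over a 4-symbol alphabet."""
        pool = [
            T(s)
            for s in ("a", "b", "X", "Y", "_", "f(a)", "f(X)", "f(a,b)", "f(X,Y)", "g(a)")
        ]
        for a, b in itertools.product(pool, repeat=2):
            left = unify(a, b)
            right = unify(b, a)
            assert (left is None) == (right is None), (a, b)


def _ground_terms(max_depth=3):
    leaves = st.one_of(
        st.sampled_from(["a", "b", "c", "d"]).map(Atom),
        st.integers(0, 5).map(Int),
    )
    return st.recursive(
        leaves,
        lambda children: st.builds(
            Struct,
            st.sampled_from(["f", "g"]),
            st.lists(children, min_size=1, max_size=2).map(tuple),
        ),
        max_leaves=4,
    )


def _patterns():
    leaves = st.one_of(
        st.sampled_from(["a", "b", "c", "d"]).map(Atom),
        st.integers(0, 5).map(Int),
        st.sampled_from(["X", "Y"]).map(Var),
    )
    return st.recursive(
        leaves,
        lambda children: st.builds(
            Struct,
            st.sampled_from(["f", "g"]),
            st.lists(children, min_size=1, max_size=2).map(tuple),
        ),
        max_leaves=4,
    )


def _subterms(t):
    yield t
    if isinstance(t, Struct):
        for a in t.args:
            yield from _subterms(a)


def brute_force_match(pattern, ground):
    """Substitution-enumeration oracle: try every assignment of the
    pattern's variables to ground subterms of the target."""
    vs = variables(pattern)
    candidates = list(dict.fromkeys(format_term(s) for s in _subterms(ground)))
    candidate_terms = [parse_term(c) for c in candidates]
    if not vs:
        return format_term(pattern) == format_term(ground)
    for combo in itertools.product(candidate_terms, repeat=len(vs)):
        s = Substitution(dict(zip(vs, combo)))
        if format_term(apply(s, pattern)) == format_term(ground):
            return True
    return False


@settings(max_examples=300, derandomize=True)
@given(_patterns(), _ground_terms())
def test_unify_agrees_with_enumeration_oracle(pattern, ground):
    got = unify(pattern, ground) is not None
    assert got == brute_force_match(pattern, ground)


@settings(max_examples=200, derandomize=True)
@given(_patterns(), _ground_terms())
def test_ground_application_reunifies(pattern, ground):
    """For all t, s: is_ground(apply(s,t)) implies unify(t, apply(s,t))
    succeeds."""
    s = unify(pattern, ground)
    if s is None:
        return
    applied = apply(s, pattern)
    if is_ground(applied):
        assert unify(pattern, applied) is not None


class TestApply:
    def test_offset_evaluation(self):
        out = apply(Substitution({"X": Int(2)}), T("look(obj(Q,X+1))"))
        assert format_term(out) == "look(obj(Q,3))"

    def test_identity(self):
        t = T("grasp(obj(toy,4))")
        assert apply(EMPTY_SUBST, t) is t or format_term(apply(EMPTY_SUBST, t)) == format_term(t)

    def test_partial(self):
        out = apply(Substitution({"P": Atom("toy")}), T("grasp(obj(P,4))"))
        assert format_term(out) == "grasp(obj(toy,4))"


class TestGroundAndFreshen:
    @pytest.mark.parametrize(
        "text,expected",
        [("obj(toy,3)", True), ("obj(P,3)", False), ("obj(toy,X+1)", False), ("_", False)],
    )
    def test_is_ground(self, text, expected):
        assert is_ground(T(text)) is expected

    def test_freshen_renames_consistently(self):
        t = T("f(P,X,P)")
        out = freshen(t)
        assert isinstance(out, Struct)
        p1, x1, p2 = out.args
        assert p1 == p2 and p1 != x1
        assert p1.name not in ("P", "X")

    def test_freshen_identity_on_ground(self):
        t = T("obj(toy,3)")
        assert format_term(freshen(t)) == "obj(toy,3)"

    def test_freshen_distinct_anonymous(self):
        out = freshen(T("f(_,_)"))
        assert isinstance(out.args[0], Anon) and isinstance(out.args[1], Anon)
        assert out.args[0].ident != out.args[1].ident


class TestSyntax:
    @settings(max_examples=200, derandomize=True)
    @given(_ground_terms())
    def test_round_trip_lossless_on_ground_terms(self, t):
        assert format_term(parse_term(format_term(t))) == format_term(t)

    @pytest.mark.parametrize("bad", ["", "f(", "f(a,,b)", "3+", "f(a))", "+2"])
    def test_syntax_errors(self, bad):
        with pytest.raises(TermSyntaxError):
            parse_term(bad)

    def test_anonymous_parse_distinct(self):
        t = parse_term("f(_,_)")
        assert t.args[0].ident != t.args[1].ident
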