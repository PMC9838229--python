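"""Circuit parsing, validation, compilation and contextual deduction."""

import random

import pytest

from conftest import brute_force_ist, ist_rendered, random_instance

from virtcog.compiler import (
    CircuitError,
    DeliveredCond,
    Fact,
    FireOp,
    FiredCond,
    Implication,
    compile_circuit,
    ist,
    parse_circuit,
    validate_circuit,
)
from virtcog.experiments import build_circuit
from virtcog.terms import format_term, parse_term

T = parse_term


class TestParse:
    def test_grasp_circuit_structure(self):
        spec = build_circuit("substage1_2")
        assert len(spec.nodes) == 3
        conj = [e for e in spec.edges if e.kind == "conj"]
        assert len(conj) == 1 and len(conj[0].sources) == 2
        assert [a.kind for a in spec.annotations] == ["stp"]

    def test_empty_source_is_error(self):
        with pytest.raises(CircuitError, match="no nodes"):
            parse_circuit("")

    @pytest.mark.parametrize(
        "src,msg",
        [
            ("node widget s a a(X)", "unknown node kind"),
            ("circuit x\nnode sensor s a a(X)\nedge warp a a", "unknown connector"),
            ("frobnicate", "unknown declaration"),
            ("circuit x\nnode sensor s a f(", "bad term"),
        ],
    )
    def test_syntax_errors_carry_line_info(self, src, msg):
        with pytest.raises(CircuitError, match=msg):
            parse_circuit(src)


class TestValidate:
    def test_builtin_circuits_are_clean(self):
        for name in ("substage1_2", "substage3", "substage4", "substage5",
                     "substage6", "aplysia", "operant"):
            assert validate_circuit(build_circuit(name)) == []

    def test_edge_to_undeclared_node(self):
        spec = parse_circuit("circuit x\nstream s\nnode sensor s a a(X)\nedge synapse a ghost")
        assert any("ghost" in r for r in validate_circuit(spec))

    def test_plasticity_must_attach_to_existing_pathway(self):
        spec = parse_circuit(
            "circuit x\nstream s\nnode sensor s a a(X)\nnode effector s b b(X)\n"
            "ltp a b trigger=a partner=a"
        )
        assert any("missing pathway" in r for r in validate_circuit(spec))

    def test_conjunction_needs_two_sources(self):
        spec = parse_circuit(
            "circuit x\nstream s\nnode sensor s a a(X)\nnode effector s b b(X)\n"
            "edge conj a b"
        )
        assert any(">= 2 sources" in r for r in validate_circuit(spec))

    def test_undeclared_stream(self):
        spec = parse_circuit("circuit x\nnode sensor phantom a a(X)")
        assert any("undeclared stream" in r for r in validate_circuit(spec))


class TestCompile:
    def test_single_synapse_compiles_to_guarded_fire(self):
        spec = parse_circuit(
            "circuit m\nstream s\nnode sensor s p p(X)\nnode effector s q q(X)\n"
            "edge synapse p q"
        )
        rb = compile_circuit(spec)
        assert len(rb.implications) == 1
        imp = rb.implications[0]
        assert isinstance(imp.guard[0], DeliveredCond)
        assert isinstance(imp.instructions[0], FireOp)
        assert imp.instructions[0].node == "q"

    def test_compilation_is_pure_and_order_stable(self):
        a = compile_circuit(build_circuit("substage6")).render()
        b = compile_circuit(build_circuit("substage6")).render()
        assert a == b

    def test_range_restriction_enforced(self):
        spec = parse_circuit(
            "circuit m\nstream s\nnode sensor s p p(X)\nnode effector s q q(X,Z)\n"
            "edge synapse p q"
        )
        with pytest.raises(CircuitError, match="range restriction"):
            compile_circuit(spec)

    def test_extension_chain(self):
        """Each later substage circuit strictly extends the previous one."""
        s3 = build_circuit("substage3")
        s4 = build_circuit("substage4")
        s5 = build_circuit("substage5")
        s6 = build_circuit("substage6")
        assert s4.contains(s3) and not s3.contains(s4)
        assert s5.contains(s4)
        assert s6.contains(s5)


class TestIst:
    def test_empty_model(self):
        rules = compile_circuit(build_circuit("substage1_2")).implications
        assert ist([], rules) == []

    def test_single_matching_guard(self):
        imp = Implication(
            index=1,
            guard=(FiredCond("p", T("p(X)")),),
            instructions=(FireOp("q", T("q(X)")),),
        )
        facts = [Fact(1, "fired", "p", T("p(3)"), 1, 1)]
        out = ist(facts, [imp])
        assert len(out) == 1
        rendered = format_term(
            __import__("virtcog.terms", fromlist=["apply"]).apply(
                out[0].binding, out[0].instructions[0].pattern
            )
        )
        assert rendered == "q(3)"
        assert out[0].consumed == (1,)

    def test_consumption_prevents_double_use(self):
        imp1 = Implication(1, (FiredCond("p", T("p(X)")),), (FireOp("q", T("q(X)")),))
        imp2 = Implication(2, (FiredCond("p", T("p(X)")),), (FireOp("r", T("r(X)")),))
        facts = [Fact(1, "fired", "p", T("p(3)"), 1, 1)]
        out = ist(facts, [imp1, imp2])
        assert [d.implication.index for d in out] == [1]

    def test_choice_group_first_match_wins(self):
        imp1 = Implication(1, (FiredCond("p", T("p(a)")),), (FireOp("q", T("q1")),),
                           choice_group="g")
        imp2 = Implication(2, (FiredCond("p", T("p(X)")),), (FireOp("q", T("q2")),),
                           choice_group="g")
        facts = [Fact(1, "fired", "p", T("p(a)"), 1, 1)]
        assert [d.implication.index for d in ist(facts, [imp1, imp2])] == [1]
        facts = [Fact(1, "fired", "p", T("p(b)"), 1, 1)]
        assert [d.implication.index for d in ist(facts, [imp1, imp2])] == [2]

    @pytest.mark.parametrize("seed", range(120))
    def test_matches_brute_force_enumeration(self, seed):
        """On random circuits (<= 10 implications, <= 8 facts) ist equals
        cross-product guard-instantiation enumeration."""
        rng = random.Random(seed)
        rules, facts = random_instance(rng)
        assert ist_rendered(facts, rules) == brute_force_ist(facts, rules)
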