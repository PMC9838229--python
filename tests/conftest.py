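"""Shared fixtures and independent oracles for the suite."""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

import pytest

from virtcog.compiler import Fact, FireOp, FiredCond, Implication
from virtcog.terms import (
    Atom,
    Int,
    Struct,
    Var,
    apply,
    format_term,
    parse_term,
    unify,
)

ATOMS = ["a", "b", "c", "d"]


# ---------------------------------------------------------------------------
# random (rule base, facts) instances for the contextual-deduction oracle

def random_term(rng: random.Random, depth: int, vars_pool: list[str], ground: bool):
    roll = rng.random()
    if depth <= 0 or roll < 0.35:
        return Atom(rng.choice(ATOMS))
    if roll < 0.5:
        return Int(rng.randint(0, 3))
    if not ground and roll < 0.7 and vars_pool:
        return Var(rng.choice(vars_pool))
    arity = rng.randint(1, 2)
    return Struct(
        rng.choice(["f", "g"]),
        tuple(random_term(rng, depth - 1, vars_pool, ground) for _ in range(arity)),
    )


def random_instance(rng: random.Random, max_rules: int = 10, max_facts: int = 8):
    """A random rule base (guards over fired-facts only) plus a random
    fact context, within the stated size bounds."""
    nodes = ["p", "q", "r"]
    facts = [
        Fact(i + 1, "fired", rng.choice(nodes), random_term(rng, 2, [], ground=True), 1, 1)
        for i in range(rng.randint(0, max_facts))
    ]
    rules = []
    n_groups = rng.randint(0, 2)
    groups = [f"g{i}" for i in range(n_groups)]
    for idx in range(1, rng.randint(1, max_rules) + 1):
        vars_pool = ["X", "Y"]
        n_conds = rng.randint(1, 2)
        guard = tuple(
            FiredCond(
                rng.choice(nodes),
                random_term(rng, 2, vars_pool, ground=False),
                consume=rng.random() < 0.8,
            )
            for _ in range(n_conds)
        )
        out_vars = sorted({v for c in guard for v in _vars(c.pattern)})
        instr_pat = Struct("out", tuple(Var(v) for v in out_vars)) if out_vars else Atom("out")
        rules.append(
            Implication(
                index=idx,
                guard=guard,
                instructions=(FireOp("sink", instr_pat),),
                choice_group=rng.choice(groups) if groups and rng.random() < 0.3 else None,
            )
        )
    return rules, facts


def _vars(t):
    from virtcog.terms import variables

    return variables(t)


def brute_force_ist(facts, rules):
    """Independent oracle for contextual deduction: per rule (in order),
    enumerate the full cross-product of fact assignments to guard
    conditions in fact order, take the first that unifies with distinct,
    unconsumed facts; consume; repeat until no assignment matches.  At
    most one deduction per choice group.  Returns (rule index, consumed
    fact ids, canonical instruction rendering) triples."""
    consumed: set[int] = set()
    done_groups: set[str] = set()
    seen: set[tuple] = set()
    out = []
    for rule in rules:
        if rule.choice_group is not None and rule.choice_group in done_groups:
            continue
        while True:
            hit = None
            for combo in itertools.product(facts, repeat=len(rule.guard)):
                ids = tuple(f.fid for f in combo)
                if len(set(ids)) != len(ids):
                    continue
                if any(f.fid in consumed for f in combo):
                    continue
                if (rule.index, ids) in seen:
                    continue
                if any(f.key != c.node for f, c in zip(combo, rule.guard)):
                    continue
                s = {}
                from virtcog.terms import EMPTY_SUBST, freshen

                mapping = {}
                sub = EMPTY_SUBST
                ok = True
                fresh_guard = [freshen(c.pattern, mapping) for c in rule.guard]
                fresh_instr = [
                    freshen(op.pattern, mapping) for op in rule.instructions
                ]
                for f, pat in zip(combo, fresh_guard):
                    sub = unify(pat, f.term, sub)
                    if sub is None:
                        ok = False
                        break
                if not ok:
                    continue
                hit = (ids, combo, sub, fresh_instr)
                break
            if hit is None:
                break
            ids, combo, sub, fresh_instr = hit
            seen.add((rule.index, ids))
            for f, c in zip(combo, rule.guard):
                if c.consume:
                    consumed.add(f.fid)
            rendering = tuple(format_term(apply(sub, p)) for p in fresh_instr)
            out.append((rule.index, tuple(
                f.fid for f, c in zip(combo, rule.guard) if c.consume
            ), rendering))
            if rule.choice_group is not None:
                done_groups.add(rule.choice_group)
                break
    return out


def ist_rendered(facts, rules):
    """Run the implementation and render deductions the same way the
    oracle does."""
    from virtcog.compiler import ist

    out = []
    for ded in ist(list(facts), rules):
        rendering = tuple(
            format_term(apply(ded.binding, op.pattern))
            for op in ded.instructions
            if isinstance(op, FireOp)
        )
        out.append((ded.implication.index, ded.consumed, rendering))
    return out


@pytest.fixture
def mini_ltp_circuit():
    """A minimal potentiation circuit: pathway a->r opens by pairing the
    a and b stimuli in the same cycle."""
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
    return compile_circuit(parse_circuit(src))
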