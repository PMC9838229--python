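"""First-order term algebra with named/anonymous variables and +k offsets.

Terms carry every symbol that appears in circuits, stimuli and traces:
atoms (``toy``, ``cs``), integers (positions on the one-dimensional spatial
axis), named variables (``X``, ``P`` — uppercase), anonymous variables
(``_`` — pairwise distinct, never co-referring), compounds (``obj(P, X)``)
and arithmetic offsets (``X+1``, the saccade-anticipation convention).

The object-at-position notation is encoded first-order as ``obj(Image,
Position)`` and box contents as ``box(BoxId, Contents, Position)``, which
keeps unification standard and decidable.

Anonymous variables implement *weak* binding: they may be matched, but the
match is consumed and never recorded, so a weakly potentiated pathway that
was instantiated once can never re-instantiate differently.  Named
variables implement *strong* binding and may be rebound per activation.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Union

__all__ = [
    "Term",
    "Atom",
    "Int",
    "Var",
    "Anon",
    "Struct",
    "Arith",
    "Substitution",
    "EMPTY_SUBST",
    "unify",
    "apply",
    "is_ground",
    "freshen",
    "variables",
    "parse_term",
    "format_term",
    "TermSyntaxError",
]

_anon_counter = itertools.count(1)
_fresh_counter = itertools.count(1)


@dataclass(frozen=True)
class Atom:
    name: str

    def __repr__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Int:
    value: int

    def __repr__(self) -> str:
        return str(self.value)


@dataclass(frozen=True)
class Var:
    """Named variable; scoped per compiled implication instance."""

    name: str

    def __repr__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Anon:
    """Anonymous variable.  Each occurrence is distinct (fresh ident)."""

    ident: int = field(default_factory=lambda: next(_anon_counter))

    def __repr__(self) -> str:
        return "_"


@dataclass(frozen=True)
class Struct:
    functor: str
    args: tuple["Term", ...]

    def __repr__(self) -> str:
        return f"{self.functor}({', '.join(map(repr, self.args))})"


@dataclass(frozen=True)
class Arith:
    """``base + offset`` on the integer axis; evaluated eagerly once the
    base is bound."""

    base: "Term"
    offset: int

    def __repr__(self) -> str:
        if self.offset >= 0:
            return f"{self.base!r}+{self.offset}"
        return f"{self.base!r}-{-self.offset}"


Term = Union[Atom, Int, Var, Anon, Struct, Arith]


class Substitution(Mapping[str, Term]):
    """Idempotent mapping from named-variable names to terms.

    Never holds bindings for anonymous variables: those are consumed by a
    match but not recorded.
    """

    __slots__ = ("_map",)

    def __init__(self, mapping: Optional[Mapping[str, Term]] = None):
        self._map: dict[str, Term] = dict(mapping) if mapping else {}

    def __getitem__(self, key: str) -> Term:
        return self._map[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}->{v!r}" for k, v in sorted(self._map.items()))
        return "{" + inner + "}"

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Substitution):
            return self._map == other._map
        if isinstance(other, Mapping):
            return self._map == dict(other)
        return NotImplemented

    def __hash__(self):  # pragma: no cover - substitutions are not hashed
        raise TypeError("Substitution is unhashable")

    def bind(self, name: str, value: Term) -> "Substitution":
        new = dict(self._map)
        new[name] = value
        return Substitution(new)

    def merged(self, other: "Substitution") -> "Substitution":
        new = dict(self._map)
        new.update(other._map)
        return Substitution(new)


EMPTY_SUBST = Substitution()


def walk(t: Term, s: Substitution) -> Term:
    """Resolve a variable through the substitution chain."""
    while isinstance(t, Var) and t.name in s:
        t = s[t.name]
    return t


def _eval_arith(t: Arith, s: Substitution) -> Term:
    base = walk(t.base, s)
    if isinstance(base, Arith):
        base = _eval_arith(base, s)
    if isinstance(base, Int):
        return Int(base.value + t.offset)
    return Arith(base, t.offset)


def unify(a: Term, b: Term, s: Substitution = EMPTY_SUBST) -> Optional[Substitution]:
    """Most general unifier of ``a`` and ``b`` extending ``s``.

    Returns ``None`` on failure (never raises for clash or arity mismatch).
    Anonymous variables match anything but leave no binding behind.
    Arithmetic sub-terms are evaluated eagerly when their base is bound;
    an unevaluable arithmetic term fails the match.  No occurs-check:
    circuit guards are shallow and cyclic terms cannot arise from the DSL.
    """
    a = walk(a, s)
    b = walk(b, s)
    if isinstance(a, Arith):
        a = _eval_arith(a, s)
    if isinstance(b, Arith):
        b = _eval_arith(b, s)
    if isinstance(a, Anon) or isinstance(b, Anon):
        return s
    if isinstance(a, Var):
        if isinstance(b, Var) and b.name == a.name:
            return s
        return s.bind(a.name, b)
    if isinstance(b, Var):
        return s.bind(b.name, a)
    if isinstance(a, Atom) and isinstance(b, Atom):
        return s if a.name == b.name else None
    if isinstance(a, Int) and isinstance(b, Int):
        return s if a.value == b.value else None
    if isinstance(a, Struct) and isinstance(b, Struct):
        if a.functor != b.functor or len(a.args) != len(b.args):
            return None
        for x, y in zip(a.args, b.args):
            s2 = unify(x, y, s)
            if s2 is None:
                return None
            s = s2
        return s
    if isinstance(a, Arith) or isinstance(b, Arith):
        # unevaluable arithmetic (unbound base) never matches
        return None
    return None


def apply(s: Substitution, t: Term) -> Term:
    """Apply ``s`` to ``t``: replace bound named variables, evaluate
    arithmetic whose base became an integer; unbound variables pass
    through untouched."""
    t = walk(t, s)
    if isinstance(t, (Atom, Int, Anon)):
        return t
    if isinstance(t, Var):
        return t
    if isinstance(t, Struct):
        return Struct(t.functor, tuple(apply(s, a) for a in t.args))
    if isinstance(t, Arith):
        evaluated = _eval_arith(Arith(apply(s, t.base), t.offset), s)
        return evaluated
    raise TypeError(f"not a term: {t!r}")


def is_ground(t: Term) -> bool:
    """True iff ``t`` contains no variables and no unevaluated arithmetic."""
    if isinstance(t, (Atom, Int)):
        return True
    if isinstance(t, (Var, Anon, Arith)):
        return False
    if isinstance(t, Struct):
        return all(is_ground(a) for a in t.args)
    raise TypeError(f"not a term: {t!r}")


def variables(t: Term) -> list[str]:
    """Named variables of ``t`` in first-appearance order."""
    out: list[str] = []

    def visit(u: Term) -> None:
        if isinstance(u, Var):
            if u.name not in out:
                out.append(u.name)
        elif isinstance(u, Struct):
            for a in u.args:
                visit(a)
        elif isinstance(u, Arith):
            visit(u.base)

    visit(t)
    return out


def freshen(t: Term, mapping: Optional[dict[str, str]] = None) -> Term:
    """Consistently rename named variables to globally unused names and
    replace every anonymous variable by a fresh distinct one."""
    if mapping is None:
        mapping = {}

    def visit(u: Term) -> Term:
        if isinstance(u, Var):
            if u.name not in mapping:
                mapping[u.name] = f"{u.name}${next(_fresh_counter)}"
            return Var(mapping[u.name])
        if isinstance(u, Anon):
            return Anon()
        if isinstance(u, Struct):
            return Struct(u.functor, tuple(visit(a) for a in u.args))
        if isinstance(u, Arith):
            return Arith(visit(u.base), u.offset)
        return u

    return visit(t)


# ---------------------------------------------------------------------------
# literal syntax: lowercase atoms, Uppercase named vars, `_` anonymous,
# f(a,B,_) compounds, X+1 offsets.  Round-trip is lossless for ground terms.

class TermSyntaxError(ValueError):
    pass


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<int>-?\d+)|(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<punct>[(),+\-]))"
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            rest = text[pos:].strip()
            if not rest:
                break
            raise TermSyntaxError(f"bad character at {text[pos:]!r}")
        pos = m.end()
        if m.group("int") is not None:
            tokens.append(("int", m.group("int")))
        elif m.group("name") is not None:
            tokens.append(("name", m.group("name")))
        else:
            tokens.append(("punct", m.group("punct")))
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], text: str):
        self.tokens = tokens
        self.i = 0
        self.text = text

    def peek(self) -> Optional[tuple[str, str]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise TermSyntaxError(f"unexpected end of term in {self.text!r}")
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        kind, val = self.next()
        if val != value:
            raise TermSyntaxError(f"expected {value!r}, got {val!r} in {self.text!r}")

    def term(self) -> Term:
        base = self.primary()
        tok = self.peek()
        if tok is not None and tok[1] in ("+", "-"):
            self.next()
            kind, val = self.next()
            if kind != "int":
                raise TermSyntaxError(f"offset must be an integer in {self.text!r}")
            k = int(val) if tok[1] == "+" else -int(val)
            if isinstance(base, Int):
                return Int(base.value + k)
            return Arith(base, k)
        return base

    def primary(self) -> Term:
        kind, val = self.next()
        if kind == "int":
            return Int(int(val))
        if kind == "punct":
            raise TermSyntaxError(f"unexpected {val!r} in {self.text!r}")
        if val == "_":
            return Anon()
        first = val[0]
        if first.isupper() or (first == "_" and len(val) > 1):
            return Var(val)
        tok = self.peek()
        if tok is not None and tok[1] == "(":
            self.next()
            args: list[Term] = [self.term()]
            while self.peek() is not None and self.peek()[1] == ",":
                self.next()
                args.append(self.term())
            self.expect(")")
            return Struct(val, tuple(args))
        return Atom(val)


def parse_term(text: str) -> Term:
    """Parse a term literal.  Raises :class:`TermSyntaxError` on bad input."""
    tokens = _tokenize(text)
    if not tokens:
        raise TermSyntaxError("empty term")
    p = _Parser(tokens, text)
    t = p.term()
    if p.peek() is not None:
        raise TermSyntaxError(f"trailing input in {text!r}")
    return t


def format_term(t: Term) -> str:
    """Canonical textual rendering; inverse of :func:`parse_term` on
    ground terms."""
    if isinstance(t, Atom):
        return t.name
    if isinstance(t, Int):
        return str(t.value)
    if isinstance(t, Var):
        return t.name
    if isinstance(t, Anon):
        return "_"
    if isinstance(t, Struct):
        return f"{t.functor}({','.join(format_term(a) for a in t.args)})"
    if isinstance(t, Arith):
        sign = "+" if t.offset >= 0 else "-"
        return f"{format_term(t.base)}{sign}{abs(t.offset)}"
    raise TypeError(f"not a term: {t!r}")
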