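"""SWRL-style rules and SQWRL-style queries over an :class:`InstanceGraph`.

The rule language is a plain-text rendering of rules as they are
conventionally printed: prefixed atoms joined by ``^`` (also ``∧``/``Λ``),
with ``->`` (or ``→``) separating antecedent from consequent::

    rule classify-rad9:
      tuo:Protein(?someEntity) ^ tuo:synonym(?someEntity, ?s)
        ^ swrlb:containsIgnoreCase(?s, "rad9")
      -> tuo:Rad9(?someEntity)

A consequent of ``sqwrl:select(...)`` makes the stanza a query instead of a
rule; query results are presented to the caller but never stored back in
the graph.  ``swrlx:makeOWLThing(?new, ?anchor)`` in a consequent mints a
new individual, guarded so that re-running the rule for the same binding
reuses the individual it already created instead of multiplying duplicates.

Evaluation is forward chaining to fixpoint with subclass-closed class-atom
matching; defined classes (named class / intersection / existential
restriction expressions) are classified by iterated semantic evaluation.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

from .instance_graph import Instance, InstanceGraph, Literal, UnknownSymbolError

__all__ = [
    "RuleParseError",
    "ChainingLimitError",
    "Var",
    "Atom",
    "Rule",
    "SelectQuery",
    "Named",
    "IntersectionOf",
    "SomeValuesFrom",
    "ClassExpression",
    "BUILTINS",
    "eval_builtin",
    "parse_rule",
    "parse_rule_file",
    "parse_class_expression",
    "parse_defined_classes",
    "match",
    "apply_rules",
    "select",
    "classify",
]


class RuleParseError(ValueError):
    """Syntax or safety error in a rule/query/expression, with position."""


class ChainingLimitError(RuntimeError):
    """Forward chaining exceeded its round bound (possible non-termination)."""


# ---------------------------------------------------------------------------
# builtins
# ---------------------------------------------------------------------------

def _contains_ignore_case(a: str, b: str) -> bool:
    return b.lower() in a.lower()


BUILTINS: dict[str, tuple[int, Callable[..., bool]]] = {
    "swrlb:containsIgnoreCase": (2, _contains_ignore_case),
    # the OCR-typo spelling seen in print is accepted as an alias
    "swrlb:containslgnoreCase": (2, _contains_ignore_case),
    "swrlb:contains": (2, lambda a, b: b in a),
    "swrlb:equal": (2, lambda a, b: a == b),
    "swrlb:stringEqualIgnoreCase": (2, lambda a, b: a.lower() == b.lower()),
}

#: consequent-only pseudo-builtin that mints a new individual
MAKE_INDIVIDUAL = "swrlx:makeOWLThing"


def eval_builtin(name: str, args: Sequence[str]) -> bool:
    """Evaluate a registered builtin on literal string arguments (pure)."""
    if name not in BUILTINS:
        raise RuleParseError(f"unregistered builtin {name!r}")
    arity, fn = BUILTINS[name]
    if len(args) != arity:
        raise RuleParseError(f"builtin {name} expects {arity} args, got {len(args)}")
    return fn(*args)


# ---------------------------------------------------------------------------
# syntax
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Var:
    name: str

    def __repr__(self) -> str:
        return f"?{self.name}"


Arg = Union[Var, Literal]


@dataclass(frozen=True)
class Atom:
    """One predicate application: class, property, builtin, or select."""

    kind: str  # class | property | builtin | select | make
    predicate: str
    args: tuple[Arg, ...]

    def variables(self) -> list[str]:
        return [a.name for a in self.args if isinstance(a, Var)]


@dataclass
class Rule:
    antecedent: list[Atom]
    consequent: list[Atom]
    id: str = "rule"


@dataclass
class SelectQuery:
    antecedent: list[Atom]
    projection: list[str]
    id: str = "query"


# class expressions --------------------------------------------------------

@dataclass(frozen=True)
class Named:
    cls: str


@dataclass(frozen=True)
class IntersectionOf:
    parts: tuple


@dataclass(frozen=True)
class SomeValuesFrom:
    prop: str
    filler: object


ClassExpression = Union[Named, IntersectionOf, SomeValuesFrom]


# tokenizer ----------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<comment>\#[^\n]*)
  | (?P<arrow>->|→)
  | (?P<and>\^|∧|Λ)
  | (?P<var>\?[A-Za-z_][\w.-]*(?::[A-Za-z_][\w.-]*)?)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<ident>[A-Za-z_][\w.-]*(?::[A-Za-z_][\w.-]*)?)
  | (?P<lpar>\()
  | (?P<rpar>\))
  | (?P<comma>,)
    """,
    re.VERBOSE,
)


def _tokenize(text: str):
    pos = 0
    out = []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise RuleParseError(f"unexpected character {text[pos]!r} at offset {pos}")
        pos = m.end()
        kind = m.lastgroup
        if kind in ("ws", "comment"):
            continue
        out.append((kind, m.group(), m.start()))
    out.append(("eof", "", len(text)))
    return out


class _Parser:
    def __init__(self, text: str):
        self.toks = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.toks[self.i]

    def take(self, kind: str, what: str = ""):
        k, v, pos = self.toks[self.i]
        if k != kind:
            raise RuleParseError(f"expected {what or kind} at offset {pos}, found {v!r}")
        self.i += 1
        return v

    def at(self, kind: str) -> bool:
        return self.toks[self.i][0] == kind

    # atoms ---------------------------------------------------------------

    def parse_atom(self) -> Atom:
        pred = self.take("ident", "predicate name")
        self.take("lpar", "'('")
        args: list[Arg] = []
        if not self.at("rpar"):
            args.append(self.parse_arg())
            while self.at("comma"):
                self.take("comma")
                args.append(self.parse_arg())
        self.take("rpar", "')'")
        return _classify_atom(pred, tuple(args))

    def parse_arg(self) -> Arg:
        if self.at("var"):
            raw = self.take("var")[1:]
            # variables may be written prefixed (?rules:s); the prefix is
            # a notational namespace and is stripped
            return Var(raw.rsplit(":", 1)[-1])
        if self.at("string"):
            raw = self.take("string")
            return Literal(raw[1:-1].replace('\\"', '"').replace("\\\\", "\\"))
        if self.at("ident"):
            # bare identifier constant is treated as a text literal
            return Literal(self.take("ident"))
        k, v, pos = self.peek()
        raise RuleParseError(f"expected argument at offset {pos}, found {v!r}")

    def parse_conjunction(self) -> list[Atom]:
        atoms = [self.parse_atom()]
        while self.at("and"):
            self.take("and")
            atoms.append(self.parse_atom())
        return atoms

    # class expressions ---------------------------------------------------

    def parse_expr(self) -> ClassExpression:
        parts = [self.parse_term()]
        while self.at("ident") and self.peek()[1] == "and":
            self.take("ident")
            parts.append(self.parse_term())
        return parts[0] if len(parts) == 1 else IntersectionOf(tuple(parts))

    def parse_term(self) -> ClassExpression:
        if self.at("lpar"):
            self.take("lpar")
            inner = self.parse_expr()
            self.take("rpar", "')'")
            return inner
        name = self.take("ident", "class or property name")
        if self.at("ident") and self.peek()[1] == "some":
            self.take("ident")
            return SomeValuesFrom(name, self.parse_primary())
        return Named(name)

    def parse_primary(self) -> ClassExpression:
        if self.at("lpar"):
            self.take("lpar")
            inner = self.parse_expr()
            self.take("rpar", "')'")
            return inner
        name = self.take("ident", "class name")
        if self.at("ident") and self.peek()[1] == "some":
            self.take("ident")
            return SomeValuesFrom(name, self.parse_primary())
        return Named(name)


def _classify_atom(pred: str, args: tuple[Arg, ...]) -> Atom:
    prefix = pred.split(":", 1)[0] if ":" in pred else ""
    if pred == "sqwrl:select":
        if not args:
            raise RuleParseError("sqwrl:select needs at least one argument")
        return Atom("select", pred, args)
    if pred == MAKE_INDIVIDUAL:
        if len(args) < 1 or not isinstance(args[0], Var):
            raise RuleParseError(f"{MAKE_INDIVIDUAL} needs a leading variable argument")
        return Atom("make", pred, args)
    if prefix == "swrlb":
        if pred not in BUILTINS:
            raise RuleParseError(f"unregistered builtin {pred!r}")
        arity = BUILTINS[pred][0]
        if len(args) != arity:
            raise RuleParseError(f"builtin {pred} expects {arity} args, got {len(args)}")
        return Atom("builtin", pred, args)
    if len(args) == 1:
        return Atom("class", pred, args)
    if len(args) == 2:
        return Atom("property", pred, args)
    raise RuleParseError(f"atom {pred} has {len(args)} arguments; expected 1 or 2")


def parse_rule(text: str, id: str = "rule") -> Union[Rule, SelectQuery]:
    """Parse one rule or query stanza and enforce safety conditions."""
    p = _Parser(text)
    antecedent = p.parse_conjunction()
    p.take("arrow", "'->'")
    consequent = p.parse_conjunction()
    if not p.at("eof"):
        k, v, pos = p.peek()
        raise RuleParseError(f"trailing input at offset {pos}: {v!r}")

    bound = {v for a in antecedent for v in a.variables()}
    for a in antecedent:
        if a.kind in ("select", "make"):
            raise RuleParseError(f"{a.predicate} is not allowed in an antecedent")

    selects = [a for a in consequent if a.kind == "select"]
    if selects:
        if len(consequent) != 1:
            raise RuleParseError("sqwrl:select must be the sole consequent atom")
        proj = []
        for arg in selects[0].args:
            if not isinstance(arg, Var):
                raise RuleParseError("sqwrl:select arguments must be variables")
            if arg.name not in bound:
                raise RuleParseError(f"projection variable ?{arg.name} not bound in antecedent")
            proj.append(arg.name)
        return SelectQuery(antecedent, proj, id=id)

    introduced: set[str] = set()
    for a in consequent:
        if a.kind == "make":
            for extra in a.args[1:]:
                if isinstance(extra, Var) and extra.name not in bound | introduced:
                    raise RuleParseError(
                        f"?{extra.name} in {MAKE_INDIVIDUAL} not bound in antecedent"
                    )
            introduced.add(a.args[0].name)
            continue
        if a.kind == "builtin":
            raise RuleParseError(f"builtin {a.predicate} is not allowed in a consequent")
        for v in a.variables():
            if v not in bound | introduced:
                raise RuleParseError(f"consequent variable ?{v} not bound in antecedent")
    return Rule(antecedent, consequent, id=id)


_STANZA_HEADER = re.compile(r"^(rule|query)\s+([\w.:-]+)\s*:\s*$")


def parse_rule_file(text: str) -> list[Union[Rule, SelectQuery]]:
    """Parse a rules file: ``#`` comments, blank-line-separated stanzas,
    each optionally headed by ``rule <id>:`` / ``query <id>:``."""
    out: list[Union[Rule, SelectQuery]] = []
    stanza_lines: list[str] = []
    stanza_id: Optional[str] = None
    n_anon = 0

    def flush():
        nonlocal stanza_lines, stanza_id, n_anon
        body = "\n".join(stanza_lines).strip()
        if body:
            rid = stanza_id or f"rule{n_anon + 1}"
            n_anon += 1
            out.append(parse_rule(body, id=rid))
        stanza_lines, stanza_id = [], None

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            flush()
            continue
        m = _STANZA_HEADER.match(line.strip())
        if m:
            flush()
            stanza_id = m.group(2)
            continue
        stanza_lines.append(line)
    flush()
    return out


def parse_class_expression(text: str) -> ClassExpression:
    p = _Parser(text)
    expr = p.parse_expr()
    if not p.at("eof"):
        k, v, pos = p.peek()
        raise RuleParseError(f"trailing input at offset {pos}: {v!r}")
    return expr


_DEFINE_HEADER = re.compile(r"^define\s+([\w.:-]+)(?:\s*<\s*([\w.:-]+))?\s*:\s*$")


def parse_defined_classes(text: str) -> list[tuple[str, Optional[str], ClassExpression]]:
    """Parse a defined-class file into (name, optional parent, expression)."""
    out = []
    name: Optional[str] = None
    parent: Optional[str] = None
    body: list[str] = []

    def flush():
        nonlocal name, parent, body
        src = "\n".join(body).strip()
        if name and src:
            out.append((name, parent, parse_class_expression(src)))
        elif src and not name:
            raise RuleParseError("expression without a 'define <name>:' header")
        name, parent, body = None, None, []

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            flush()
            continue
        m = _DEFINE_HEADER.match(line.strip())
        if m:
            flush()
            name, parent = m.group(1), m.group(2)
            continue
        body.append(line)
    flush()
    return out


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

Binding = dict[str, Union[Instance, Literal]]


def _value_key(v: Union[Instance, Literal]):
    return ("i", v.id) if isinstance(v, Instance) else ("l", v.value)


def _binding_key(b: Binding):
    return tuple(sorted((k, _value_key(v)) for k, v in b.items()))


def _resolve(arg: Arg, binding: Binding):
    if isinstance(arg, Var):
        return binding.get(arg.name)
    return arg


def match(graph: InstanceGraph, antecedent: Sequence[Atom]) -> list[Binding]:
    """All bindings satisfying every atom conjunctively.

    Class atoms honor subclass closure.  Builtin atoms are evaluated once
    all their variables are bound (atoms are re-ordered internally to make
    that so); results are de-duplicated and deterministically ordered.
    """
    pending = list(antecedent)
    bindings: list[Binding] = [{}]
    while pending:
        # pick the next evaluable atom: any non-builtin, else a builtin
        # whose variables are already bound in every partial binding
        idx = None
        for j, atom in enumerate(pending):
            if atom.kind != "builtin":
                idx = j
                break
        if idx is None:
            for j, atom in enumerate(pending):
                vars_needed = set(atom.variables())
                if all(vars_needed <= set(b) for b in bindings) or not bindings:
                    idx = j
                    break
        if idx is None:
            raise RuleParseError("builtin atoms with unbound variables cannot be evaluated")
        atom = pending.pop(idx)
        bindings = _extend(graph, atom, bindings)
        if not bindings:
            return []
    seen = set()
    out = []
    for b in bindings:
        key = _binding_key(b)
        if key not in seen:
            seen.add(key)
            out.append(b)
    return out


def _extend(graph: InstanceGraph, atom: Atom, bindings: list[Binding]) -> list[Binding]:
    out: list[Binding] = []
    if atom.kind == "class":
        members = graph.class_members(atom.predicate)  # raises if unknown
        arg = atom.args[0]
        for b in bindings:
            cur = _resolve(arg, b)
            if cur is not None:
                if isinstance(cur, Instance) and cur in members:
                    out.append(b)
                continue
            for inst in members:
                nb = dict(b)
                nb[arg.name] = inst
                out.append(nb)
        return out

    if atom.kind == "property":
        pdef = graph.properties.get(atom.predicate)
        if pdef is None:
            raise UnknownSymbolError(f"unknown property {atom.predicate!r}")
        sarg, varg = atom.args
        pairs: list[tuple[Instance, Union[Instance, Literal]]] = []
        for inst in graph.instances.values():
            for v in inst.assertions.get(atom.predicate, ()):
                pairs.append((inst, v))
        for b in bindings:
            s = _resolve(sarg, b)
            v = _resolve(varg, b)
            for subj, val in pairs:
                if s is not None and not _same(s, subj):
                    continue
                if v is not None and not _same(v, val):
                    continue
                nb = dict(b)
                if isinstance(sarg, Var):
                    nb[sarg.name] = subj
                if isinstance(varg, Var):
                    nb[varg.name] = val
                out.append(nb)
        return out

    if atom.kind == "builtin":
        for b in bindings:
            vals = []
            ok = True
            for arg in atom.args:
                r = _resolve(arg, b)
                if r is None or isinstance(r, Instance):
                    ok = False
                    break
                vals.append(r.value)
            if ok and eval_builtin(atom.predicate, vals):
                out.append(b)
        return out

    raise RuleParseError(f"atom kind {atom.kind!r} cannot appear in an antecedent")


def _same(a, b) -> bool:
    if isinstance(a, Instance) and isinstance(b, Instance):
        return a.id == b.id
    if isinstance(a, Literal) and isinstance(b, Literal):
        return a.value == b.value
    return False


# ---------------------------------------------------------------------------
# forward chaining
# ---------------------------------------------------------------------------

@dataclass
class ChainReport:
    """What a chaining run added: (rule id, description) per assertion."""

    assertions: list[tuple[str, str]] = field(default_factory=list)
    rounds: int = 0

    def __len__(self) -> int:
        return len(self.assertions)


def apply_rules(
    graph: InstanceGraph,
    rules: Sequence[Rule],
    max_rounds: int = 100,
) -> ChainReport:
    """Forward-chain ``rules`` over ``graph`` to fixpoint (mutating).

    Monotone: assertions are only added, never retracted.  Idempotent: an
    immediate re-run adds nothing.  Individuals minted by
    ``swrlx:makeOWLThing`` get ids deterministic in (rule id, binding), so
    re-firing a creating rule reuses the individual it already minted.
    """
    for r in rules:
        if isinstance(r, SelectQuery):
            raise RuleParseError(f"{r.id}: queries cannot be applied as rules; use select()")
    report = ChainReport()
    for round_no in range(1, max_rounds + 1):
        report.rounds = round_no
        added = 0
        for rule in rules:
            for binding in match(graph, rule.antecedent):
                added += _fire(graph, rule, binding, report)
        if added == 0:
            return report
    raise ChainingLimitError(
        f"no fixpoint after {max_rounds} rounds; check rules for runaway creation"
    )


def _fire(graph: InstanceGraph, rule: Rule, binding: Binding, report: ChainReport) -> int:
    added = 0
    b = dict(binding)
    for atom in rule.consequent:
        if atom.kind == "make":
            new_var = atom.args[0].name
            key_src = rule.id + "|" + repr(_binding_key(binding))
            digest = hashlib.sha1(key_src.encode()).hexdigest()[:12]
            iid = f"rule:{rule.id}#{digest}"
            if iid in graph.instances:
                b[new_var] = graph.instances[iid]
            else:
                inst = graph.add_instance(iid, source=f"rule:{rule.id}")
                b[new_var] = inst
                added += 1
                report.assertions.append((rule.id, f"new individual {iid}"))
            continue
        if atom.kind == "class":
            target = _resolve(atom.args[0], b)
            if not isinstance(target, Instance):
                raise RuleParseError(f"{rule.id}: class atom argument must bind an instance")
            if atom.predicate not in graph.classes:
                graph.add_class(atom.predicate)
            if graph.assert_class(target, atom.predicate):
                added += 1
                report.assertions.append((rule.id, f"{target.id} a {atom.predicate}"))
            continue
        if atom.kind == "property":
            subj = _resolve(atom.args[0], b)
            val = _resolve(atom.args[1], b)
            if not isinstance(subj, Instance):
                raise RuleParseError(f"{rule.id}: property subject must bind an instance")
            if atom.predicate not in graph.properties:
                kind = "object" if isinstance(val, Instance) else "data"
                graph.add_property(atom.predicate, kind)
            if graph.assert_value(subj, atom.predicate, val):
                added += 1
                report.assertions.append((rule.id, f"{subj.id} {atom.predicate} {val}"))
            continue
        raise RuleParseError(f"{rule.id}: {atom.predicate} cannot appear in a consequent")
    return added


# ---------------------------------------------------------------------------
# select (non-materializing)
# ---------------------------------------------------------------------------

def select(graph: InstanceGraph, query: SelectQuery) -> list[tuple]:
    """Evaluate a query; the graph is bit-identical before and after.

    Rows are projections of matched bindings, de-duplicated, in
    deterministic order.  Instance cells are returned as instance ids,
    literal cells as their text.
    """
    rows = []
    seen = set()
    for b in match(graph, query.antecedent):
        row = tuple(
            b[v].id if isinstance(b[v], Instance) else b[v].value for v in query.projection
        )
        if row not in seen:
            seen.add(row)
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# defined-class classification
# ---------------------------------------------------------------------------

def _satisfies(graph: InstanceGraph, inst: Instance, expr: ClassExpression) -> bool:
    if isinstance(expr, Named):
        return expr.cls in graph.types_of(inst)
    if isinstance(expr, IntersectionOf):
        return all(_satisfies(graph, inst, p) for p in expr.parts)
    if isinstance(expr, SomeValuesFrom):
        for v in inst.assertions.get(expr.prop, ()):
            if isinstance(v, Instance) and _satisfies(graph, v, expr.filler):
                return True
        return False
    raise TypeError(f"not a class expression: {expr!r}")


def classify(
    graph: InstanceGraph,
    defined: Mapping[str, ClassExpression],
    parents: Optional[Mapping[str, str]] = None,
    max_rounds: int = 100,
) -> ChainReport:
    """Infer membership of defined classes, iterated to fixpoint so nested
    defined classes compose.  Membership is asserted into the graph."""
    parents = parents or {}
    for name in defined:
        parent = parents.get(name)
        graph.add_class(name, [parent] if parent else [])
    report = ChainReport()
    for round_no in range(1, max_rounds + 1):
        report.rounds = round_no
        added = 0
        for inst in graph.instances.values():
            for name, expr in defined.items():
                if name in inst.asserted_classes:
                    continue
                if _satisfies(graph, inst, expr):
                    graph.assert_class(inst, name)
                    report.assertions.append(("defined:" + name, f"{inst.id} a {name}"))
                    added += 1
        if added == 0:
            return report
    raise ChainingLimitError(
        f"defined-class classification found no fixpoint after {max_rounds} rounds"
    )
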