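"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: conjunctive
matching by exhaustive enumeration of variable assignments, defined-class
evaluation by direct recursion, reconciliation by a hand-rolled union-find,
and plain scans over XML/graphs for counting.
"""

from __future__ import annotations

import itertools
import random

from rbmed.instance_graph import Instance, InstanceGraph, Literal
from rbmed.rule_engine import Atom, Var


def brute_force_match(graph: InstanceGraph, antecedent) -> set[tuple]:
    """All satisfying bindings by exhaustive assignment enumeration."""
    variables = sorted({v for atom in antecedent for v in atom.variables()})
    literal_pool = {
        v.value
        for inst in graph.instances.values()
        for vals in inst.assertions.values()
        for v in vals
        if isinstance(v, Literal)
    }
    domain = list(graph.instances.values()) + [Literal(x) for x in sorted(literal_pool)]

    def types_of(inst):
        out = set()
        stack = list(inst.asserted_classes)
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(graph.classes[c].parents)
        return out

    def satisfied(atom: Atom, env) -> bool:
        def val(a):
            return env[a.name] if isinstance(a, Var) else a

        if atom.kind == "class":
            x = val(atom.args[0])
            return isinstance(x, Instance) and atom.predicate in types_of(x)
        if atom.kind == "property":
            s, v = val(atom.args[0]), val(atom.args[1])
            if not isinstance(s, Instance):
                return False
            for got in s.assertions.get(atom.predicate, ()):
                if isinstance(got, Instance) and isinstance(v, Instance) and got.id == v.id:
                    return True
                if isinstance(got, Literal) and isinstance(v, Literal) and got.value == v.value:
                    return True
            return False
        if atom.kind == "builtin":
            args = [val(a) for a in atom.args]
            if any(isinstance(a, Instance) for a in args):
                return False
            texts = [a.value for a in args]
            name = atom.predicate.split(":")[1]
            if name in ("containsIgnoreCase", "containslgnoreCase"):
                return texts[1].lower() in texts[0].lower()
            if name == "contains":
                return texts[1] in texts[0]
            if name == "equal":
                return texts[0] == texts[1]
            if name == "stringEqualIgnoreCase":
                return texts[0].lower() == texts[1].lower()
            raise AssertionError(name)
        raise AssertionError(atom.kind)

    out = set()
    for combo in itertools.product(domain, repeat=len(variables)):
        env = dict(zip(variables, combo))
        if all(satisfied(a, env) for a in antecedent):
            out.add(
                tuple(
                    (v, env[v].id if isinstance(env[v], Instance) else ("lit", env[v].value))
                    for v in variables
                )
            )
    return out


def binding_set(bindings) -> set[tuple]:
    """Normalize implementation bindings to the oracle's shape."""
    out = set()
    for b in bindings:
        out.add(
            tuple(
                (k, v.id if isinstance(v, Instance) else ("lit", v.value))
                for k, v in sorted(b.items())
            )
        )
    return out


def recursive_satisfies(graph: InstanceGraph, inst: Instance, expr) -> bool:
    """Direct recursive evaluation of a class expression."""
    from rbmed.rule_engine import IntersectionOf, Named, SomeValuesFrom

    if isinstance(expr, Named):
        closure = set()
        stack = list(inst.asserted_classes)
        while stack:
            c = stack.pop()
            if c not in closure:
                closure.add(c)
                stack.extend(graph.classes[c].parents)
        return expr.cls in closure
    if isinstance(expr, IntersectionOf):
        return all(recursive_satisfies(graph, inst, p) for p in expr.parts)
    if isinstance(expr, SomeValuesFrom):
        return any(
            isinstance(v, Instance) and recursive_satisfies(graph, v, expr.filler)
            for v in inst.assertions.get(expr.prop, ())
        )
    raise AssertionError(expr)


class UnionFind:
    """Classic DSU with path compression, the reconciliation oracle."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def join(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def sets(self) -> set[frozenset]:
        groups: dict = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return {frozenset(s) for s in groups.values()}


def random_graph(seed: int, n_instances: int = 20) -> InstanceGraph:
    """A small random graph with hierarchy, object and data assertions."""
    rng = random.Random(seed)
    g = InstanceGraph()
    class_names = ["A", "B", "C", "D", "E"]
    for i, name in enumerate(class_names):
        parents = [rng.choice(class_names[:i])] if i and rng.random() < 0.6 else []
        g.add_class(name, parents)
    g.add_property("r", "object")
    g.add_property("p", "data")
    words = ["rad9", "RAD53", "checkpoint", "kinase", "telomere", "x"]
    insts = []
    for i in range(n_instances):
        inst = g.add_instance(f"t#{i}", [rng.choice(class_names)], source="test")
        insts.append(inst)
    for inst in insts:
        for _ in range(rng.randint(0, 2)):
            g.assert_value(inst, "r", rng.choice(insts))
        for _ in range(rng.randint(0, 2)):
            g.assert_value(inst, "p", Literal(rng.choice(words)))
    return g
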