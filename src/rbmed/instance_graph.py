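"""In-memory ontology-instance store shared by every stage of the mediation
pipeline.

Both syntactic ontologies (mirroring a data format's element structure) and
the core domain ontology are held in the same structure: a set of named
classes with single- or multiple-inheritance parents, object/data property
definitions, and typed instances carrying property assertions plus a
provenance label naming the data source each instance came from.

Identifiers are prefixed names such as ``tuo:Protein`` or ``up:Entry``; the
prefix keeps symbols from different ontologies disjoint when graphs are
unioned.  Instance ids are namespaced as ``<source>#<local>`` so instances
from different sources can never collide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import rdflib
from rdflib import RDF, RDFS, Literal as RdfLiteral, Namespace, URIRef

__all__ = [
    "SchemaConflictError",
    "UnknownSymbolError",
    "IntegrityError",
    "Literal",
    "OntClass",
    "PropertyDef",
    "Instance",
    "InstanceGraph",
    "union",
    "instances_of",
]

#: Base IRI used when rendering prefixed names / instance ids as RDF.
BASE_IRI = "http://rbmed.example/ns/"

#: Recognised literal kind tags.
LITERAL_KINDS = ("text", "integer", "decimal", "boolean")


class SchemaConflictError(ValueError):
    """Two graphs define the same class/property name differently."""


class UnknownSymbolError(KeyError):
    """A class, property, or instance id does not resolve."""


class IntegrityError(ValueError):
    """Referential integrity of an InstanceGraph is violated."""


@dataclass(frozen=True)
class Literal:
    """A data value: text payload plus an optional kind tag."""

    value: str
    kind: str = "text"

    def __post_init__(self) -> None:
        if self.kind not in LITERAL_KINDS:
            raise ValueError(f"unknown literal kind {self.kind!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.value


@dataclass
class OntClass:
    """A named class; ``parents`` holds direct superclass names."""

    name: str
    parents: tuple[str, ...] = ()

    def same_definition(self, other: "OntClass") -> bool:
        return self.name == other.name and set(self.parents) == set(other.parents)


@dataclass
class PropertyDef:
    """An object or data property definition.

    ``domain``/``range`` are advisory (None = unconstrained); for data
    properties ``range`` is a literal kind tag.
    """

    name: str
    kind: str  # "object" | "data"
    domain: Optional[str] = None
    range: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("object", "data"):
            raise ValueError(f"property kind must be object|data, got {self.kind!r}")

    def same_definition(self, other: "PropertyDef") -> bool:
        return (
            self.name == other.name
            and self.kind == other.kind
            and self.domain == other.domain
            and self.range == other.range
        )


Value = Union["Instance", Literal]


@dataclass(eq=False)
class Instance:
    """A typed individual with property assertions and source provenance.

    ``assertions`` maps property name -> list of values in insertion order;
    multi-valued assertions are always allowed.  ``provenance`` is a list of
    source labels; it grows past length one only when equivalent instances
    from several sources are merged.
    """

    id: str
    asserted_classes: set[str] = field(default_factory=set)
    provenance: list[str] = field(default_factory=list)
    assertions: dict[str, list[Value]] = field(default_factory=dict)

    @property
    def source(self) -> Optional[str]:
        return self.provenance[0] if self.provenance else None

    def values(self, prop: str) -> list[Value]:
        return list(self.assertions.get(prop, ()))

    def literals(self, prop: str) -> list[str]:
        return [v.value for v in self.assertions.get(prop, ()) if isinstance(v, Literal)]

    def objects(self, prop: str) -> list["Instance"]:
        return [v for v in self.assertions.get(prop, ()) if isinstance(v, Instance)]


class InstanceGraph:
    """Classes + properties (the schema) and instances (the data).

    Iteration order over classes, properties, instances, and each
    instance's assertions is insertion order, making every downstream
    computation deterministic.
    """

    def __init__(self) -> None:
        self.classes: dict[str, OntClass] = {}
        self.properties: dict[str, PropertyDef] = {}
        self.instances: dict[str, Instance] = {}

    # -- schema ----------------------------------------------------------

    def add_class(self, name: str, parents: Iterable[str] = ()) -> OntClass:
        parents = tuple(parents)
        if name in self.classes:
            existing = self.classes[name]
            merged = OntClass(name, tuple(dict.fromkeys(existing.parents + parents)))
            if not existing.same_definition(merged):
                for p in merged.parents:
                    if p not in self.classes:
                        raise UnknownSymbolError(f"unknown parent class {p!r}")
                self.classes[name] = merged
                self._check_acyclic(name)
            return self.classes[name]
        for p in parents:
            if p not in self.classes:
                raise UnknownSymbolError(f"unknown parent class {p!r}")
        cls = OntClass(name, parents)
        self.classes[name] = cls
        self._check_acyclic(name)
        return cls

    def add_property(
        self,
        name: str,
        kind: str,
        domain: Optional[str] = None,
        range: Optional[str] = None,
    ) -> PropertyDef:
        prop = PropertyDef(name, kind, domain, range)
        if name in self.properties:
            if not self.properties[name].same_definition(prop):
                raise SchemaConflictError(f"conflicting redefinition of property {name!r}")
            return self.properties[name]
        self.properties[name] = prop
        return prop

    def _check_acyclic(self, start: str) -> None:
        seen: set[str] = set()
        stack = [start]
        while stack:
            cur = stack.pop()
            if cur == start and seen:
                raise IntegrityError(f"cycle in class hierarchy at {start!r}")
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(self.classes[cur].parents)

    def ancestors(self, cls: str) -> set[str]:
        """All superclasses of ``cls``, including itself."""
        if cls not in self.classes:
            raise UnknownSymbolError(f"unknown class {cls!r}")
        out: set[str] = set()
        stack = [cls]
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            stack.extend(self.classes[cur].parents)
        return out

    def descendants(self, cls: str) -> set[str]:
        """All subclasses of ``cls``, including itself."""
        if cls not in self.classes:
            raise UnknownSymbolError(f"unknown class {cls!r}")
        out = {cls}
        changed = True
        while changed:
            changed = False
            for c in self.classes.values():
                if c.name not in out and any(p in out for p in c.parents):
                    out.add(c.name)
                    changed = True
        return out

    # -- instances -------------------------------------------------------

    def add_instance(
        self,
        id: str,
        classes: Iterable[str] = (),
        source: Optional[str] = None,
    ) -> Instance:
        if id in self.instances:
            raise IntegrityError(f"duplicate instance id {id!r}")
        inst = Instance(id)
        self.instances[id] = inst
        for c in classes:
            self.assert_class(inst, c)
        if source is not None:
            inst.provenance.append(source)
        return inst

    def assert_class(self, inst: Instance, cls: str) -> bool:
        """Assert membership; returns True if this is a new assertion."""
        if cls not in self.classes:
            raise UnknownSymbolError(f"unknown class {cls!r}")
        if cls in inst.asserted_classes:
            return False
        inst.asserted_classes.add(cls)
        return True

    def assert_value(self, inst: Instance, prop: str, value: Value) -> bool:
        """Assert a (property, value) pair; returns True if new."""
        pdef = self.properties.get(prop)
        if pdef is None:
            raise UnknownSymbolError(f"unknown property {prop!r}")
        if pdef.kind == "object":
            if not isinstance(value, Instance):
                raise IntegrityError(f"object property {prop!r} needs an instance value")
            if value.id not in self.instances or self.instances[value.id] is not value:
                raise IntegrityError(f"object value {value.id!r} not in graph")
        else:
            if not isinstance(value, Literal):
                raise IntegrityError(f"data property {prop!r} needs a literal value")
        bucket = inst.assertions.setdefault(prop, [])
        if value in bucket:
            return False
        bucket.append(value)
        return True

    def instance(self, id: str) -> Instance:
        try:
            return self.instances[id]
        except KeyError:
            raise UnknownSymbolError(f"unknown instance {id!r}") from None

    # -- queries ---------------------------------------------------------

    def types_of(self, inst: Instance) -> set[str]:
        """Asserted classes closed under the superclass relation."""
        out: set[str] = set()
        for c in inst.asserted_classes:
            out |= self.ancestors(c)
        return out

    def class_members(self, cls: str) -> list[Instance]:
        subs = self.descendants(cls)
        return [i for i in self.instances.values() if i.asserted_classes & subs]

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Walk the graph and raise IntegrityError on any broken reference."""
        for cls in self.classes.values():
            for p in cls.parents:
                if p not in self.classes:
                    raise IntegrityError(f"class {cls.name!r} has unknown parent {p!r}")
        for inst in self.instances.values():
            for c in inst.asserted_classes:
                if c not in self.classes:
                    raise IntegrityError(f"instance {inst.id!r} in unknown class {c!r}")
            for prop, values in inst.assertions.items():
                pdef = self.properties.get(prop)
                if pdef is None:
                    raise IntegrityError(f"instance {inst.id!r} uses unknown property {prop!r}")
                for v in values:
                    if pdef.kind == "object":
                        if not isinstance(v, Instance) or self.instances.get(v.id) is not v:
                            raise IntegrityError(
                                f"{inst.id!r}.{prop} references a value outside the graph"
                            )
                    elif not isinstance(v, Literal):
                        raise IntegrityError(f"{inst.id!r}.{prop} holds a non-literal value")
        for name in self.classes:
            self._check_acyclic(name)

    # -- copying ---------------------------------------------------------

    def copy(self) -> "InstanceGraph":
        out = InstanceGraph()
        _copy_into(self, out)
        return out

    # -- serialization ---------------------------------------------------

    def to_rdflib(self) -> rdflib.Graph:
        """Render as an rdflib graph (class membership as rdf:type)."""
        g = rdflib.Graph()
        g.bind("rbm", Namespace(BASE_IRI))
        for cls in self.classes.values():
            c = _iri(cls.name)
            g.add((c, RDF.type, RDFS.Class))
            for p in cls.parents:
                g.add((c, RDFS.subClassOf, _iri(p)))
        for prop in self.properties.values():
            p = _iri(prop.name)
            g.add((p, RDF.type, RDF.Property))
            if prop.domain:
                g.add((p, RDFS.domain, _iri(prop.domain)))
            if prop.kind == "object" and prop.range:
                g.add((p, RDFS.range, _iri(prop.range)))
        for inst in self.instances.values():
            s = _iri(inst.id)
            for c in sorted(inst.asserted_classes):
                g.add((s, RDF.type, _iri(c)))
            for propname, values in inst.assertions.items():
                p = _iri(propname)
                for v in values:
                    if isinstance(v, Instance):
                        g.add((s, p, _iri(v.id)))
                    else:
                        g.add((s, p, RdfLiteral(v.value)))
        return g

    def serialize(self, fmt: str = "turtle") -> str:
        """Serialize to ``turtle``, ``xml`` (RDF/XML) or ``nt``.

        N-Triples output is sorted line-wise, so it is byte-deterministic
        and usable as a graph fingerprint.
        """
        g = self.to_rdflib()
        if fmt == "nt":
            lines = sorted(
                line for line in g.serialize(format="nt").splitlines() if line.strip()
            )
            return "\n".join(lines) + "\n"
        return g.serialize(format=fmt)

    def fingerprint(self) -> str:
        import hashlib

        return hashlib.sha256(self.serialize("nt").encode()).hexdigest()


def _iri(name: str) -> URIRef:
    return URIRef(BASE_IRI + name.replace(" ", "_"))


def _copy_into(src: InstanceGraph, dst: InstanceGraph) -> None:
    for cls in src.classes.values():
        dst.classes.setdefault(cls.name, OntClass(cls.name, cls.parents))
    for prop in src.properties.values():
        if prop.name in dst.properties:
            if not dst.properties[prop.name].same_definition(prop):
                raise SchemaConflictError(f"conflicting definitions of property {prop.name!r}")
        else:
            dst.properties[prop.name] = PropertyDef(prop.name, prop.kind, prop.domain, prop.range)
    for inst in src.instances.values():
        if inst.id in dst.instances:
            raise IntegrityError(f"instance id collision on union: {inst.id!r}")
        dst.instances[inst.id] = Instance(inst.id, set(inst.asserted_classes), list(inst.provenance))
    # second pass: rewire object values to the copies
    for inst in src.instances.values():
        mirror = dst.instances[inst.id]
        for prop, values in inst.assertions.items():
            mirror.assertions[prop] = [
                dst.instances[v.id] if isinstance(v, Instance) else v for v in values
            ]


def union(graphs: Sequence[InstanceGraph]) -> InstanceGraph:
    """Combine graphs into one.

    Class definitions that collide must agree (parent sets are unioned for
    classes, exact match required for properties); instance ids must be
    disjoint — guaranteed in practice by the ``source#local`` id convention.
    """
    out = InstanceGraph()
    for g in graphs:
        for cls in g.classes.values():
            if cls.name in out.classes:
                existing = out.classes[cls.name]
                out.classes[cls.name] = OntClass(
                    cls.name, tuple(dict.fromkeys(existing.parents + cls.parents))
                )
            else:
                out.classes[cls.name] = OntClass(cls.name, cls.parents)
    for g in graphs:
        for prop in g.properties.values():
            if prop.name in out.properties:
                if not out.properties[prop.name].same_definition(prop):
                    raise SchemaConflictError(
                        f"conflicting definitions of property {prop.name!r}"
                    )
            else:
                out.properties[prop.name] = PropertyDef(
                    prop.name, prop.kind, prop.domain, prop.range
                )
    for g in graphs:
        for inst in g.instances.values():
            if inst.id in out.instances:
                raise IntegrityError(f"instance id collision on union: {inst.id!r}")
            out.instances[inst.id] = Instance(
                inst.id, set(inst.asserted_classes), list(inst.provenance)
            )
    for g in graphs:
        for inst in g.instances.values():
            mirror = out.instances[inst.id]
            for prop, values in inst.assertions.items():
                mirror.assertions[prop] = [
                    out.instances[v.id] if isinstance(v, Instance) else v for v in values
                ]
    out.validate()
    return out


def instances_of(graph: InstanceGraph, cls: str) -> set[Instance]:
    """Instances asserted in ``cls`` or any of its descendant classes."""
    if cls not in graph.classes:
        raise UnknownSymbolError(f"unknown class {cls!r}")
    return {i for i in graph.class_members(cls)}
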