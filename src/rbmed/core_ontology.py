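"""The core ("telomere") domain ontology: schema loading, equivalence
reconciliation, and organism restriction.

The core ontology is the semantically homogeneous integration target.  Its
vocabulary (``tuo:`` prefix) never references any source format: proteins
(with named subclasses per gene of interest), processes/interactions,
participant roles linking the two (``plays``/``playedBy``/
``hasParticipant``), organisms, compartments, and cross-references.

Reconciliation automates the manual sameAs step: instances sharing a key
(by default a UniProtKB accession; fallback, exact case-insensitive primary
name within one taxon) are declared equivalent and merged into a canonical
instance that unions their classes, assertions and provenance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx

from .instance_graph import (
    Instance,
    InstanceGraph,
    Literal,
    OntClass,
    PropertyDef,
)

__all__ = [
    "CoreSchema",
    "EquivalencePartition",
    "load_core_schema",
    "default_core_schema",
    "accession_key",
    "name_taxon_key",
    "KEY_EXTRACTORS",
    "assert_equivalences",
    "merge_equivalents",
    "restrict_organism",
]

log = logging.getLogger(__name__)

# core vocabulary defaults (overridable in every operation)
PROTEIN = "tuo:Protein"
PROCESS = "tuo:Process"
ROLE = "tuo:ParticipantRole"
PLAYED_BY = "tuo:playedBy"
PLAYS = "tuo:plays"
HAS_PARTICIPANT = "tuo:hasParticipant"
TAXON_ID = "tuo:taxonId"
ACCESSION = "tuo:accession"
PRIMARY_NAME = "tuo:primaryName"


@dataclass
class CoreSchema:
    """Parsed declarative core schema: a schema-only graph plus the
    inverse-property pairs it declares."""

    graph: InstanceGraph
    inverses: dict[str, str] = field(default_factory=dict)

    def install_into(self, graph: InstanceGraph) -> None:
        """Add this schema's classes/properties into ``graph``."""
        for cls in self.graph.classes.values():
            graph.add_class(cls.name)
        for cls in self.graph.classes.values():
            if cls.parents:
                graph.add_class(cls.name, cls.parents)
        for prop in self.graph.properties.values():
            graph.add_property(prop.name, prop.kind, prop.domain, prop.range)


_CLASS_RE = re.compile(r"^class\s+([\w.:-]+)(?:\s*<\s*([\w.:-]+(?:\s*,\s*[\w.:-]+)*))?$")
_PROP_RE = re.compile(
    r"^(objprop|dataprop)\s+([\w.:-]+)"
    r"(?:\s+domain\s+([\w.:-]+))?(?:\s+range\s+([\w.:-]+))?"
    r"(?:\s+inverse\s+([\w.:-]+))?$"
)


def load_core_schema(text: str) -> CoreSchema:
    """Parse the declarative schema format::

        class tuo:Protein < tuo:Entity
        objprop tuo:plays domain tuo:Protein range tuo:ParticipantRole inverse tuo:playedBy
        dataprop tuo:synonym
    """
    graph = InstanceGraph()
    inverses: dict[str, str] = {}
    deferred_parents: list[tuple[str, tuple[str, ...]]] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _CLASS_RE.match(line)
        if m:
            name, parents = m.group(1), m.group(2)
            graph.add_class(name)
            if parents:
                deferred_parents.append(
                    (name, tuple(p.strip() for p in parents.split(",")))
                )
            continue
        m = _PROP_RE.match(line)
        if m:
            kw, name, domain, rng, inverse = m.groups()
            kind = "object" if kw == "objprop" else "data"
            graph.add_property(name, kind, domain, rng)
            if inverse:
                inverses[name] = inverse
                inverses.setdefault(inverse, name)
            continue
        raise ValueError(f"core schema line {lineno}: cannot parse {raw!r}")
    for name, parents in deferred_parents:
        graph.add_class(name, parents)
    graph.validate()
    return CoreSchema(graph, inverses)


def default_core_schema() -> CoreSchema:
    """The schema shipped with the package (``rules/core_schema.txt``)."""
    from importlib.resources import files

    text = files("rbmed").joinpath("rules/core_schema.txt").read_text()
    return load_core_schema(text)


# ---------------------------------------------------------------------------
# reconciliation
# ---------------------------------------------------------------------------

KeyExtractor = Callable[[Instance], list[tuple]]


def accession_key(inst: Instance) -> list[tuple]:
    """Shared database accession (default reconciliation key)."""
    return [("accession", v) for v in inst.literals(ACCESSION)]


def name_taxon_key(inst: Instance) -> list[tuple]:
    """Exact case-insensitive primary name, scoped to one taxon."""
    taxa = inst.literals(TAXON_ID)
    if len(taxa) != 1:
        return []
    return [("name-taxon", n.lower(), taxa[0]) for n in inst.literals(PRIMARY_NAME)]


KEY_EXTRACTORS: dict[str, KeyExtractor] = {
    "accession": accession_key,
    "name+taxon": name_taxon_key,
}


@dataclass
class EquivalencePartition:
    """Disjoint sets of instance ids; each set denotes one real entity.

    Covers the whole instance-id universe of the graph it was computed
    from: ids without any shared key form singleton sets.
    """

    sets: list[frozenset[str]]

    def __post_init__(self) -> None:
        self._index: dict[str, int] = {}
        for i, s in enumerate(self.sets):
            for iid in s:
                if iid in self._index:
                    raise ValueError(f"id {iid!r} appears in two sets")
                self._index[iid] = i

    def set_of(self, iid: str) -> frozenset[str]:
        return self.sets[self._index[iid]]

    def canonical(self, iid: str) -> str:
        return min(self.set_of(iid))

    def non_trivial(self) -> list[frozenset[str]]:
        return [s for s in self.sets if len(s) > 1]


def assert_equivalences(
    graph: InstanceGraph,
    keys: Sequence[KeyExtractor | str] = ("accession", "name+taxon"),
    taxon_prop: str = TAXON_ID,
) -> EquivalencePartition:
    """Compute the equivalence partition from shared keys.

    The partition is the reflexive-symmetric-transitive closure of the
    pairwise shared-key relation.  Instances sharing a key but carrying
    contradictory taxon ids are NOT merged (a conflict warning is logged);
    deterministic regardless of instance insertion order.
    """
    extractors: list[KeyExtractor] = [
        KEY_EXTRACTORS[k] if isinstance(k, str) else k for k in keys
    ]
    g = nx.Graph()
    g.add_nodes_from(graph.instances)
    by_key: dict[tuple, list[str]] = {}
    for inst in graph.instances.values():
        for ex in extractors:
            for key in ex(inst):
                by_key.setdefault(key, []).append(inst.id)
    for key, ids in sorted(by_key.items(), key=lambda kv: repr(kv[0])):
        ids = sorted(set(ids))
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = graph.instances[ids[i]], graph.instances[ids[j]]
                ta, tb = set(a.literals(taxon_prop)), set(b.literals(taxon_prop))
                if ta and tb and ta.isdisjoint(tb):
                    log.warning(
                        "key %r shared by %s and %s but taxa differ (%s vs %s); not merged",
                        key, a.id, b.id, sorted(ta), sorted(tb),
                    )
                    continue
                g.add_edge(a.id, b.id)
    sets = sorted(
        (frozenset(c) for c in nx.connected_components(g)), key=lambda s: min(s)
    )
    return EquivalencePartition(sets)


def merge_equivalents(
    graph: InstanceGraph, partition: EquivalencePartition
) -> InstanceGraph:
    """Collapse each equivalence set onto one canonical instance.

    The canonical instance (lowest id of the set) carries the union of the
    set's classes, assertions (deduplicated) and provenance labels; object
    references anywhere in the graph are rewired to canonical ids.
    """
    out = InstanceGraph()
    for cls in graph.classes.values():
        out.classes[cls.name] = OntClass(cls.name, cls.parents)
    for prop in graph.properties.values():
        out.properties[prop.name] = PropertyDef(prop.name, prop.kind, prop.domain, prop.range)

    canon_of = {iid: partition.canonical(iid) for iid in graph.instances}
    # create canonicals in the order their first member appears (determinism)
    for inst in graph.instances.values():
        cid = canon_of[inst.id]
        if cid not in out.instances:
            out.instances[cid] = Instance(cid)
    for inst in graph.instances.values():  # members in insertion order
        target = out.instances[canon_of[inst.id]]
        target.asserted_classes |= inst.asserted_classes
        for label in inst.provenance:
            if label not in target.provenance:
                target.provenance.append(label)
    for inst in graph.instances.values():
        target = out.instances[canon_of[inst.id]]
        for prop, values in inst.assertions.items():
            bucket = target.assertions.setdefault(prop, [])
            for v in values:
                nv = out.instances[canon_of[v.id]] if isinstance(v, Instance) else v
                if isinstance(nv, Instance):
                    if all(not (isinstance(x, Instance) and x.id == nv.id) for x in bucket):
                        bucket.append(nv)
                elif nv not in bucket:
                    bucket.append(nv)
    out.validate()
    return out


def restrict_organism(
    graph: InstanceGraph,
    taxon_id: str,
    protein_class: str = PROTEIN,
    taxon_prop: str = TAXON_ID,
    role_class: str = ROLE,
    played_by: str = PLAYED_BY,
    process_class: str = PROCESS,
    has_participant: str = HAS_PARTICIPANT,
) -> list[str]:
    """Remove proteins of other organisms, then roles and interactions left
    dangling; mutates ``graph`` and returns the removed instance ids.

    A protein with no taxon assertion is retained with a warning; a protein
    whose taxon set contains ``taxon_id`` is never removed.
    """
    taxon_id = str(taxon_id)
    removed: set[str] = set()
    if protein_class in graph.classes:
        for inst in graph.class_members(protein_class):
            taxa = inst.literals(taxon_prop)
            if not taxa:
                log.warning("protein %s has no taxon id; retained", inst.id)
                continue
            if taxon_id not in taxa:
                removed.add(inst.id)
    # roles whose player was removed
    if role_class in graph.classes:
        for inst in graph.class_members(role_class):
            players = [o.id for o in inst.objects(played_by)]
            if players and all(p in removed for p in players):
                removed.add(inst.id)
    # processes referencing a removed role
    if process_class in graph.classes:
        for inst in graph.class_members(process_class):
            if any(o.id in removed for o in inst.objects(has_participant)):
                removed.add(inst.id)
    for iid in removed:
        del graph.instances[iid]
    # scrub dangling object references
    for inst in graph.instances.values():
        for prop in list(inst.assertions):
            kept = [
                v
                for v in inst.assertions[prop]
                if not (isinstance(v, Instance) and v.id in removed)
            ]
            if kept:
                inst.assertions[prop] = kept
            else:
                del inst.assertions[prop]
    graph.validate()
    return sorted(removed)
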