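"""Format-aware readers producing populated syntactic ontologies.

Three input formats are supported here: UniProtKB-style entry XML, PSI-MI
1.0 interaction XML (the dialect BioGRID exports), and BioPAX level-2-style
RDF (Pathway Commons).  The two XML formats are thin specializations of
the generic XML converter with a *pinned* schema — class names must be
stable because they anchor the mapping-rule atoms — while BioPAX, already
being RDF/OWL, is loaded natively triple-by-triple.

SBML is deliberately not read here: the model is both an input and the
output target, and lives in :mod:`rbmed.sbml_annotator`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import rdflib
from lxml import etree

from .instance_graph import InstanceGraph, IntegrityError, Literal
from .xml_to_ontology import XmlMappingConvention, derive_schema, extend_schema, parse_xml, populate

__all__ = [
    "SourceDescriptor",
    "read_uniprot",
    "read_psimif",
    "read_biopax",
    "read_source",
    "UNIPROT_CONVENTION",
    "PSIMIF_CONVENTION",
]

log = logging.getLogger(__name__)

UNIPROT_CONVENTION = XmlMappingConvention(prefix="up")
PSIMIF_CONVENTION = XmlMappingConvention(prefix="psi")

BIOPAX_NS = "http://www.biopax.org/release/biopax-level2.owl#"
_BIOPAX_KNOWN = {
    "protein",
    "physicalEntity",
    "physicalInteraction",
    "interaction",
    "physicalEntityParticipant",
    "sequenceParticipant",
    "unificationXref",
    "relationshipXref",
    "xref",
    "bioSource",
    "openControlledVocabulary",
}

# Template documents pin the schema of each XML dialect: every element,
# attribute, and nesting the reader supports appears here once.
_UNIPROT_TEMPLATE = """\
<uniprot>
 <entry>
  <accession>P00000</accession>
  <name>TEMPLATE</name>
  <protein>
   <recommendedName><fullName>t</fullName></recommendedName>
   <alternativeName><fullName>t</fullName></alternativeName>
  </protein>
  <gene><name type="primary">t</name></gene>
  <organism>
   <name type="scientific">t</name>
   <dbReference type="NCBI Taxonomy" id="0"/>
  </organism>
  <comment type="subcellular location">
   <subcellularLocation><location>t</location></subcellularLocation>
  </comment>
  <comment type="function"><text>t</text></comment>
  <dbReference type="DB" id="0"/>
 </entry>
</uniprot>
"""

_PSIMIF_TEMPLATE = """\
<entrySet>
 <entry>
  <interactorList>
   <proteinInteractor id="i0">
    <names><shortLabel>t</shortLabel><fullName>t</fullName></names>
    <xref>
     <primaryRef db="d" id="0"/>
     <secondaryRef db="d" id="0"/>
    </xref>
    <organism ncbiTaxId="0"/>
   </proteinInteractor>
  </interactorList>
  <interactionList>
   <interaction>
    <names><shortLabel>t</shortLabel></names>
    <participantList>
     <proteinParticipant><proteinInteractorRef ref="i0"/></proteinParticipant>
    </participantList>
   </interaction>
  </interactionList>
 </entry>
</entrySet>
"""


@dataclass(frozen=True)
class SourceDescriptor:
    """A named data source: which reader runs, on which file(s)."""

    name: str
    format: str  # uniprot-xml | psi-mif | biopax-rdf | sbml
    paths: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.format not in ("uniprot-xml", "psi-mif", "biopax-rdf", "sbml"):
            raise ValueError(f"unknown source format {self.format!r}")


def uniprot_schema() -> InstanceGraph:
    g = derive_schema(_UNIPROT_TEMPLATE, UNIPROT_CONVENTION)
    g.add_property("up:hasPrimaryAccession", "data")
    g.add_property("up:hasSecondaryAccession", "data")
    return g


def psimif_schema() -> InstanceGraph:
    g = derive_schema(_PSIMIF_TEMPLATE, PSIMIF_CONVENTION)
    g.add_property("psi:refersTo", "object")
    return g


def read_uniprot(
    files: Union[str, Path, Sequence[Union[str, Path]]],
    source_label: str = "UniProtKB",
) -> InstanceGraph:
    """Read UniProtKB-style XML into a syntactic graph (provenance
    ``UniProtKB``).

    Entries without a primary accession are skipped with a logged warning.
    Each ``up:Entry`` instance additionally exposes
    ``up:hasPrimaryAccession`` (first accession element, the UniProt
    convention) and ``up:hasSecondaryAccession`` for the rest — document
    order is positional information the generic conversion cannot name.
    """
    graph = uniprot_schema()
    for path in _as_list(files):
        root = parse_xml(str(path))
        for entry in list(root.iter("entry")):
            if not any((a.text or "").strip() for a in entry.findall("accession")):
                log.warning("uniprot entry without primary accession skipped (%s)", path)
                entry.getparent().remove(entry)
        populate(root, graph, UNIPROT_CONVENTION, source_label, mode="strict")
    # post-pass: positional accession semantics
    for inst in graph.class_members("up:Entry"):
        accs = [
            v
            for acc in inst.objects("up:hasAccession")
            for v in acc.literals("up:hasValue")
        ]
        if accs and not inst.literals("up:hasPrimaryAccession"):
            graph.assert_value(inst, "up:hasPrimaryAccession", Literal(accs[0]))
            for sec in accs[1:]:
                graph.assert_value(inst, "up:hasSecondaryAccession", Literal(sec))
    return graph


def read_psimif(
    files: Union[str, Path, Sequence[Union[str, Path]]],
    source_label: str = "BioGRID",
) -> InstanceGraph:
    """Read PSI-MI 1.0-style XML into a syntactic graph (provenance
    ``BioGRID``).

    ``proteinInteractorRef`` references are resolved into direct
    ``psi:refersTo`` object links from each participant to its declared
    interactor; an undeclared id raises :class:`IntegrityError`.
    """
    graph = psimif_schema()
    for path in _as_list(files):
        populate(str(path), graph, PSIMIF_CONVENTION, source_label, mode="strict")
    interactors = {
        lit: inst
        for inst in graph.class_members("psi:ProteinInteractor")
        for lit in inst.literals("psi:hasId")
    }
    for part in graph.class_members("psi:ProteinParticipant"):
        for ref in part.objects("psi:hasProteinInteractorRef"):
            for target_id in ref.literals("psi:hasRef"):
                if target_id not in interactors:
                    raise IntegrityError(
                        f"interaction participant references undeclared interactor {target_id!r}"
                    )
                graph.assert_value(part, "psi:refersTo", interactors[target_id])
    return graph


def read_biopax(
    files: Union[str, Path, Sequence[Union[str, Path]]],
    source_label: str = "PathwayCommons",
) -> InstanceGraph:
    """Read BioPAX level-2-style RDF/XML natively (provenance
    ``PathwayCommons``).

    Typed resources become instances of ``bp:<ClassName>``; BioPAX-namespace
    predicates become ``bp:`` properties (object or data according to the
    value).  A resource typed with an unrecognized BioPAX class is kept with
    a warning.  The entity/occurrence dichotomy of BioPAX (``protein`` vs
    ``physicalEntityParticipant``) survives untouched.
    """
    graph = InstanceGraph()
    graph.add_class("bp:Thing")
    # pinned vocabulary: rule atoms must resolve even when a given corpus
    # does not exercise every property
    for cls in sorted(_BIOPAX_KNOWN):
        graph.add_class(f"bp:{cls}")
    for prop in ("XREF", "ORGANISM", "TAXON-XREF", "PHYSICAL-ENTITY", "PARTICIPANTS"):
        graph.add_property(f"bp:{prop}", "object")
    for prop in ("NAME", "SHORT-NAME", "SYNONYMS", "COMMENT", "DB", "ID"):
        graph.add_property(f"bp:{prop}", "data")
    for path in _as_list(files):
        rg = rdflib.Graph()
        rg.parse(str(path))  # rdflib raises on RDF parse failure
        subjects: dict[str, rdflib.term.Node] = {}
        typed: dict[str, list[str]] = {}
        for s, o in sorted(rg.subject_objects(rdflib.RDF.type)):
            if not str(o).startswith(BIOPAX_NS):
                continue
            local = str(o)[len(BIOPAX_NS):]
            if local not in _BIOPAX_KNOWN:
                log.warning("unknown BioPAX class %r; instance kept as bp:Thing", local)
                cls = "bp:Thing"
            else:
                cls = f"bp:{local}"
                if cls not in graph.classes:
                    graph.add_class(cls)
            sid = _biopax_id(s, source_label)
            subjects[sid] = s
            typed.setdefault(sid, []).append(cls)
        for sid in sorted(typed):
            if sid not in graph.instances:
                graph.add_instance(sid, typed[sid], source=source_label)
            else:
                for cls in typed[sid]:
                    graph.assert_class(graph.instances[sid], cls)
        for sid in sorted(typed):
            inst = graph.instances[sid]
            for p, o in sorted(rg.predicate_objects(subjects[sid])):
                if p == rdflib.RDF.type or not str(p).startswith(BIOPAX_NS):
                    continue
                prop = f"bp:{str(p)[len(BIOPAX_NS):]}"
                if isinstance(o, rdflib.Literal):
                    if prop not in graph.properties:
                        graph.add_property(prop, "data")
                    graph.assert_value(inst, prop, Literal(str(o)))
                else:
                    oid = _biopax_id(o, source_label)
                    if oid not in graph.instances:
                        # object never typed: keep it as a generic thing
                        graph.add_instance(oid, ["bp:Thing"], source=source_label)
                    if prop not in graph.properties:
                        graph.add_property(prop, "object")
                    graph.assert_value(inst, prop, graph.instances[oid])
    return graph


def read_source(desc: SourceDescriptor) -> InstanceGraph:
    """Dispatch on a source descriptor's format."""
    if desc.format == "uniprot-xml":
        graph = read_uniprot(list(desc.paths), source_label=desc.name)
    elif desc.format == "psi-mif":
        graph = read_psimif(list(desc.paths), source_label=desc.name)
    elif desc.format == "biopax-rdf":
        graph = read_biopax(list(desc.paths), source_label=desc.name)
    else:
        raise ValueError(
            "SBML models are read by rbmed.sbml_annotator (the model is both input and output)"
        )
    return graph


def _as_list(files) -> list:
    if isinstance(files, (str, Path)):
        return [files]
    return list(files)


def _biopax_id(node: rdflib.term.Node, source_label: str = "PathwayCommons") -> str:
    s = str(node)
    local = s.rsplit("#", 1)[-1].rsplit("/", 1)[-1]
    return f"{source_label}#{local}"
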