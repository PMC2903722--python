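"""SBML model reading, species↔entity mapping, MIRIAM/SBO annotation
export, and skeleton-reaction proposal.

This module plays the MFO role in the pipeline: the SBML model is both an
input (its species anchor the biological question) and the output target
(integrated knowledge is written back as annotations, names, new species
and skeleton reactions).  All SBML I/O goes through libsbml; every change
made to a model is recorded in a :class:`ModelDelta`, which is auditable
and can be re-applied to the pristine input to reproduce the output.

Annotation URIs use the MIRIAM URN scheme ``urn:miriam:<datatype>:<id>``
(ids percent-encoded) with the biomodels.net biology qualifier ``is`` by
default; identifiers.org URLs can be emitted instead.  Nothing already in
the model is ever modified or removed — export is strictly additive and
idempotent.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union
from urllib.parse import quote, unquote

import libsbml

from .instance_graph import Instance, InstanceGraph

__all__ = [
    "SbmlValidationError",
    "AmbiguousMappingError",
    "MiriamAnnotation",
    "ModelSpecies",
    "ModelDelta",
    "SbmlModel",
    "read_model",
    "write_model",
    "validate_model",
    "map_species_to_entities",
    "export_annotations",
    "propose_new_reactions",
    "apply_delta",
    "default_miriam_registry",
    "parse_miriam_uri",
]

log = logging.getLogger(__name__)

SBO_PATTERN = re.compile(r"^SBO:\d{7}$")

# core/mfo vocabulary consumed here (produced by import/export rules)
CROSSREF_PROP = "mfo:annotatedWith"
SBO_PROP = "mfo:hasSboTerm"
NAME_PROP = "mfo:hasName"
DB_NAME = "tuo:databaseName"
DB_ID = "tuo:databaseId"
SYNONYM = "tuo:synonym"
ACCESSION = "tuo:accession"
PRIMARY_NAME = "tuo:primaryName"

_QUALIFIERS = {
    "is": libsbml.BQB_IS,
    "hasPart": libsbml.BQB_HAS_PART,
    "isPartOf": libsbml.BQB_IS_PART_OF,
    "isVersionOf": libsbml.BQB_IS_VERSION_OF,
    "hasVersion": libsbml.BQB_HAS_VERSION,
    "isHomologTo": libsbml.BQB_IS_HOMOLOG_TO,
    "isDescribedBy": libsbml.BQB_IS_DESCRIBED_BY,
    "isEncodedBy": libsbml.BQB_IS_ENCODED_BY,
    "encodes": libsbml.BQB_ENCODES,
}
_QUALIFIER_NAMES = {v: k for k, v in _QUALIFIERS.items()}


class SbmlValidationError(ValueError):
    """Invalid SBML; ``errors`` lists the validator messages."""

    def __init__(self, errors: list[str]):
        super().__init__("invalid SBML:\n" + "\n".join(errors))
        self.errors = errors


class AmbiguousMappingError(ValueError):
    """A species matched more than one canonical core entity."""


@dataclass(frozen=True)
class MiriamAnnotation:
    """One qualifier+URI cross-reference annotation."""

    qualifier: str
    uri: str

    def __post_init__(self) -> None:
        if self.qualifier not in _QUALIFIERS:
            raise ValueError(f"unknown biology qualifier {self.qualifier!r}")


@dataclass
class ModelSpecies:
    """Read-only view of one SBML species."""

    id: str
    name: Optional[str]
    compartment: Optional[str]
    sbo_term: Optional[str]
    annotations: list[MiriamAnnotation] = field(default_factory=list)


def default_miriam_registry() -> dict[str, str]:
    """Database label -> MIRIAM datatype token, from the packaged table."""
    import yaml
    from importlib.resources import files

    raw = yaml.safe_load(files("rbmed").joinpath("rules/miriam_registry.yaml").read_text())
    return dict(raw)


def _registry_lookup(registry: Mapping[str, str], db: str) -> Optional[str]:
    norm = {k.lower().replace(" ", "").replace("_", ""): v for k, v in registry.items()}
    return norm.get(db.lower().replace(" ", "").replace("_", ""))


def miriam_uri(token: str, identifier: str, style: str = "urn") -> str:
    if style == "urn":
        return f"urn:miriam:{token}:{quote(identifier, safe='')}"
    if style == "url":
        return f"http://identifiers.org/{token}/{identifier}"
    raise ValueError("style must be 'urn' or 'url'")


def parse_miriam_uri(uri: str) -> Optional[tuple[str, str]]:
    """Decompose a MIRIAM URN or identifiers.org URL into (token, id)."""
    if uri.startswith("urn:miriam:"):
        rest = uri[len("urn:miriam:"):]
        token, _, ident = rest.partition(":")
        if token and ident:
            return token, unquote(ident)
        return None
    m = re.match(r"https?://identifiers\.org/([^/]+)/(.+)$", uri)
    if m:
        return m.group(1), m.group(2)
    return None


# ---------------------------------------------------------------------------
# model wrapper + I/O
# ---------------------------------------------------------------------------

class SbmlModel:
    """Thin wrapper over a libsbml document with deterministic accessors."""

    def __init__(self, document: libsbml.SBMLDocument):
        self.document = document
        self.model = document.getModel()
        if self.model is None:
            raise SbmlValidationError(["document contains no model"])

    # -- reading ---------------------------------------------------------

    def species(self) -> list[ModelSpecies]:
        out = []
        for i in range(self.model.getNumSpecies()):
            sp = self.model.getSpecies(i)
            out.append(
                ModelSpecies(
                    id=sp.getId(),
                    name=sp.getName() or None,
                    compartment=sp.getCompartment() or None,
                    sbo_term=sp.getSBOTermID() if sp.isSetSBOTerm() else None,
                    annotations=_read_cvterms(sp),
                )
            )
        return out

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species()]

    def reactions(self) -> list[dict]:
        """Each reaction as {id, name, reactants, products, modifiers}."""
        out = []
        for i in range(self.model.getNumReactions()):
            rx = self.model.getReaction(i)
            out.append(
                {
                    "id": rx.getId(),
                    "name": rx.getName() or None,
                    "reactants": [
                        rx.getReactant(j).getSpecies() for j in range(rx.getNumReactants())
                    ],
                    "products": [
                        rx.getProduct(j).getSpecies() for j in range(rx.getNumProducts())
                    ],
                    "modifiers": [
                        rx.getModifier(j).getSpecies() for j in range(rx.getNumModifiers())
                    ],
                }
            )
        return out

    def reaction_species(self, reaction: dict) -> set[str]:
        return set(reaction["reactants"]) | set(reaction["products"]) | set(
            reaction["modifiers"]
        )

    def reactions_involving(self, species_ids: Iterable[str]) -> list[dict]:
        wanted = set(species_ids)
        return [r for r in self.reactions() if self.reaction_species(r) & wanted]

    # -- round-trip fingerprints ----------------------------------------

    def annotation_content(self) -> dict[str, tuple]:
        """Annotation-relevant content per species (round-trip contract)."""
        return {
            s.id: (
                s.name,
                s.compartment,
                s.sbo_term,
                tuple(sorted((a.qualifier, a.uri) for a in s.annotations)),
            )
            for s in self.species()
        }

    def to_string(self) -> str:
        return libsbml.writeSBMLToString(self.document)


def _read_cvterms(element) -> list[MiriamAnnotation]:
    out = []
    for i in range(element.getNumCVTerms()):
        term = element.getCVTerm(i)
        if term.getQualifierType() != libsbml.BIOLOGICAL_QUALIFIER:
            continue
        qual = _QUALIFIER_NAMES.get(term.getBiologicalQualifierType())
        if qual is None:
            continue
        for j in range(term.getNumResources()):
            out.append(MiriamAnnotation(qual, term.getResourceURI(j)))
    return out


def read_model(path: Union[str, Path]) -> SbmlModel:
    """Read and validate an SBML Level 2 file."""
    doc = libsbml.readSBMLFromFile(str(path))
    errors = _collect_errors(doc)
    if errors:
        raise SbmlValidationError(errors)
    return SbmlModel(doc)


def read_model_from_string(text: str) -> SbmlModel:
    doc = libsbml.readSBMLFromString(text)
    errors = _collect_errors(doc)
    if errors:
        raise SbmlValidationError(errors)
    return SbmlModel(doc)


def write_model(model: SbmlModel, path: Union[str, Path]) -> None:
    """Serialize deterministically (libsbml's canonical writer)."""
    libsbml.writeSBMLToFile(model.document, str(path))


def _collect_errors(doc: libsbml.SBMLDocument) -> list[str]:
    out = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            out.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    return out


def validate_model(model: SbmlModel) -> list[str]:
    """Full consistency check; returns error-severity messages (empty =
    schema-valid)."""
    doc = model.document.clone()
    doc.checkConsistency()
    return _collect_errors(doc)


# ---------------------------------------------------------------------------
# delta
# ---------------------------------------------------------------------------

@dataclass
class ModelDelta:
    """Everything a pipeline run adds to a model — never anything removed.

    Applying a delta to the pristine input model reproduces the output
    model; every element is traceable to a core-graph instance via the
    ``provenance`` map (species id -> source labels).
    """

    annotations_added: dict[str, list[MiriamAnnotation]] = field(default_factory=dict)
    sbo_added: dict[str, str] = field(default_factory=dict)
    names_added: dict[str, str] = field(default_factory=dict)
    species_added: list[dict] = field(default_factory=list)
    reactions_added: list[dict] = field(default_factory=list)
    confirmed_interactions: list[dict] = field(default_factory=list)
    candidate_identities: dict[str, dict] = field(default_factory=dict)
    unplaced: list[str] = field(default_factory=list)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {
            "annotations": sum(len(v) for v in self.annotations_added.values()),
            "sbo_terms": len(self.sbo_added),
            "names": len(self.names_added),
            "species": len(self.species_added),
            "reactions": len(self.reactions_added),
            "confirmed": len(self.confirmed_interactions),
            "candidates": len(self.candidate_identities),
        }

    def is_empty(self) -> bool:
        return all(v == 0 for v in self.counts().values())

    def merged_with(self, other: "ModelDelta") -> "ModelDelta":
        out = ModelDelta(
            annotations_added={k: list(v) for k, v in self.annotations_added.items()},
            sbo_added=dict(self.sbo_added),
            names_added=dict(self.names_added),
            species_added=list(self.species_added),
            reactions_added=list(self.reactions_added),
            confirmed_interactions=list(self.confirmed_interactions),
            candidate_identities=dict(self.candidate_identities),
            unplaced=list(self.unplaced),
            provenance={k: list(v) for k, v in self.provenance.items()},
        )
        for k, v in other.annotations_added.items():
            out.annotations_added.setdefault(k, []).extend(v)
        out.sbo_added.update(other.sbo_added)
        out.names_added.update(other.names_added)
        out.species_added.extend(other.species_added)
        out.reactions_added.extend(other.reactions_added)
        out.confirmed_interactions.extend(other.confirmed_interactions)
        out.candidate_identities.update(other.candidate_identities)
        out.unplaced.extend(other.unplaced)
        for k, v in other.provenance.items():
            bucket = out.provenance.setdefault(k, [])
            bucket.extend(x for x in v if x not in bucket)
        return out

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, MiriamAnnotation):
                return {"qualifier": o.qualifier, "uri": o.uri}
            raise TypeError(type(o))

        payload = {
            "annotations_added": self.annotations_added,
            "sbo_added": self.sbo_added,
            "names_added": self.names_added,
            "species_added": self.species_added,
            "reactions_added": self.reactions_added,
            "confirmed_interactions": self.confirmed_interactions,
            "candidate_identities": self.candidate_identities,
            "unplaced": self.unplaced,
            "provenance": self.provenance,
            "counts": self.counts(),
        }
        return json.dumps(payload, indent=2, default=enc, sort_keys=True)


# ---------------------------------------------------------------------------
# species ↔ entity mapping
# ---------------------------------------------------------------------------

def map_species_to_entities(
    model: SbmlModel,
    core_graph: InstanceGraph,
    protein_class: str = "tuo:Protein",
    uniprot_tokens: Sequence[str] = ("uniprot", "uniprotkb"),
) -> dict[str, Instance]:
    """Map species ids to canonical core entities (partial).

    A species maps when (a) one of its existing MIRIAM UniProtKB
    annotations matches an entity's accession, else (b) its display name
    (falling back to its id) equals an entity synonym case-insensitively.
    Many species may map to one entity; a species matching two distinct
    entities raises :class:`AmbiguousMappingError`; placeholder species
    matching nothing are simply absent from the result.
    """
    if protein_class not in core_graph.classes:
        return {}
    entities = core_graph.class_members(protein_class)
    by_accession: dict[str, list[Instance]] = {}
    by_synonym: dict[str, list[Instance]] = {}
    for ent in entities:
        for acc in ent.literals(ACCESSION):
            by_accession.setdefault(acc, []).append(ent)
        for syn in ent.literals(SYNONYM):
            by_synonym.setdefault(syn.lower(), []).append(ent)

    mapping: dict[str, Instance] = {}
    for sp in model.species():
        candidates: list[Instance] = []
        for ann in sp.annotations:
            parsed = parse_miriam_uri(ann.uri)
            if parsed and parsed[0] in uniprot_tokens:
                candidates.extend(by_accession.get(parsed[1], []))
        if not candidates:
            label = (sp.name or sp.id).lower()
            candidates.extend(by_synonym.get(label, []))
        unique = {c.id: c for c in candidates}
        if len(unique) > 1:
            raise AmbiguousMappingError(
                f"species {sp.id!r} matches several entities: {sorted(unique)}"
            )
        if unique:
            mapping[sp.id] = next(iter(unique.values()))
    return mapping


# ---------------------------------------------------------------------------
# annotation export
# ---------------------------------------------------------------------------

def export_annotations(
    model: SbmlModel,
    core_graph: InstanceGraph,
    mapping: Mapping[str, Instance],
    registry: Optional[Mapping[str, str]] = None,
    qualifier: str = "is",
    uri_style: str = "urn",
) -> ModelDelta:
    """Write entity knowledge onto mapped species; additive and idempotent.

    Per mapped species: one MIRIAM annotation per distinct exported
    cross-reference on its entity (``mfo:annotatedWith``, deduplicated
    against annotations already on the species), an SBO term if the
    entity's export facts dictate one and the species has none, and a name
    if the species has none.  Cross-references naming a database absent
    from the registry are skipped with a warning.  The model is mutated;
    the returned delta reproduces the mutation from the pristine input.
    """
    registry = registry if registry is not None else default_miriam_registry()
    delta = ModelDelta()
    for sp in model.species():
        ent = mapping.get(sp.id)
        if ent is None:
            continue
        existing = {(a.qualifier, a.uri) for a in sp.annotations}
        planned: list[MiriamAnnotation] = []
        for xref in ent.objects(CROSSREF_PROP):
            for db in xref.literals(DB_NAME):
                token = _registry_lookup(registry, db)
                if token is None:
                    log.warning(
                        "cross-reference database %r not in MIRIAM registry; skipped", db
                    )
                    continue
                for ident in xref.literals(DB_ID):
                    ann = MiriamAnnotation(qualifier, miriam_uri(token, ident, uri_style))
                    key = (ann.qualifier, ann.uri)
                    if key not in existing and ann not in planned:
                        planned.append(ann)
        if planned:
            delta.annotations_added[sp.id] = planned
        if sp.sbo_term is None:
            terms = ent.literals(SBO_PROP)
            if terms:
                if not SBO_PATTERN.match(terms[0]):
                    raise ValueError(f"malformed SBO term {terms[0]!r} on {ent.id}")
                delta.sbo_added[sp.id] = terms[0]
        if not sp.name:
            names = ent.literals(NAME_PROP)
            if names:
                delta.names_added[sp.id] = names[0]
        if sp.id in delta.annotations_added or sp.id in delta.sbo_added or sp.id in delta.names_added:
            delta.provenance[sp.id] = list(ent.provenance)
    apply_delta(model, delta)
    return delta


# ---------------------------------------------------------------------------
# skeleton reactions
# ---------------------------------------------------------------------------

def propose_new_reactions(
    model: SbmlModel,
    core_graph: InstanceGraph,
    mapping: Mapping[str, Instance],
    interaction_classes: Sequence[str],
    focus_class: str = "tuo:Rad9",
    registry: Optional[Mapping[str, str]] = None,
    qualifier: str = "is",
    uri_style: str = "urn",
    has_participant: str = "tuo:hasParticipant",
    played_by: str = "tuo:playedBy",
) -> ModelDelta:
    """Turn classified focus-protein interactions into model extensions.

    For each interaction inferred into one of ``interaction_classes``:

    * if the model already has a reaction pairing a focus-mapped species
      with a partner-mapped species, the interaction is *confirmed* and
      never duplicated;
    * otherwise a skeleton reaction is added — reactants only, no kinetic
      law, no parameters — creating the partner species from its core
      entity (with copied MIRIAM annotations) only if no model species maps
      to it;
    * unmapped placeholder species sitting in a reaction with a focus
      species are examined: a newly-proposed kinase partner whose name
      marks it as a kinase is reported as a *candidate* identity for a
      placeholder with a kinase-style name — reported, never substituted.

    The model is mutated; the returned delta records everything.
    """
    registry = registry if registry is not None else default_miriam_registry()
    delta = ModelDelta()

    focus_members = {
        i.id for i in (core_graph.class_members(focus_class) if focus_class in core_graph.classes else [])
    }
    species_for_entity: dict[str, list[str]] = {}
    for sid, ent in mapping.items():
        species_for_entity.setdefault(ent.id, []).append(sid)
    focus_species = [
        sid for sid in model.species_ids() if mapping.get(sid) is not None
        and mapping[sid].id in focus_members
    ]

    # gather classified interactions, deduplicated to (focus, partner) entity pairs
    interactions: list[Instance] = []
    seen_ids: set[str] = set()
    for cls in interaction_classes:
        if cls not in core_graph.classes:
            continue
        for inst in core_graph.class_members(cls):
            if inst.id not in seen_ids:
                seen_ids.add(inst.id)
                interactions.append(inst)
    interactions.sort(key=lambda i: i.id)

    pairs: dict[tuple[str, str], list[str]] = {}  # (focus ent, partner ent) -> provenance
    partner_entities: dict[str, Instance] = {}
    for inter in interactions:
        players = []
        for role in inter.objects(has_participant):
            players.extend(role.objects(played_by))
        foci = [p for p in players if p.id in focus_members]
        partners = [p for p in players if p.id not in focus_members]
        if not foci or not partners:
            continue
        for f in foci:
            for p in partners:
                bucket = pairs.setdefault((f.id, p.id), [])
                for label in inter.provenance:
                    if label not in bucket:
                        bucket.append(label)
                partner_entities[p.id] = p

    reactions = model.reactions()
    confirmed_pairs: set[tuple[str, str]] = set()
    new_pairs: list[tuple[str, str]] = []
    for (fid, pid), prov in sorted(pairs.items()):
        f_species = set(species_for_entity.get(fid, []))
        p_species = set(species_for_entity.get(pid, []))
        hit = None
        for rx in reactions:
            involved = model.reaction_species(rx)
            if involved & f_species and involved & p_species:
                hit = rx
                break
        if hit is not None:
            confirmed_pairs.add((fid, pid))
            delta.confirmed_interactions.append(
                {
                    "focus_entity": fid,
                    "partner_entity": pid,
                    "partner_name": _entity_label(partner_entities[pid]),
                    "reaction": hit["id"],
                    "provenance": prov,
                }
            )
        else:
            new_pairs.append((fid, pid))

    # skeleton reactions for unconfirmed pairs
    for fid, pid in new_pairs:
        ent = partner_entities[pid]
        prov = pairs[(fid, pid)]
        if not species_for_entity.get(fid):
            delta.unplaced.append(f"no model species maps to focus entity {fid}")
            continue
        focus_sid = species_for_entity[fid][0]  # first in model order
        if species_for_entity.get(pid):
            partner_sid = species_for_entity[pid][0]
        else:
            partner_sid = _new_species(model, core_graph, ent, focus_sid, delta,
                                       registry, qualifier, uri_style)
            species_for_entity.setdefault(pid, []).append(partner_sid)
        rid = _unique_id(model, f"skeleton_{focus_sid}_{partner_sid}")
        delta.reactions_added.append(
            {
                "id": rid,
                "reactants": [focus_sid, partner_sid],
                "partner_entity": pid,
                "partner_name": _entity_label(ent),
                "provenance": prov,
            }
        )
        delta.provenance.setdefault(rid, []).extend(
            x for x in prov if x not in delta.provenance.get(rid, [])
        )

    # candidate identities for placeholder species
    placeholder_ids = [
        sid
        for rx in model.reactions_involving(focus_species)
        for sid in sorted(model.reaction_species(rx))
        if sid not in mapping and sid not in focus_species
    ]
    proposed_partners = [pid for _, pid in new_pairs]
    for sid in dict.fromkeys(placeholder_ids):
        if "kin" not in sid.lower():
            continue
        kinases = [
            pid
            for pid in proposed_partners
            if "kinase" in _entity_label(partner_entities[pid]).lower()
        ]
        if len(kinases) == 1:
            ent = partner_entities[kinases[0]]
            delta.candidate_identities[sid] = {
                "entity": ent.id,
                "name": _entity_label(ent),
                "accessions": ent.literals(ACCESSION),
                "basis": "interacts with the focus protein and is annotated as a kinase",
            }
        elif len(kinases) > 1:
            delta.unplaced.append(
                f"placeholder {sid}: several kinase candidates {sorted(kinases)}"
            )
    apply_delta(model, delta, skip_existing=True)
    return delta


def _entity_label(ent: Instance) -> str:
    names = ent.literals(PRIMARY_NAME) or ent.literals(NAME_PROP) or ent.literals(SYNONYM)
    return names[0] if names else ent.id


def _new_species(
    model: SbmlModel,
    core_graph: InstanceGraph,
    ent: Instance,
    sibling_sid: str,
    delta: ModelDelta,
    registry: Mapping[str, str],
    qualifier: str,
    uri_style: str,
) -> str:
    syns = sorted(ent.literals(SYNONYM), key=lambda s: (len(s), s))
    base = re.sub(r"\W+", "_", syns[0] if syns else ent.id.split("#")[-1])
    sid = _unique_id(model, base)
    sibling = next(s for s in model.species() if s.id == sibling_sid)
    annotations = []
    for xref in ent.objects(CROSSREF_PROP):
        for db in xref.literals(DB_NAME):
            token = _registry_lookup(registry, db)
            if token is None:
                continue
            for ident in xref.literals(DB_ID):
                ann = MiriamAnnotation(qualifier, miriam_uri(token, ident, uri_style))
                if ann not in annotations:
                    annotations.append(ann)
    sbo = ent.literals(SBO_PROP)
    delta.species_added.append(
        {
            "id": sid,
            "name": _entity_label(ent),
            "compartment": sibling.compartment,
            "sbo": sbo[0] if sbo else None,
            "annotations": annotations,
            "entity": ent.id,
        }
    )
    delta.provenance[sid] = list(ent.provenance)
    return sid


def _unique_id(model: SbmlModel, base: str) -> str:
    existing = set(model.species_ids()) | {r["id"] for r in model.reactions()}
    if base not in existing:
        return base
    n = 2
    while f"{base}_{n}" in existing:
        n += 1
    return f"{base}_{n}"


# ---------------------------------------------------------------------------
# applying deltas
# ---------------------------------------------------------------------------

def apply_delta(
    model: SbmlModel,
    delta: ModelDelta,
    skip_existing: bool = False,
) -> None:
    """Apply a recorded delta to a model (mutating).

    Everything is additive; with ``skip_existing`` elements already present
    are left alone (used internally when the proposing pass has partially
    applied)."""
    m = model.model
    for sd in delta.species_added:
        if m.getSpecies(sd["id"]) is not None:
            if skip_existing:
                continue
            raise SbmlValidationError([f"species id {sd['id']!r} already in model"])
        sp = m.createSpecies()
        sp.setId(sd["id"])
        if sd.get("name"):
            sp.setName(sd["name"])
        if sd.get("compartment"):
            sp.setCompartment(sd["compartment"])
        elif m.getNumCompartments():
            sp.setCompartment(m.getCompartment(0).getId())
        sp.setInitialConcentration(0.0)
        sp.setHasOnlySubstanceUnits(False)
        if sd.get("sbo"):
            sp.setSBOTerm(int(sd["sbo"].split(":")[1]))
        for ann in sd.get("annotations", []):
            _add_cvterm(sp, ann)
    for sid, anns in delta.annotations_added.items():
        sp = m.getSpecies(sid)
        if sp is None:
            raise SbmlValidationError([f"annotation target species {sid!r} missing"])
        present = {(a.qualifier, a.uri) for a in _read_cvterms(sp)}
        for ann in anns:
            if (ann.qualifier, ann.uri) not in present:
                _add_cvterm(sp, ann)
    for sid, term in delta.sbo_added.items():
        sp = m.getSpecies(sid)
        if sp is not None and not sp.isSetSBOTerm():
            sp.setSBOTerm(int(term.split(":")[1]))
    for sid, name in delta.names_added.items():
        sp = m.getSpecies(sid)
        if sp is not None and not sp.getName():
            sp.setName(name)
    for rd in delta.reactions_added:
        if m.getReaction(rd["id"]) is not None:
            if skip_existing:
                continue
            raise SbmlValidationError([f"reaction id {rd['id']!r} already in model"])
        rx = m.createReaction()
        rx.setId(rd["id"])
        rx.setReversible(False)
        if hasattr(rx, "setFast"):
            rx.setFast(False)
        if rd.get("partner_name"):
            rx.setName(f"skeleton: focus protein with {rd['partner_name']}")
        for sid in rd["reactants"]:
            ref = rx.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(1.0)
        # no products, no kinetic law, no parameters: a placeholder for curation


def _add_cvterm(element, ann: MiriamAnnotation) -> None:
    if not element.isSetMetaId():
        element.setMetaId(f"meta_{element.getId()}")
    term = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
    term.setBiologicalQualifierType(_QUALIFIERS[ann.qualifier])
    term.addResource(ann.uri)
    code = element.addCVTerm(term)
    if code != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise SbmlValidationError([f"could not add annotation {ann.uri} to {element.getId()}"])
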