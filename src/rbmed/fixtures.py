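"""Deterministic synthetic corpus emulating the study's four data sources.

The corpus fixes the study inputs so the whole pipeline runs offline
and reproducibly: a UniProtKB-style XML file with the five yeast
checkpoint proteins (RAD9 P14737, RAD53 P22216, CHK1 P38147, MEC1 P38111,
RAD17 P48581), a PSI-MI 1.0 file carrying the BioGRID interaction pattern
(RAD9–RAD53, RAD9–MEC1, RAD9–RAD17), a BioPAX level-2 RDF file carrying
the Pathway Commons pattern (RAD9–RAD53, RAD9–CHK1), and a toy
telomere-uncapping SBML model with two RAD9 species (active/inactive),
four RAD9 reactions, and the placeholder species Rad9Kin and ExoX.

Decoy records (a human RAD9 homolog, a non-RAD9 interaction) never share a
reconciliation key with roster proteins of the target taxon, so each decoy
is removable by exactly one mechanism (organism restriction, rule filters).
The default corpus uses no randomness; regeneration is checksum-identical.
An optional seed adds extra noise records for stress tests.

The file dialects are minimal documented subsets of the real formats,
validated against the shipped readers; they do not track any official
schema release.  The toy model's species/compartment layout is this
package's own — synthetic, not the deposited curated model.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Optional

import libsbml
from lxml import etree

__all__ = ["CorpusManifest", "generate_corpus", "YEAST_TAXON", "HUMAN_TAXON", "ROSTER"]

YEAST_TAXON = "559292"
HUMAN_TAXON = "9606"

#: The protein roster: accession -> (gene, recommended full name)
ROSTER = {
    "P14737": ("RAD9", "DNA damage-dependent checkpoint protein RAD9"),
    "P22216": ("RAD53", "Serine/threonine-protein kinase RAD53"),
    "P38147": ("CHK1", "Serine/threonine-protein kinase CHK1"),
    "P38111": ("MEC1", "Serine/threonine-protein kinase MEC1"),
    "P48581": ("RAD17", "DNA damage checkpoint control protein RAD17"),
}

_RULE_FILES = [
    "core_schema.txt",
    "miriam_registry.yaml",
    "import_uniprot.rules",
    "import_psimif.rules",
    "import_biopax.rules",
    "classify_proteins.rules",
    "defined_interactions.txt",
    "export_sbml.rules",
    "queries.rules",
]


@dataclass
class CorpusManifest:
    """What was generated: file checksums, roster, interaction pattern."""

    files: dict[str, str]
    taxon: str
    roster: dict[str, str]
    interactions: dict[str, list[list[str]]]
    decoys: bool
    seed: Optional[int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "files": self.files,
                "taxon": self.taxon,
                "roster": self.roster,
                "interactions": self.interactions,
                "decoys": self.decoys,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# UniProtKB-style XML
# ---------------------------------------------------------------------------

def _uniprot_entry(
    parent,
    accessions: list[str],
    entry_name: str,
    rec_name: str,
    genes: list[str],
    taxon: str,
    location: Optional[str] = None,
    xrefs: list[tuple[str, str]] = (),
    alt_names: list[str] = (),
    function_note: Optional[str] = None,
) -> None:
    e = etree.SubElement(parent, "entry")
    for acc in accessions:
        etree.SubElement(e, "accession").text = acc
    etree.SubElement(e, "name").text = entry_name
    prot = etree.SubElement(e, "protein")
    rn = etree.SubElement(prot, "recommendedName")
    etree.SubElement(rn, "fullName").text = rec_name
    for alt in alt_names:
        an = etree.SubElement(prot, "alternativeName")
        etree.SubElement(an, "fullName").text = alt
    gene = etree.SubElement(e, "gene")
    for i, g in enumerate(genes):
        etree.SubElement(gene, "name", type="primary" if i == 0 else "synonym").text = g
    org = etree.SubElement(e, "organism")
    etree.SubElement(org, "name", type="scientific").text = (
        "Saccharomyces cerevisiae" if taxon == YEAST_TAXON else "Homo sapiens"
    )
    etree.SubElement(org, "dbReference", type="NCBI Taxonomy", id=taxon)
    if location:
        c = etree.SubElement(e, "comment", type="subcellular location")
        sl = etree.SubElement(c, "subcellularLocation")
        etree.SubElement(sl, "location").text = location
    if function_note:
        c = etree.SubElement(e, "comment", type="function")
        etree.SubElement(c, "text").text = function_note
    for db, ident in xrefs:
        etree.SubElement(e, "dbReference", type=db, id=ident)


def _build_uniprot(decoys: bool, rng: Optional[random.Random]) -> bytes:
    root = etree.Element("uniprot")
    _uniprot_entry(
        root,
        ["P14737", "D6VTR8"],
        "RAD9_YEAST",
        ROSTER["P14737"][1],
        ["RAD9"],
        YEAST_TAXON,
        location="Nucleus",
        xrefs=[("IntAct", "EBI-14826"), ("SGD", "S000002625")],
    )
    _uniprot_entry(
        root, ["P22216"], "RAD53_YEAST", ROSTER["P22216"][1], ["RAD53", "SPK1"],
        YEAST_TAXON, location="Nucleus", xrefs=[("SGD", "S000005946")],
    )
    _uniprot_entry(
        root, ["P38147"], "CHK1_YEAST", ROSTER["P38147"][1], ["CHK1"],
        YEAST_TAXON, location="Nucleus", xrefs=[("SGD", "S000000233")],
    )
    _uniprot_entry(
        root, ["P38111"], "MEC1_YEAST", ROSTER["P38111"][1], ["MEC1"],
        YEAST_TAXON, location="Nucleus", xrefs=[("SGD", "S000000340")],
        function_note=(
            "Serine/threonine protein kinase of the checkpoint response; "
            "phosphorylates the RAD9 checkpoint protein after DNA damage."
        ),
    )
    _uniprot_entry(
        root, ["P48581"], "RAD17_YEAST", ROSTER["P48581"][1], ["RAD17"],
        YEAST_TAXON, location="Nucleus", xrefs=[("SGD", "S000005579")],
    )
    if decoys:
        # human homolog: shares the 'rad9' name pattern but neither the
        # accession key nor the taxon — removable only by organism restriction
        _uniprot_entry(
            root, ["Q99638"], "RAD9A_HUMAN",
            "Cell cycle checkpoint control protein RAD9A", ["RAD9A"],
            HUMAN_TAXON, location="Nucleus", xrefs=[("IntAct", "EBI-728222")],
        )
    if rng is not None:
        for k in range(3):
            acc = f"P9990{k}"
            _uniprot_entry(
                root, [acc], f"NOISE{k}_YEAST",
                f"Uncharacterized noise protein {rng.randint(100, 999)}",
                [f"NSE{k}"], YEAST_TAXON,
            )
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# PSI-MI 1.0-style XML (BioGRID pattern)
# ---------------------------------------------------------------------------

def _psi_interactor(parent, iid: str, label: str, accession: str,
                    secondary: list[tuple[str, str]], taxon: str) -> None:
    p = etree.SubElement(parent, "proteinInteractor", id=iid)
    names = etree.SubElement(p, "names")
    etree.SubElement(names, "shortLabel").text = label
    xref = etree.SubElement(p, "xref")
    etree.SubElement(xref, "primaryRef", db="uniprotkb", id=accession)
    for db, ident in secondary:
        etree.SubElement(xref, "secondaryRef", db=db, id=ident)
    etree.SubElement(p, "organism", ncbiTaxId=taxon)


def _build_psimif(decoys: bool, rng: Optional[random.Random]) -> bytes:
    root = etree.Element("entrySet")
    entry = etree.SubElement(root, "entry")
    ilist = etree.SubElement(entry, "interactorList")
    _psi_interactor(ilist, "i1", "RAD9", "P14737",
                    [("sgd", "S000002625"), ("biogrid", "33194")], YEAST_TAXON)
    _psi_interactor(ilist, "i2", "RAD53", "P22216", [("biogrid", "31171")], YEAST_TAXON)
    _psi_interactor(ilist, "i3", "MEC1", "P38111", [("biogrid", "31068")], YEAST_TAXON)
    _psi_interactor(ilist, "i4", "RAD17", "P48581", [("biogrid", "33425")], YEAST_TAXON)
    pairs = [("i1", "i2", "rad9-rad53"), ("i1", "i3", "rad9-mec1"), ("i1", "i4", "rad9-rad17")]
    if decoys:
        _psi_interactor(ilist, "i5", "CDC28", "P00546", [("biogrid", "30799")], YEAST_TAXON)
        # decoy interaction without RAD9: caught by no defined class
        pairs.append(("i2", "i5", "rad53-cdc28"))
    if rng is not None:
        for k in range(2):
            a, b = rng.sample(["i2", "i3", "i4"], 2)
            pairs.append((a, b, f"noise-{k}"))
    xlist = etree.SubElement(entry, "interactionList")
    for a, b, label in pairs:
        inter = etree.SubElement(xlist, "interaction")
        names = etree.SubElement(inter, "names")
        etree.SubElement(names, "shortLabel").text = label
        plist = etree.SubElement(inter, "participantList")
        for ref in (a, b):
            part = etree.SubElement(plist, "proteinParticipant")
            etree.SubElement(part, "proteinInteractorRef", ref=ref)
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# BioPAX level-2-style RDF/XML (Pathway Commons pattern)
# ---------------------------------------------------------------------------

_BIOPAX_HEADER = """<?xml version="1.0" encoding="UTF-8"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:bp="http://www.biopax.org/release/biopax-level2.owl#"
         xml:base="http://rbmed.example/pc#">
"""


def _bp_protein(lines: list[str], rid: str, name: str, accession: str,
                extra_xrefs: list[tuple[str, str, str]], taxon_ref: str) -> None:
    xref_ids = [f"{rid}_upx"]
    lines.append(
        f'  <bp:unificationXref rdf:ID="{rid}_upx">\n'
        f"    <bp:DB>UniProt</bp:DB>\n    <bp:ID>{accession}</bp:ID>\n"
        f"  </bp:unificationXref>"
    )
    for n, (kind, db, ident) in enumerate(extra_xrefs):
        xid = f"{rid}_x{n}"
        xref_ids.append(xid)
        lines.append(
            f'  <bp:{kind} rdf:ID="{xid}">\n'
            f"    <bp:DB>{db}</bp:DB>\n    <bp:ID>{ident}</bp:ID>\n"
            f"  </bp:{kind}>"
        )
    refs = "\n".join(f'    <bp:XREF rdf:resource="#{x}"/>' for x in xref_ids)
    lines.append(
        f'  <bp:protein rdf:ID="{rid}">\n'
        f"    <bp:NAME>{name}</bp:NAME>\n{refs}\n"
        f'    <bp:ORGANISM rdf:resource="#{taxon_ref}"/>\n'
        f"  </bp:protein>"
    )


def _build_biopax(decoys: bool) -> bytes:
    lines = [_BIOPAX_HEADER.rstrip()]
    lines.append(
        '  <bp:unificationXref rdf:ID="taxon_yeast_x">\n'
        f"    <bp:DB>NCBI_taxonomy</bp:DB>\n    <bp:ID>{YEAST_TAXON}</bp:ID>\n"
        "  </bp:unificationXref>"
    )
    lines.append(
        '  <bp:bioSource rdf:ID="taxon_yeast">\n'
        '    <bp:TAXON-XREF rdf:resource="#taxon_yeast_x"/>\n'
        "  </bp:bioSource>"
    )
    _bp_protein(
        lines, "rad9_pc", "RAD9", "P14737",
        [("relationshipXref", "IntAct", "EBI-4641958"),
         ("relationshipXref", "Pathway Commons", "CPATH-34926")],
        "taxon_yeast",
    )
    _bp_protein(lines, "rad53_pc", "RAD53", "P22216", [], "taxon_yeast")
    _bp_protein(lines, "chk1_pc", "CHK1", "P38147", [], "taxon_yeast")
    participants = {
        "int_rad9_rad53": ["rad9_pc", "rad53_pc"],
        "int_rad9_chk1": ["rad9_pc", "chk1_pc"],
    }
    for iid, prots in participants.items():
        pep_ids = []
        for prot in prots:
            pid = f"{iid}_pep_{prot}"
            pep_ids.append(pid)
            lines.append(
                f'  <bp:physicalEntityParticipant rdf:ID="{pid}">\n'
                f'    <bp:PHYSICAL-ENTITY rdf:resource="#{prot}"/>\n'
                "  </bp:physicalEntityParticipant>"
            )
        refs = "\n".join(
            f'    <bp:PARTICIPANTS rdf:resource="#{p}"/>' for p in pep_ids
        )
        lines.append(f'  <bp:physicalInteraction rdf:ID="{iid}">\n{refs}\n  </bp:physicalInteraction>')
    lines.append("</rdf:RDF>\n")
    return "\n".join(lines).encode()


# ---------------------------------------------------------------------------
# toy telomere-uncapping SBML model
# ---------------------------------------------------------------------------

def _build_model() -> bytes:
    doc = libsbml.SBMLDocument(2, 4)
    model = doc.createModel("telomere_uncapping_toy")
    model.setName("toy telomere uncapping model (synthetic)")
    comp = model.createCompartment()
    comp.setId("nucleus")
    comp.setSize(1.0)

    def add_species(sid, name=None, accession=None):
        sp = model.createSpecies()
        sp.setId(sid)
        if name:
            sp.setName(name)
        sp.setCompartment("nucleus")
        sp.setInitialConcentration(0.0)
        if accession:
            sp.setMetaId(f"meta_{sid}")
            term = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
            term.setBiologicalQualifierType(libsbml.BQB_IS)
            term.addResource(f"urn:miriam:uniprot:{accession}")
            sp.addCVTerm(term)
        return sp

    # two species for one protein: the active/inactive forms of RAD9, each
    # carrying the modeller's single original UniProtKB reference
    add_species("Rad9_inactive", "inactive Rad9", accession="P14737")
    add_species("Rad9_active", "active Rad9", accession="P14737")
    add_species("Rad53")
    add_species("Chk1")
    add_species("Mec1")
    add_species("Rad17")
    add_species("Rad9Kin")  # placeholder: the unknown RAD9-activating kinase
    add_species("ExoX")     # placeholder: the unknown exonuclease

    def add_reaction(rid, reactants, products=(), modifiers=()):
        rx = model.createReaction()
        rx.setId(rid)
        rx.setReversible(False)
        for sid in reactants:
            ref = rx.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(1.0)
        for sid in products:
            ref = rx.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(1.0)
        for sid in modifiers:
            ref = rx.createModifier()
            ref.setSpecies(sid)

    # four reactions involve a RAD9 species; two of them use placeholders
    add_reaction("rad9_activation", ["Rad9_inactive"], ["Rad9_active"], ["Rad9Kin"])
    add_reaction("rad9_rad53_binding", ["Rad9_active", "Rad53"])
    add_reaction("rad9_chk1_binding", ["Rad9_active", "Chk1"])
    add_reaction("rad9_degradation", ["Rad9_active", "ExoX"])
    add_reaction("mec1_rad53_signaling", ["Mec1", "Rad53"])
    return libsbml.writeSBMLToString(doc).encode()


# ---------------------------------------------------------------------------
# pipeline config + assembly
# ---------------------------------------------------------------------------

_PIPELINE_YAML = """\
sources:
  - name: UniProtKB
    format: uniprot-xml
    paths: [uniprot.xml]
  - name: BioGRID
    format: psi-mif
    paths: [biogrid.xml]
  - name: PathwayCommons
    format: biopax-rdf
    paths: [pathwaycommons.owl]
core_schema: rules/core_schema.txt
rules:
  import:
    - rules/import_uniprot.rules
    - rules/import_psimif.rules
    - rules/import_biopax.rules
  classification:
    - rules/classify_proteins.rules
  defined_classes:
    - rules/defined_interactions.txt
  export:
    - rules/export_sbml.rules
queries:
  - rules/queries.rules
reconciliation_keys: [accession, name+taxon]
target_taxon: "559292"
focus_class: tuo:Rad9
interaction_classes:
  - tuo:Rad9Rad53Interaction
  - tuo:Rad9Chk1Interaction
  - tuo:Rad9Mec1Interaction
  - tuo:Rad9Rad17Interaction
miriam_registry: rules/miriam_registry.yaml
model: model.xml
output:
  model: annotated_model.xml
  delta: delta.json
flags:
  provenance_notes: false
  xml_mode: strict
  uri_style: urn
"""


def generate_corpus(
    out_dir, include_decoys: bool = True, seed: Optional[int] = None
) -> CorpusManifest:
    """Write the corpus into ``out_dir`` and return its manifest.

    Content is fully determined by (package version, ``include_decoys``,
    ``seed``); with the default ``seed=None`` no randomness is involved and
    regeneration yields identical checksums.
    """
    out = Path(out_dir)
    (out / "rules").mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed) if seed is not None else None

    contents: dict[str, bytes] = {
        "uniprot.xml": _build_uniprot(include_decoys, rng),
        "biogrid.xml": _build_psimif(include_decoys, rng),
        "pathwaycommons.owl": _build_biopax(include_decoys),
        "model.xml": _build_model(),
        "pipeline.yaml": _PIPELINE_YAML.encode(),
    }
    for name in _RULE_FILES:
        contents[f"rules/{name}"] = files("rbmed").joinpath(f"rules/{name}").read_bytes()

    checksums: dict[str, str] = {}
    for rel, data in contents.items():
        path = out / rel
        path.write_bytes(data)
        checksums[rel] = hashlib.sha256(data).hexdigest()

    interactions = {
        "BioGRID": [["P14737", "P22216"], ["P14737", "P38111"], ["P14737", "P48581"]],
        "PathwayCommons": [["P14737", "P22216"], ["P14737", "P38147"]],
    }
    manifest = CorpusManifest(
        files=checksums,
        taxon=YEAST_TAXON,
        roster={acc: gene for acc, (gene, _) in ROSTER.items()},
        interactions=interactions,
        decoys=include_decoys,
        seed=seed,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
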