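import pytest

from rbmed.core_ontology import default_core_schema
from rbmed.instance_graph import InstanceGraph, Literal
from rbmed.sbml_annotator import (
    AmbiguousMappingError,
    MiriamAnnotation,
    SbmlValidationError,
    apply_delta,
    default_miriam_registry,
    export_annotations,
    map_species_to_entities,
    parse_miriam_uri,
    propose_new_reactions,
    read_model,
    read_model_from_string,
    validate_model,
    write_model,
)


@pytest.fixture()
def model(corpus_dir):
    return read_model(corpus_dir / "model.xml")


def entity_graph(entries):
    """entries: (id, accession, synonyms, xrefs[(db, ident)], classes)."""
    g = InstanceGraph()
    default_core_schema().install_into(g)
    g.add_property("mfo:annotatedWith", "object")
    g.add_property("mfo:hasSboTerm", "data")
    g.add_property("mfo:hasName", "data")
    for iid, acc, syns, xrefs, classes in entries:
        inst = g.add_instance(iid, classes, source=iid.split("#")[0])
        if acc:
            g.assert_value(inst, "tuo:accession", Literal(acc))
        for s in syns:
            g.assert_value(inst, "tuo:synonym", Literal(s))
        if syns:
            g.assert_value(inst, "tuo:primaryName", Literal(syns[0]))
            g.assert_value(inst, "mfo:hasName", Literal(syns[0]))
        g.assert_value(inst, "mfo:hasSboTerm", Literal("SBO:0000252"))
        for n, (db, ident) in enumerate(xrefs):
            x = g.add_instance(f"{iid}_x{n}", ["tuo:CrossReference"], source="x")
            g.assert_value(x, "tuo:databaseName", Literal(db))
            g.assert_value(x, "tuo:databaseId", Literal(ident))
            g.assert_value(inst, "tuo:hasCrossReference", x)
            g.assert_value(inst, "mfo:annotatedWith", x)
    return g


# -- reading ----------------------------------------------------------------

def test_toy_model_structure(model):
    species = {s.id for s in model.species()}
    assert {"Rad9_inactive", "Rad9_active", "Rad9Kin", "ExoX"} <= species
    rad9 = [s for s in model.species()
            if any("P14737" in a.uri for a in s.annotations)]
    assert sorted(s.id for s in rad9) == ["Rad9_active", "Rad9_inactive"]
    involving = model.reactions_involving([s.id for s in rad9])
    assert len(involving) == 4


def test_round_trip_preserves_annotation_content(model, tmp_path):
    out = tmp_path / "copy.xml"
    write_model(model, out)
    assert read_model(out).annotation_content() == model.annotation_content()


def test_invalid_sbml_rejected():
    with pytest.raises(SbmlValidationError):
        read_model_from_string("<sbml xmlns='http://www.sbml.org/sbml/level2/version4' level='2' version='4'><model><listOfSpecies><species/></listOfSpecies></model></sbml>")


# -- mapping ----------------------------------------------------------------

def test_mapping_by_annotation_and_name(model):
    g = entity_graph(
        [
            ("c#rad9", "P14737", ["RAD9"], [], ["tuo:Protein", "tuo:Rad9"]),
            ("c#rad53", "P22216", ["Serine/threonine-protein kinase RAD53", "RAD53"],
             [], ["tuo:Protein"]),
        ]
    )
    mapping = map_species_to_entities(model, g)
    assert mapping["Rad9_inactive"].id == "c#rad9"
    assert mapping["Rad9_active"].id == "c#rad9"  # many species, one entity
    assert mapping["Rad53"].id == "c#rad53"  # case-insensitive synonym match
    assert "Rad9Kin" not in mapping and "ExoX" not in mapping  # placeholders


def test_mapping_matches_pairwise_scan_oracle(model, pipeline):
    g = pipeline.core_graph
    mapping = map_species_to_entities(model, g)
    entities = g.class_members("tuo:Protein")
    for sp in model.species():
        expected = set()
        accs = {parse_miriam_uri(a.uri)[1] for a in sp.annotations
                if parse_miriam_uri(a.uri) and parse_miriam_uri(a.uri)[0] == "uniprot"}
        for ent in entities:
            if accs & set(ent.literals("tuo:accession")):
                expected.add(ent.id)
        if not expected:
            label = (sp.name or sp.id).lower()
            for ent in entities:
                if label in {s.lower() for s in ent.literals("tuo:synonym")}:
                    expected.add(ent.id)
        got = {mapping[sp.id].id} if sp.id in mapping else set()
        assert got == expected


def test_ambiguous_mapping_is_an_error(model):
    g = entity_graph(
        [
            ("c#a", "P14737", ["A"], [], ["tuo:Protein"]),
            ("c#b", "P14737", ["B"], [], ["tuo:Protein"]),
        ]
    )
    with pytest.raises(AmbiguousMappingError, match="Rad9_inactive"):
        map_species_to_entities(model, g)


# -- export -----------------------------------------------------------------

def test_export_adds_deduplicates_and_is_idempotent(model):
    g = entity_graph(
        [
            (
                "c#rad9", "P14737", ["RAD9"],
                [("UniProt", "P14737"),  # already on the species: dedup
                 ("IntAct", "EBI-14826"), ("SGD", "S000002625")],
                ["tuo:Protein", "tuo:Rad9"],
            )
        ]
    )
    mapping = map_species_to_entities(model, g)
    delta = export_annotations(model, g, mapping)
    added = delta.annotations_added["Rad9_inactive"]
    assert [a.uri for a in added] == [
        "urn:miriam:intact:EBI-14826",
        "urn:miriam:sgd:S000002625",
    ]
    assert delta.sbo_added["Rad9_inactive"] == "SBO:0000252"
    # every emitted URN parses back to an (db,id) pair on the entity
    registry = default_miriam_registry()
    xref_pairs = set()
    ent = g.instances["c#rad9"]
    for x in ent.objects("mfo:annotatedWith"):
        for db in x.literals("tuo:databaseName"):
            for ident in x.literals("tuo:databaseId"):
                xref_pairs.add((registry.get(db, db).lower(), ident))
    for ann in added:
        assert parse_miriam_uri(ann.uri) in xref_pairs
    # idempotence
    delta2 = export_annotations(model, g, mapping)
    assert delta2.is_empty()


def test_export_never_removes_or_changes_existing(model):
    before = model.annotation_content()
    g = entity_graph(
        [("c#rad9", "P14737", ["a new name"], [("SGD", "S1")], ["tuo:Protein"])]
    )
    mapping = map_species_to_entities(model, g)
    export_annotations(model, g, mapping)
    after = model.annotation_content()
    for sid, (name, comp, sbo, anns) in before.items():
        a_name, a_comp, a_sbo, a_anns = after[sid]
        assert comp == a_comp
        assert name is None or a_name == name  # names only filled when absent
        assert sbo is None or a_sbo == sbo
        assert set(anns) <= set(a_anns)


def test_export_skips_unregistered_database(model, caplog):
    g = entity_graph(
        [("c#rad9", "P14737", ["RAD9"], [("MadeUpDB", "1")], ["tuo:Protein"])]
    )
    mapping = map_species_to_entities(model, g)
    with caplog.at_level("WARNING"):
        delta = export_annotations(model, g, mapping)
    assert "Rad9_inactive" not in delta.annotations_added
    assert any("MadeUpDB" in r.getMessage() for r in caplog.records)


def test_entity_without_xrefs_yields_no_annotations(model):
    g = entity_graph([("c#rad9", "P14737", [], [], ["tuo:Protein"])])
    # strip SBO/name export facts so the delta is truly empty for this species
    ent = g.instances["c#rad9"]
    ent.assertions.pop("mfo:hasSboTerm", None)
    ent.assertions.pop("mfo:hasName", None)
    mapping = map_species_to_entities(model, g)
    model_before = model.annotation_content()
    delta = export_annotations(model, g, mapping)
    assert delta.is_empty()
    assert model.annotation_content() == model_before


# -- delta + validation -----------------------------------------------------

def test_delta_reapplication_reproduces_output(corpus_dir, pipeline):
    fresh = read_model(corpus_dir / "model.xml")
    apply_delta(fresh, pipeline.delta)
    annotated = read_model(pipeline.out_model)
    assert fresh.annotation_content() == annotated.annotation_content()
    assert {r["id"] for r in fresh.reactions()} == {r["id"] for r in annotated.reactions()}


def test_annotated_model_passes_sbml_validation(pipeline):
    assert validate_model(read_model(pipeline.out_model)) == []


def test_skeleton_reactions_have_no_kinetics(pipeline):
    annotated = read_model(pipeline.out_model)
    skeleton_ids = {r["id"] for r in pipeline.delta.reactions_added}
    assert skeleton_ids
    for i in range(annotated.model.getNumReactions()):
        rx = annotated.model.getReaction(i)
        if rx.getId() in skeleton_ids:
            assert not rx.isSetKineticLaw()
            assert rx.getNumProducts() == 0
            assert rx.getNumReactants() == 2


def test_new_species_created_when_partner_absent(corpus_dir):
    """A partner with no model species is added with copied annotations."""
    model = read_model(corpus_dir / "model.xml")
    g = entity_graph(
        [
            ("c#rad9", "P14737", ["RAD9"], [], ["tuo:Protein", "tuo:Rad9"]),
            ("c#dun1", "P39009", ["DUN1", "Serine/threonine-protein kinase DUN1"],
             [("SGD", "S000002260")], ["tuo:Protein"]),
        ]
    )
    g.add_class("NewPair", ["tuo:Interaction"])
    role1 = g.add_instance("c#role1", ["tuo:ParticipantRole"], source="c")
    role2 = g.add_instance("c#role2", ["tuo:ParticipantRole"], source="c")
    g.assert_value(role1, "tuo:playedBy", g.instances["c#rad9"])
    g.assert_value(role2, "tuo:playedBy", g.instances["c#dun1"])
    inter = g.add_instance("c#int1", ["tuo:Interaction", "NewPair"], source="c")
    g.assert_value(inter, "tuo:hasParticipant", role1)
    g.assert_value(inter, "tuo:hasParticipant", role2)
    mapping = map_species_to_entities(model, g)
    delta = propose_new_reactions(model, g, mapping, ["NewPair"])
    assert len(delta.species_added) == 1
    sp = delta.species_added[0]
    assert sp["name"] == "DUN1"
    assert any(a.uri == "urn:miriam:sgd:S000002260" for a in sp["annotations"])
    assert len(delta.reactions_added) == 1
    assert validate_model(model) == []


def test_miriam_uri_grammar_and_percent_encoding():
    ann = MiriamAnnotation("is", "urn:miriam:obo.go:GO%3A0005634")
    assert parse_miriam_uri(ann.uri) == ("obo.go", "GO:0005634")
    assert parse_miriam_uri("http://identifiers.org/uniprot/P14737") == (
        "uniprot", "P14737",
    )
    assert parse_miriam_uri("not-a-miriam-uri") is None
    with pytest.raises(ValueError):
        MiriamAnnotation("frobs", "urn:miriam:x:y")
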