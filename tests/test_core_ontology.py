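import random

import pytest

from rbmed.core_ontology import (
    assert_equivalences,
    default_core_schema,
    load_core_schema,
    merge_equivalents,
    restrict_organism,
)
from rbmed.instance_graph import InstanceGraph, Literal

from oracles import UnionFind


def core_graph(entries, links=()):
    """entries: (id, accession|None, name|None, taxon|None); links: (role, protein)."""
    g = InstanceGraph()
    schema = default_core_schema()
    schema.install_into(g)
    for iid, acc, name, taxon in entries:
        inst = g.add_instance(iid, ["tuo:Protein"], source=iid.split("#")[0])
        if acc:
            g.assert_value(inst, "tuo:accession", Literal(acc))
        if name:
            g.assert_value(inst, "tuo:primaryName", Literal(name))
            g.assert_value(inst, "tuo:synonym", Literal(name))
        if taxon:
            g.assert_value(inst, "tuo:taxonId", Literal(taxon))
    return g


def test_schema_loads_and_is_source_independent():
    schema = default_core_schema()
    assert "tuo:Protein" in schema.graph.classes
    assert schema.inverses["tuo:plays"] == "tuo:playedBy"
    for sym in list(schema.graph.classes) + list(schema.graph.properties):
        prefix = sym.split(":")[0]
        assert prefix == "tuo"  # nothing names a source format


def test_schema_parse_error_carries_line():
    with pytest.raises(ValueError, match="line 2"):
        load_core_schema("class tuo:A\nnonsense here\n")


def test_three_rad9_instances_form_one_set():
    g = core_graph(
        [
            ("UniProtKB#e1", "P14737", "RAD9", "559292"),
            ("BioGRID#i1", "P14737", "RAD9", "559292"),
            ("PathwayCommons#p1", "P14737", "RAD9", "559292"),
            ("UniProtKB#e2", "P22216", "RAD53", "559292"),
        ]
    )
    part = assert_equivalences(g)
    assert sorted(map(len, part.sets)) == [1, 3]
    big = part.set_of("UniProtKB#e1")
    assert {i.split("#")[0] for i in big} == {"UniProtKB", "BioGRID", "PathwayCommons"}


def test_no_shared_keys_all_singletons():
    g = core_graph([("a#1", "P1", None, "4932"), ("b#2", "P2", None, "4932")])
    part = assert_equivalences(g)
    assert all(len(s) == 1 for s in part.sets)


def test_taxon_conflict_blocks_merge(caplog):
    g = core_graph(
        [("a#1", "PX", None, "559292"), ("b#2", "PX", None, "9606")]
    )
    with caplog.at_level("WARNING"):
        part = assert_equivalences(g)
    assert all(len(s) == 1 for s in part.sets)
    assert any("not merged" in r.getMessage() for r in caplog.records)


@pytest.mark.parametrize("seed", range(5))
def test_partition_equals_union_find_oracle(seed):
    rng = random.Random(seed)
    accs = [f"P{n}" for n in range(6)]
    entries = []
    for i in range(15):
        entries.append((f"s#{i}", rng.choice(accs + [None] * 3), None, "4932"))
    g = core_graph(entries)
    part = assert_equivalences(g, keys=["accession"])

    uf = UnionFind([e[0] for e in entries])
    for i, (ida, acca, _, _) in enumerate(entries):
        for idb, accb, _, _ in entries[i + 1:]:
            if acca and acca == accb:
                uf.join(ida, idb)
    assert set(part.sets) == uf.sets()


def test_partition_deterministic_under_insertion_order():
    entries = [
        ("c#1", "P1", None, "4932"),
        ("a#2", "P1", None, "4932"),
        ("b#3", "P2", None, "4932"),
        ("d#4", "P2", None, "4932"),
    ]
    p1 = assert_equivalences(core_graph(entries))
    p2 = assert_equivalences(core_graph(list(reversed(entries))))
    assert set(p1.sets) == set(p2.sets)


def test_name_taxon_fallback_key():
    g = core_graph(
        [("a#1", None, "Rad9", "559292"), ("b#2", None, "RAD9", "559292"),
         ("c#3", None, "RAD9", "9606")]
    )
    part = assert_equivalences(g)
    assert part.set_of("a#1") == frozenset({"a#1", "b#2"})  # case-insensitive, same taxon
    assert part.set_of("c#3") == frozenset({"c#3"})


def test_merge_unions_assertions_and_provenance():
    g = core_graph(
        [
            ("UniProtKB#e1", "P14737", "RAD9 checkpoint", "559292"),
            ("BioGRID#i1", "P14737", "RAD9", "559292"),
            ("PathwayCommons#p1", "P14737", "RAD9", "559292"),
        ]
    )
    # one cross-reference per source
    for n, owner in enumerate(["UniProtKB#e1", "BioGRID#i1", "PathwayCommons#p1"]):
        x = g.add_instance(f"x#{n}", ["tuo:CrossReference"], source=owner.split("#")[0])
        g.assert_value(x, "tuo:databaseName", Literal(f"DB{n}"))
        g.assert_value(g.instances[owner], "tuo:hasCrossReference", x)
    part = assert_equivalences(g)
    merged = merge_equivalents(g, part)
    canon = merged.instances[part.canonical("UniProtKB#e1")]
    assert sorted(canon.provenance) == ["BioGRID", "PathwayCommons", "UniProtKB"]
    assert len(canon.objects("tuo:hasCrossReference")) == 3
    # information preservation: every pre-merge (prop, literal) pair survives
    for inst in g.instances.values():
        target = merged.instances[part.canonical(inst.id)]
        for prop, vals in inst.assertions.items():
            for v in vals:
                if isinstance(v, Literal):
                    assert v.value in target.literals(prop)


def test_merge_singleton_unchanged_and_dedup_conserves_pairs():
    g = core_graph([("a#1", "P1", "X", "4932")])
    part = assert_equivalences(g)
    merged = merge_equivalents(g, part)
    a = merged.instances["a#1"]
    assert a.literals("tuo:accession") == ["P1"]
    n_pairs = lambda gr: {
        (i.id, p, v.value if isinstance(v, Literal) else v.id)
        for i in gr.instances.values()
        for p, vs in i.assertions.items()
        for v in vs
    }
    assert n_pairs(merged) == n_pairs(g)


def test_restrict_organism_removes_decoy_keeps_match(caplog):
    g = core_graph(
        [
            ("a#yeast", "P1", "RAD9", "559292"),
            ("b#human", "P2", "RAD9A", "9606"),
            ("c#unknown", "P3", "ORF", None),
        ]
    )
    with caplog.at_level("WARNING"):
        removed = restrict_organism(g, "559292")
    assert removed == ["b#human"]
    assert "a#yeast" in g.instances and "c#unknown" in g.instances
    assert any("no taxon" in r.getMessage() for r in caplog.records)


def test_restrict_organism_all_matching_unchanged():
    g = core_graph([("a#1", "P1", None, "559292"), ("a#2", "P2", None, "559292")])
    before = g.fingerprint()
    assert restrict_organism(g, "559292") == []
    assert g.fingerprint() == before


def test_restrict_organism_removes_dangling_roles_and_processes():
    g = core_graph(
        [("a#yeast", "P1", None, "559292"), ("b#human", "P2", None, "9606")]
    )
    role = g.add_instance("r#1", ["tuo:ParticipantRole"], source="r")
    g.assert_value(role, "tuo:playedBy", g.instances["b#human"])
    proc = g.add_instance("i#1", ["tuo:Interaction"], source="r")
    g.assert_value(proc, "tuo:hasParticipant", role)
    keeper_role = g.add_instance("r#2", ["tuo:ParticipantRole"], source="r")
    g.assert_value(keeper_role, "tuo:playedBy", g.instances["a#yeast"])
    removed = restrict_organism(g, "559292")
    assert set(removed) == {"b#human", "r#1", "i#1"}
    # scan oracle: mismatching proteins + their dependents
    g2 = core_graph(
        [("a#yeast", "P1", None, "559292"), ("b#human", "P2", None, "9606")]
    )
    mismatch = [
        i.id
        for i in g2.class_members("tuo:Protein")
        if i.literals("tuo:taxonId") and "559292" not in i.literals("tuo:taxonId")
    ]
    assert set(mismatch) == {"b#human"}
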