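import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbmed.instance_graph import InstanceGraph, Literal
from rbmed.rule_engine import (
    ChainingLimitError,
    Rule,
    RuleParseError,
    SelectQuery,
    apply_rules,
    classify,
    eval_builtin,
    match,
    parse_class_expression,
    parse_defined_classes,
    parse_rule,
    parse_rule_file,
    select,
)

from oracles import binding_set, brute_force_match, random_graph, recursive_satisfies

RAD9_RULE = """
tuo:Protein(?rules:someEntity) ^ tuo:synonym(?rules:someEntity, ?rules:s)
  ^ swrlb:containsIgnoreCase(?rules:s, "rad9")
-> tuo:Rad9(?rules:someEntity)
"""

INTERACTION_QUERY = """
tuo:Rad9(?rules:rad9instance) ^ tuo:plays(?rules:rad9instance, ?rules:participant)
  ^ tuo:hasParticipant(?rules:process, ?rules:participant)
-> sqwrl:select(?rules:rad9instance, ?rules:process)
"""


# -- parsing ----------------------------------------------------------------

def test_parse_rad9_rule_shape():
    rule = parse_rule(RAD9_RULE)
    assert isinstance(rule, Rule)
    assert len(rule.antecedent) == 3
    assert [a.kind for a in rule.antecedent] == ["class", "property", "builtin"]
    assert len(rule.consequent) == 1
    assert rule.consequent[0].predicate == "tuo:Rad9"


def test_parse_interaction_query_projection():
    q = parse_rule(INTERACTION_QUERY)
    assert isinstance(q, SelectQuery)
    assert q.projection == ["rad9instance", "process"]


def test_unicode_connectives_accepted():
    rule = parse_rule('tuo:Protein(?e) ∧ tuo:synonym(?e, ?s) → tuo:Rad9(?e)')
    assert len(rule.antecedent) == 2


def test_unsafe_consequent_variable_rejected():
    with pytest.raises(RuleParseError, match="ghost"):
        parse_rule("tuo:Protein(?e) -> tuo:synonym(?e, ?ghost)")


def test_unregistered_builtin_fails_at_parse_time():
    with pytest.raises(RuleParseError, match="swrlb:frobnicate"):
        parse_rule('tuo:Protein(?e) ^ swrlb:frobnicate(?e, "x") -> tuo:Rad9(?e)')


def test_rule_file_stanzas_and_comments():
    rules = parse_rule_file(
        "# a comment\nrule one:\n  tuo:Protein(?e) -> tuo:Rad9(?e)\n\n"
        "query two:\n  tuo:Rad9(?e) -> sqwrl:select(?e)\n"
    )
    assert [r.id for r in rules] == ["one", "two"]
    assert isinstance(rules[1], SelectQuery)


# -- builtins ---------------------------------------------------------------

@pytest.mark.parametrize(
    "args,expected",
    [(("RAD9 checkpoint protein", "rad9"), True), (("RAD53", "rad9"), False)],
)
def test_contains_ignore_case_examples(args, expected):
    assert eval_builtin("swrlb:containsIgnoreCase", args) is expected
    # the OCR-typo alias is the same builtin
    assert eval_builtin("swrlb:containslgnoreCase", args) is expected


@settings(max_examples=200, derandomize=True)
@given(st.text(max_size=20), st.text(max_size=8))
def test_contains_ignore_case_equals_lowercase_substring(a, b):
    assert eval_builtin("swrlb:containsIgnoreCase", (a, b)) == (b.lower() in a.lower())


# -- matching ---------------------------------------------------------------

@pytest.mark.parametrize("seed", range(6))
def test_match_agrees_with_brute_force(seed):
    g = random_graph(seed, n_instances=12)
    antecedents = [
        parse_rule("A(?x) -> A(?x)").antecedent,
        parse_rule("A(?x) ^ r(?x, ?y) -> A(?x)").antecedent,
        parse_rule("B(?x) ^ p(?x, ?s) ^ swrlb:containsIgnoreCase(?s, \"rad\") -> A(?x)").antecedent,
        parse_rule("r(?x, ?y) ^ r(?y, ?z) -> r(?x, ?z)").antecedent,
    ]
    for ante in antecedents:
        assert binding_set(match(g, ante)) == brute_force_match(g, ante)


def test_match_on_empty_graph():
    g = InstanceGraph()
    g.add_class("A")
    assert match(g, parse_rule("A(?x) -> A(?x)").antecedent) == []


def test_match_honors_subclass_closure():
    g = InstanceGraph()
    g.add_class("Protein")
    g.add_class("Rad9", ["Protein"])
    g.add_instance("s#x", ["Rad9"], source="s")
    bindings = match(g, parse_rule("Protein(?p) -> Rad9(?p)").antecedent)
    assert [b["p"].id for b in bindings] == ["s#x"]


# -- chaining ---------------------------------------------------------------

def chain_graph():
    g = InstanceGraph()
    g.add_class("Protein")
    g.add_class("Rad9", ["Protein"])
    g.add_property("synonym", "data")
    a = g.add_instance("s#a", ["Protein"], source="s")
    g.assert_value(a, "synonym", Literal("RAD9 homolog"))
    b = g.add_instance("s#b", ["Protein"], source="s")
    g.assert_value(b, "synonym", Literal("RAD53"))
    return g


def test_apply_rules_empty_sequence_noop():
    g = chain_graph()
    before = g.fingerprint()
    report = apply_rules(g, [])
    assert len(report) == 0 and g.fingerprint() == before


def test_apply_rules_idempotent_and_monotone():
    g = chain_graph()
    rule = parse_rule(RAD9_RULE.replace("tuo:", "").replace("?rules:", "?"))
    first = apply_rules(g, [rule])
    assert len(first) == 1
    assert "Rad9" in g.instances["s#a"].asserted_classes
    assert "Rad9" not in g.instances["s#b"].asserted_classes
    second = apply_rules(g, [rule])
    assert len(second) == 0


def test_rule_order_does_not_change_fixpoint():
    r1 = parse_rule("Protein(?e) ^ synonym(?e, ?s) ^ swrlb:containsIgnoreCase(?s, \"rad9\") -> Rad9(?e)")
    r2 = parse_rule("Rad9(?e) -> synonym(?e, \"classified\")")
    g1, g2 = chain_graph(), chain_graph()
    apply_rules(g1, [r1, r2])
    apply_rules(g2, [r2, r1])
    assert g1.fingerprint() == g2.fingerprint()


def test_make_individual_guarded_against_duplicates():
    g = chain_graph()
    rule = parse_rule(
        "Protein(?e) -> swrlx:makeOWLThing(?x, ?e) ^ Made(?x) ^ synonym(?x, \"made\")"
    )
    apply_rules(g, [rule])
    made = [i for i in g.instances.values() if i.id.startswith("rule:")]
    assert len(made) == 2  # one per binding, not per round
    before = len(g.instances)
    apply_rules(g, [rule])
    assert len(g.instances) == before  # re-run mints nothing new


def test_runaway_creation_hits_round_bound():
    g = InstanceGraph()
    g.add_class("A")
    g.add_instance("s#seed", ["A"], source="s")
    # each new individual feeds the next round: no fixpoint
    rule = parse_rule("A(?x) -> swrlx:makeOWLThing(?y, ?x) ^ A(?y)")
    with pytest.raises(ChainingLimitError):
        apply_rules(g, [rule], max_rounds=10)


# -- select -----------------------------------------------------------------

def test_select_is_pure_and_deduplicated():
    g = chain_graph()
    apply_rules(g, [parse_rule(
        "Protein(?e) ^ synonym(?e, ?s) ^ swrlb:containsIgnoreCase(?s, \"rad9\") -> Rad9(?e)")])
    before = g.fingerprint()
    q = parse_rule("Rad9(?e) ^ synonym(?e, ?s) -> sqwrl:select(?e)")
    rows = select(g, q)
    assert rows == [("s#a",)]
    assert g.fingerprint() == before


def test_select_empty_graph():
    g = InstanceGraph()
    g.add_class("Rad9")
    q = parse_rule("Rad9(?e) -> sqwrl:select(?e)")
    assert select(g, q) == []


# -- defined-class classification -------------------------------------------

def interaction_graph():
    g = InstanceGraph()
    for c in ("Protein", "Rad9", "Rad53", "Role", "Process"):
        g.add_class(c, ["Protein"] if c in ("Rad9", "Rad53") else [])
    g.add_property("playedBy", "object")
    g.add_property("hasParticipant", "object")
    rad9 = g.add_instance("s#rad9", ["Rad9"], source="s")
    rad53 = g.add_instance("s#rad53", ["Rad53"], source="s")
    r1 = g.add_instance("s#r1", ["Role"], source="s")
    r2 = g.add_instance("s#r2", ["Role"], source="s")
    g.assert_value(r1, "playedBy", rad9)
    g.assert_value(r2, "playedBy", rad53)
    both = g.add_instance("s#int_both", ["Process"], source="s")
    g.assert_value(both, "hasParticipant", r1)
    g.assert_value(both, "hasParticipant", r2)
    lone = g.add_instance("s#int_lone", ["Process"], source="s")
    g.assert_value(lone, "hasParticipant", r1)
    return g


def test_defined_class_membership_and_unsatisfied_conjunct():
    g = interaction_graph()
    expr = parse_class_expression(
        "hasParticipant some (playedBy some Rad9) and hasParticipant some (playedBy some Rad53)"
    )
    classify(g, {"Rad9Rad53Interaction": expr})
    assert "Rad9Rad53Interaction" in g.instances["s#int_both"].asserted_classes
    assert "Rad9Rad53Interaction" not in g.instances["s#int_lone"].asserted_classes


def test_nested_defined_classes_compose_to_fixpoint():
    g = interaction_graph()
    defined = {
        "Rad9Involving": parse_class_expression("hasParticipant some (playedBy some Rad9)"),
        "Meta": parse_class_expression("hasParticipant some (playedBy some Rad9)"),
    }
    report = classify(g, defined)
    assert report.rounds >= 1
    assert "Rad9Involving" in g.instances["s#int_both"].asserted_classes
    assert "Rad9Involving" in g.instances["s#int_lone"].asserted_classes


@pytest.mark.parametrize("seed", range(4))
def test_classify_agrees_with_recursive_evaluation(seed):
    g = random_graph(seed, n_instances=15)
    expr = parse_class_expression("r some (A and r some B)")
    expected = {i.id for i in g.instances.values() if recursive_satisfies(g, i, expr)}
    classify(g, {"Defined": expr})
    assert {i.id for i in g.instances.values() if "Defined" in i.asserted_classes} == expected


def test_defined_class_file_parsing():
    entries = parse_defined_classes(
        "# doc\ndefine tuo:X < tuo:Interaction:\n  tuo:hasParticipant some tuo:Role\n"
    )
    assert len(entries) == 1
    name, parent, expr = entries[0]
    assert name == "tuo:X" and parent == "tuo:Interaction"
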