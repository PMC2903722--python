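# Methods

## The mediation model

`rbmed` integrates heterogeneous molecular data by *materialisation into a
core ontology*: instead of translating queries into each source's schema,
data from every source is converted into a shared instance representation
and copied, by rules, into one semantically homogeneous domain model that
is then queried directly.

The architecture has three layers with strict dependencies:

* **Syntactic layer.** A generic XML→ontology conversion maps every
  distinct element tag to a class, every attribute to a data property
  (`has` + CamelCase), every parent→child nesting to an object property,
  and element text to `hasValue`; one instance is created per element
  occurrence, in document order. The naming convention is this package's
  own (the conversion idea predates it; no published convention exists for
  the property names). The UniProtKB and PSI-MI readers pin their schemas
  from template documents rather than re-deriving them per file — rule
  atoms anchor on class names, which must be stable — and add only two
  positional post-passes the generic conversion cannot express: UniProt's
  first-accession-is-primary convention, and resolution of PSI-MI
  `proteinInteractorRef` attributes into direct object links. Multiple
  files of one format populate one shared schema. BioPAX is RDF already
  and is loaded triple-by-triple with a pinned class/property vocabulary;
  resources typed with an unknown BioPAX class are kept under a generic
  class with a warning.

* **Core layer.** The shipped core schema (`rules/core_schema.txt`, a
  small declarative format) models proteins (with named subclasses for the
  genes of interest), processes/interactions, and the entity/occurrence
  dichotomy — a protein *plays* a participant role; a role is *playedBy*
  one protein — mirrored from the distinction BioPAX draws between
  `protein` and `physicalEntityParticipant` and SBML between species and
  species reference. Nothing in the core vocabulary names a source format,
  so new sources are added by writing rules, not by touching the core.
  The schema covers only what the shipped use cases exercise; a
  comprehensive domain ontology is out of scope by design.

* **Rule layer.** Rules are written in a plain-text rendering of the
  conventional printed form (`Prefix:Name(?var, …)` atoms joined by `^`,
  `->` before the consequent), parsed by a small recursive-descent parser.
  Four builtins ship (`containsIgnoreCase` — also accepted under its
  common OCR misspelling `containslgnoreCase` — `contains`, `equal`,
  `stringEqualIgnoreCase`); unknown builtins fail at parse time. Rule
  safety requires every consequent variable to be antecedent-bound, except
  variables introduced by `swrlx:makeOWLThing`, which mints a new
  individual per (rule id, antecedent binding) with a *deterministic id*.
  That id is the duplicate-individual guard: re-firing a creating rule
  finds its previous individual instead of minting another, which is the
  classic failure mode of naive forward chaining with individual creation.

## Evaluation semantics

Matching is conjunctive with subclass-closed class atoms (a `Protein` atom
matches `Rad9`-classified instances); builtins are evaluated once their
arguments are bound, with atoms reordered internally to make that so.
Forward chaining runs rounds of match-and-assert to fixpoint; assertions
are only added, never retracted, so chaining is monotone, idempotent on
re-run, and its fixpoint is independent of rule order. A configurable
round bound (default 100) aborts with a diagnostic on runaway individual
creation. Select queries evaluate over the same matcher but project
bindings into rows — de-duplicated, deterministically ordered — and the
graph is bit-identical before and after (checked by fingerprint in the
tests). Defined classes (named class / intersection / `some` restriction)
are evaluated by direct recursion over property assertions and iterated to
fixpoint so nested defined classes compose; cyclic definitions without a
fixpoint hit the same round bound.

## Reconciliation and organism restriction

Instances from different sources denoting one protein are declared
equivalent automatically by shared keys — the historical manual
`owl:sameAs` step, automated the way key-based identity (hasKey) would do
it. Default keys: shared accession; fallback, exact case-insensitive
primary name within one taxon. The partition is the transitive closure of
pairwise key sharing (computed as connected components), with one guard:
instances sharing a key but carrying disjoint taxon sets are *not* merged
and a conflict warning is logged. Merging collapses each set onto the
lexicographically smallest member id, unions classes, assertions
(deduplicated) and provenance labels, and rewires all object references —
so the result is independent of instance insertion order, and every
pre-merge assertion remains recoverable from its canonical instance.
Two source records describing one concept without a shared key are
deliberately *represented rather than reconciled*.

Organism restriction removes proteins whose taxon assertions exclude the
target taxon, then roles and processes left dangling by those removals.
Proteins with no taxon assertion are retained with a warning — absence of
evidence is not treated as mismatch.

## Export to SBML

Export is rule-driven: export rules assert `mfo:` facts (cross-reference
links, SBO term, display name) on core entities, and the annotator renders
only those facts onto model species. Species↔entity mapping prefers an
existing UniProtKB MIRIAM annotation matching an entity accession, falling
back to case-insensitive name/synonym equality; many species may map to
one entity (active/inactive forms), a species matching two entities is an
error rather than a silent choice, and placeholder species simply stay
unmapped. Annotation writing is strictly additive and idempotent: URIs use
`urn:miriam:<datatype>:<id>` (the classic URN scheme; an
identifiers.org style is a flag away) with
qualifier `bqbiol:is` by default, deduplicated against what the species
already carries; SBO terms and names are set only when absent; nothing is
ever modified or removed. Database labels are mapped to URN datatype
tokens through a shipped registry (`rules/miriam_registry.yaml`);
unregistered labels are skipped with a warning rather than emitted as
malformed URNs. `speciesType` is not used — annotations target species
attributes directly.

Classified interactions become model extensions conservatively: if a
reaction already pairs a focus-mapped species with a partner-mapped
species the interaction is recorded as *confirmed* and never duplicated;
otherwise a skeleton reaction is added (two reactants, no products, no
kinetic law, no parameters), creating the partner species from its entity
(with copied annotations) only when no species maps to it. The skeleton
uses the first focus species in model order — a deterministic tie-break
between the active/inactive forms. Placeholder identification is a
reported *candidate*, never a substitution: an unmapped species in a
reaction with the focus protein, whose id carries a kinase-style suffix,
is matched against newly proposed partners annotated as kinases, and only
a unique match is reported. This heuristic stands in for a curator's
judgement and is intentionally narrow.

Every change is recorded in a `ModelDelta` whose re-application to the
pristine input reproduces the output model — the audit object for a
pipeline that, by default, writes no tool provenance into the SBML itself
(a `--provenance-notes` flag adds tool/version into the model notes).
Rule firings are instead logged at debug level with rule id and assertion.

## The fixture corpus

The generator emulates the study conditions, not live databases: five
yeast checkpoint proteins (RAD9 P14737 with secondary accession D6VTR8,
RAD53 P22216, CHK1 P38147, MEC1 P38111, RAD17 P48581), a BioGRID-style
interaction pattern (RAD9–RAD53, RAD9–MEC1, RAD9–RAD17), a Pathway
Commons-style pattern (RAD9–RAD53, RAD9–CHK1), and a toy
telomere-uncapping model with two RAD9 species (each carrying the single
pre-existing UniProtKB reference), reactions with RAD53, CHK1 and the
placeholders Rad9Kin/ExoX, and MEC1/RAD17 present as species (MEC1 in a
non-RAD9 reaction). Decoys test one mechanism each: a human RAD9A entry
(taxon 9606) that matches the `rad9` name rules but no reconciliation key,
removed only by organism restriction; a RAD53–CDC28 interaction caught by
no defined class. Default generation uses no randomness and regenerates
checksum-identical; a seed adds extra noise records for stress tests.

Two details of the scenario are not determined by any shipped input and
are fixed here as documented choices: the SBO term placed on the RAD9 species
(`SBO:0000252`, polypeptide chain — the original value is unknown) and the
split of the five exported cross-references across IntAct ×2 (EBI-14826,
EBI-4641958), UniProtKB ×1 (D6VTR8), SGD ×1 (S000002625) and Pathway
Commons ×1 (CPATH-34926). The BioGRID identifier xrefs are deliberately
left out of the MIRIAM registry so the skip-with-warning path runs in the
default pipeline. The toy model's layout (ids, compartment) is synthetic —
constrained by the documented facts, not a copy of any deposited model.

What passing tests show: the *mechanics* of mediation — conversion, rule
chaining, reconciliation, restriction, classification, additive export —
are correct end-to-end on a corpus whose expected outcome is fixed by
construction. What they do not show: behaviour against live database
content (scale, schema drift, >10² interactions per query, conflicting
taxon annotations in the wild), PSI-MI 2.5 / BioPAX level 3 dialects, or
rule sets beyond the shipped ones.

## Numerical and design choices

* Iteration everywhere follows insertion order; serialized N-Triples are
  sorted line-wise, so graph fingerprints are byte-stable.
* Literals are text payloads with an optional kind tag; taxon ids are
  compared as strings. No typed-literal arithmetic is needed or provided.
* All properties are multi-valued; no functional-property enforcement
  (synonyms and cross-references require it, and nothing demands it).
* Negation is not supported; "already in the model" filtering is an
  explicit set intersection in the annotator, keeping the rule language at
  plain conjunctive expressivity.
* No OWL reasoner is embedded: no disjointness, cardinality, or
  consistency checking. The classifier handles exactly the expression
  forms the defined classes use (named / intersection / existential).
* The round bound (100) is far above the 2–3 rounds the shipped rules
  need; it exists to turn non-termination into a diagnostic.
* Problem sizes in tests: randomized oracle graphs use ≤40 instances
  (brute-force enumeration is exponential in variable count); the corpus
  pipeline runs in well under a second, so the full suite stays fast.

## Known limitations

* The rule grammar covers the printed-rule subset (class/property/builtin
  atoms, select, guarded creation) — no arbitrary SWRL builtins library,
  no SQWRL collection operators.
* BioPAX coverage is the level-2 subset the use cases touch.
* Reconciliation trusts keys: a wrong shared accession merges wrongly;
  only taxon conflicts are guarded.
* The candidate-identity heuristic is narrow by intent and will not
  propose identities for placeholders without a kinase-style name.
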