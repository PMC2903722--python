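# Import rules: UniProtKB syntactic ontology -> core ontology.
# The antecedents walk the element structure of the entry dialect
# (up:Entry -> up:Protein -> up:RecommendedName -> up:FullName ...);
# the consequents speak only core (tuo:) vocabulary.

rule up-protein:
  up:Entry(?e) -> tuo:Protein(?e)

rule up-accession:
  up:Entry(?e) ^ up:hasPrimaryAccession(?e, ?acc) -> tuo:accession(?e, ?acc)

rule up-primary-name:
  up:Entry(?e) ^ up:hasProtein(?e, ?p) ^ up:hasRecommendedName(?p, ?rn)
    ^ up:hasFullName(?rn, ?fn) ^ up:hasValue(?fn, ?n)
  -> tuo:primaryName(?e, ?n) ^ tuo:synonym(?e, ?n)

rule up-alt-name:
  up:Entry(?e) ^ up:hasProtein(?e, ?p) ^ up:hasAlternativeName(?p, ?an)
    ^ up:hasFullName(?an, ?fn) ^ up:hasValue(?fn, ?n)
  -> tuo:synonym(?e, ?n)

rule up-gene-name:
  up:Entry(?e) ^ up:hasGene(?e, ?g) ^ up:hasName(?g, ?gn) ^ up:hasValue(?gn, ?n)
  -> tuo:synonym(?e, ?n)

rule up-taxon:
  up:Entry(?e) ^ up:hasOrganism(?e, ?o) ^ up:hasDbReference(?o, ?r)
    ^ up:hasType(?r, "NCBI Taxonomy") ^ up:hasId(?r, ?t)
  -> tuo:taxonId(?e, ?t)

# entry-level dbReference elements (the organism's taxon reference hangs
# under up:Organism, so it is not matched here)
rule up-xref:
  up:Entry(?e) ^ up:hasDbReference(?e, ?r) ^ up:hasType(?r, ?db) ^ up:hasId(?r, ?id)
  -> tuo:CrossReference(?r) ^ tuo:databaseName(?r, ?db) ^ tuo:databaseId(?r, ?id)
     ^ tuo:hasCrossReference(?e, ?r)

# the entry itself is a database record: mint a cross-reference individual
# for its primary and secondary accessions (guarded individual creation)
rule up-self-xref:
  up:Entry(?e) ^ up:hasPrimaryAccession(?e, ?acc)
  -> swrlx:makeOWLThing(?x, ?e) ^ tuo:CrossReference(?x)
     ^ tuo:databaseName(?x, "UniProtKB") ^ tuo:databaseId(?x, ?acc)
     ^ tuo:hasCrossReference(?e, ?x)

rule up-secondary-xref:
  up:Entry(?e) ^ up:hasSecondaryAccession(?e, ?acc)
  -> swrlx:makeOWLThing(?x, ?e) ^ tuo:CrossReference(?x)
     ^ tuo:databaseName(?x, "UniProtKB") ^ tuo:databaseId(?x, ?acc)
     ^ tuo:hasCrossReference(?e, ?x)

rule up-compartment:
  up:Entry(?e) ^ up:hasComment(?e, ?c) ^ up:hasType(?c, "subcellular location")
    ^ up:hasSubcellularLocation(?c, ?sl) ^ up:hasLocation(?sl, ?loc) ^ up:hasValue(?loc, ?n)
  -> swrlx:makeOWLThing(?comp, ?loc) ^ tuo:Compartment(?comp)
     ^ tuo:primaryName(?comp, ?n) ^ tuo:locatedIn(?e, ?comp)
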