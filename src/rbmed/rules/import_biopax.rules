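# Import rules: BioPAX level-2 ontology (Pathway Commons) -> core.
# BioPAX distinguishes the entity (bp:protein) from its occurrence in an
# interaction (bp:physicalEntityParticipant); the core mirrors this with
# tuo:Protein vs tuo:ParticipantRole.

rule bp-protein:
  bp:protein(?p) -> tuo:Protein(?p)

rule bp-name:
  bp:protein(?p) ^ bp:NAME(?p, ?n) -> tuo:primaryName(?p, ?n) ^ tuo:synonym(?p, ?n)

rule bp-synonym:
  bp:protein(?p) ^ bp:SYNONYMS(?p, ?s) -> tuo:synonym(?p, ?s)

rule bp-accession:
  bp:protein(?p) ^ bp:XREF(?p, ?x) ^ bp:unificationXref(?x)
    ^ bp:DB(?x, "UniProt") ^ bp:ID(?x, ?acc)
  -> tuo:accession(?p, ?acc)

rule bp-xref:
  bp:protein(?p) ^ bp:XREF(?p, ?x) ^ bp:DB(?x, ?db) ^ bp:ID(?x, ?id)
  -> tuo:CrossReference(?x) ^ tuo:databaseName(?x, ?db) ^ tuo:databaseId(?x, ?id)
     ^ tuo:hasCrossReference(?p, ?x)

rule bp-taxon:
  bp:protein(?p) ^ bp:ORGANISM(?p, ?o) ^ bp:TAXON-XREF(?o, ?tx) ^ bp:ID(?tx, ?t)
  -> tuo:taxonId(?p, ?t)

rule bp-interaction:
  bp:physicalInteraction(?i) -> tuo:Interaction(?i)

rule bp-participant:
  bp:physicalInteraction(?i) ^ bp:PARTICIPANTS(?i, ?pep)
  -> tuo:ParticipantRole(?pep) ^ tuo:hasParticipant(?i, ?pep)

rule bp-played-by:
  bp:physicalEntityParticipant(?pep) ^ bp:PHYSICAL-ENTITY(?pep, ?p)
  -> tuo:playedBy(?pep, ?p) ^ tuo:plays(?p, ?pep)
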