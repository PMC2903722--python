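# Import rules: PSI-MI 1.0 syntactic ontology (BioGRID exports) -> core.

rule psi-protein:
  psi:ProteinInteractor(?p) -> tuo:Protein(?p)

rule psi-short-label:
  psi:ProteinInteractor(?p) ^ psi:hasNames(?p, ?ns) ^ psi:hasShortLabel(?ns, ?sl)
    ^ psi:hasValue(?sl, ?n)
  -> tuo:primaryName(?p, ?n) ^ tuo:synonym(?p, ?n)

rule psi-full-name:
  psi:ProteinInteractor(?p) ^ psi:hasNames(?p, ?ns) ^ psi:hasFullName(?ns, ?fn)
    ^ psi:hasValue(?fn, ?n)
  -> tuo:synonym(?p, ?n)

rule psi-taxon:
  psi:ProteinInteractor(?p) ^ psi:hasOrganism(?p, ?o) ^ psi:hasNcbiTaxId(?o, ?t)
  -> tuo:taxonId(?p, ?t)

rule psi-accession:
  psi:ProteinInteractor(?p) ^ psi:hasXref(?p, ?x) ^ psi:hasPrimaryRef(?x, ?r)
    ^ psi:hasDb(?r, "uniprotkb") ^ psi:hasId(?r, ?acc)
  -> tuo:accession(?p, ?acc)

rule psi-xref-primary:
  psi:ProteinInteractor(?p) ^ psi:hasXref(?p, ?x) ^ psi:hasPrimaryRef(?x, ?r)
    ^ psi:hasDb(?r, ?db) ^ psi:hasId(?r, ?id)
  -> tuo:CrossReference(?r) ^ tuo:databaseName(?r, ?db) ^ tuo:databaseId(?r, ?id)
     ^ tuo:hasCrossReference(?p, ?r)

rule psi-xref-secondary:
  psi:ProteinInteractor(?p) ^ psi:hasXref(?p, ?x) ^ psi:hasSecondaryRef(?x, ?r)
    ^ psi:hasDb(?r, ?db) ^ psi:hasId(?r, ?id)
  -> tuo:CrossReference(?r) ^ tuo:databaseName(?r, ?db) ^ tuo:databaseId(?r, ?id)
     ^ tuo:hasCrossReference(?p, ?r)

rule psi-interaction:
  psi:Interaction(?i) -> tuo:Interaction(?i)

rule psi-participant:
  psi:Interaction(?i) ^ psi:hasParticipantList(?i, ?pl) ^ psi:hasProteinParticipant(?pl, ?pt)
  -> tuo:ParticipantRole(?pt) ^ tuo:hasParticipant(?i, ?pt)

rule psi-played-by:
  psi:ProteinParticipant(?pt) ^ psi:refersTo(?pt, ?p)
  -> tuo:playedBy(?pt, ?p) ^ tuo:plays(?p, ?pt)
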