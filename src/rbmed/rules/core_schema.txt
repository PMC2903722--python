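# Core ("telomere") domain ontology schema.
# The vocabulary is source-format independent: nothing here names UniProt,
# PSI-MI, BioPAX or SBML. New use cases extend this file (e.g. add a named
# protein subclass) rather than code.

class tuo:Entity
class tuo:Protein < tuo:Entity
class tuo:Rad9 < tuo:Protein
class tuo:Rad53 < tuo:Protein
class tuo:Chk1 < tuo:Protein
class tuo:Mec1 < tuo:Protein
class tuo:Rad17 < tuo:Protein
class tuo:Process
class tuo:Interaction < tuo:Process
class tuo:ParticipantRole
class tuo:Organism
class tuo:CrossReference
class tuo:Compartment

# a protein *plays* a participant role in a process; the role is *playedBy*
# exactly one protein — the entity/occurrence dichotomy
objprop tuo:plays domain tuo:Protein range tuo:ParticipantRole inverse tuo:playedBy
objprop tuo:playedBy domain tuo:ParticipantRole range tuo:Protein inverse tuo:plays
objprop tuo:hasParticipant domain tuo:Process range tuo:ParticipantRole
objprop tuo:hasCrossReference range tuo:CrossReference
objprop tuo:fromOrganism range tuo:Organism
objprop tuo:locatedIn range tuo:Compartment

dataprop tuo:synonym
dataprop tuo:primaryName
dataprop tuo:accession
dataprop tuo:taxonId
dataprop tuo:databaseName
dataprop tuo:databaseId
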