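# Export rules: core ontology -> model-format (mfo:) facts consumed by the
# SBML annotator. Dedicated rules create MIRIAM cross-references and SBO
# terms; the annotator renders mfo: facts onto mapped species and never
# writes anything the rules did not derive.

rule mfo-miriam:
  tuo:Protein(?p) ^ tuo:hasCrossReference(?p, ?x) -> mfo:annotatedWith(?p, ?x)

# proteins map onto material-entity species; the polypeptide-chain term
rule mfo-sbo:
  tuo:Protein(?p) -> mfo:hasSboTerm(?p, "SBO:0000252")

rule mfo-name:
  tuo:Protein(?p) ^ tuo:primaryName(?p, ?n) -> mfo:hasName(?p, ?n)
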