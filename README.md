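# rbmed — rule-based mediation for SBML model annotation

Quantitative systems-biology models written in SBML are only as useful as
their biological annotation, yet annotating even a small model means
reconciling knowledge scattered across databases that disagree in both
format and meaning: protein records in UniProtKB XML, interaction exports
in PSI-MI XML, pathway data in BioPAX RDF. `rbmed` implements **rule-based
mediation**, a semantic data-integration architecture for model curators
and tool builders, with three separated layers:

1. **Syntactic ontologies** — each data format is converted mechanically
   into an ontology whose classes mirror the format's element/attribute
   structure and whose instances carry the data, isolating syntactic
   variability (BioPAX, already RDF/OWL, is loaded natively);
2. **A core domain ontology** — a compact, format-independent model of the
   biology under study (proteins and named subclasses, processes,
   participant roles with `plays`/`playedBy`, organisms, cross-references);
3. **Mapping rules** — forward-chained rules of the form
   `antecedent → consequent` over ontology atoms, e.g.

   ```
   tuo:Protein(?someEntity) ^ tuo:synonym(?someEntity, ?s)
     ^ swrlb:containsIgnoreCase(?s, "rad9")
   -> tuo:Rad9(?someEntity)
   ```

   which populate the core ontology from the syntactic ones, classify the
   proteins of interest, and drive the export.

On top of the integrated core graph, instances denoting the same protein
are reconciled by shared keys (UniProtKB accession, falling back to exact
primary name within one taxon), restricted to the target organism, and
interactions are picked out by *defined classes* — class expressions such
as

```
tuo:hasParticipant some (tuo:playedBy some tuo:Rad9)
  and tuo:hasParticipant some (tuo:playedBy some tuo:Rad53)
```

whose members are inferred, never asserted. The result is written back
onto an SBML Level 2 model as MIRIAM annotations
(`urn:miriam:<datatype>:<id>` with biology qualifier `is`), SBO terms,
display names, new species, and *skeleton reactions* (reactants only, no
kinetics) left as placeholders for manual curation. Select-style queries
(`sqwrl:select`) display results without ever storing them back.

A packaged fixture generator emulates the study system — the yeast
DNA-damage checkpoint around RAD9 (P14737) with partners RAD53, CHK1,
MEC1, RAD17, and a toy telomere-uncapping model containing two RAD9
species and the placeholder species `Rad9Kin` and `ExoX` — so the whole
pipeline runs offline and deterministically.

## Worked example

```sh
rbmed fixtures --out demo
rbmed run --config demo/pipeline.yaml
```

prints

```
annotated model -> demo/annotated_model.xml
delta report   -> demo/delta.json
{
  "annotations": 18,
  "candidates": 1,
  "confirmed": 2,
  "names": 4,
  "reactions": 2,
  "sbo_terms": 6,
  "species": 0
}
```

Reading the delta: 18 MIRIAM annotations were added across the model's
species — each of the two RAD9 species (active and inactive forms of one
protein) gained 5 new cross-references drawn from IntAct, UniProtKB, SGD
and Pathway Commons, on top of its pre-existing confirmed UniProtKB
reference; 6 species received an SBO term and 4 a display name. Two
modelled interactions (RAD9–RAD53, RAD9–CHK1) were *confirmed* against the
integrated sources and deliberately not duplicated; two newly discovered
ones (RAD9–MEC1, RAD9–RAD17) were added as skeleton reactions. One
placeholder, `Rad9Kin`, received a candidate identity — MEC1, a kinase the
interaction data pairs with RAD9 — reported for the modeller's judgement,
never substituted automatically.

`rbmed query --config demo/pipeline.yaml` runs the non-materializing
select query and lists the five (RAD9 instance, process) rows behind the
interaction analysis; `rbmed convert`, `rbmed integrate` and
`rbmed annotate` expose the individual stages. Every stage writes audit
artifacts (sorted N-Triples graphs, JSON reports) under the corpus
directory.

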