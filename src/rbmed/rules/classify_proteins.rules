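# Protein classification rules: collect core proteins whose synonyms match
# each gene of interest and declare them members of the named subclass.

rule classify-rad9:
  tuo:Protein(?someEntity) ^ tuo:synonym(?someEntity, ?s)
    ^ swrlb:containsIgnoreCase(?s, "rad9")
  -> tuo:Rad9(?someEntity)

rule classify-rad53:
  tuo:Protein(?someEntity) ^ tuo:synonym(?someEntity, ?s)
    ^ swrlb:containsIgnoreCase(?s, "rad53")
  -> tuo:Rad53(?someEntity)

rule classify-chk1:
  tuo:Protein(?someEntity) ^ tuo:synonym(?someEntity, ?s)
    ^ swrlb:containsIgnoreCase(?s, "chk1")
  -> tuo:Chk1(?someEntity)

rule classify-mec1:
  tuo:Protein(?someEntity) ^ tuo:synonym(?someEntity, ?s)
    ^ swrlb:containsIgnoreCase(?s, "mec1")
  -> tuo:Mec1(?someEntity)

rule classify-rad17:
  tuo:Protein(?someEntity) ^ tuo:synonym(?someEntity, ?s)
    ^ swrlb:containsIgnoreCase(?s, "rad17")
  -> tuo:Rad17(?someEntity)
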