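# Database label -> MIRIAM datatype token (urn:miriam:<token>:<id>).
# Lookup is case/space-insensitive, so one entry per database suffices.
# A cross-reference naming a database absent from this table is skipped
# with a warning rather than emitted as a malformed URN.
UniProt: uniprot
UniProtKB: uniprot
IntAct: intact
SGD: sgd
Pathway Commons: pathwaycommons
NCBI Taxonomy: taxonomy
SBO: biomodels.sbo
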