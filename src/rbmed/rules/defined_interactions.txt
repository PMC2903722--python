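# Defined interaction classes: a process is a member when it has one
# participant played by the focus protein and one played by the partner.
# Membership is inferred, never asserted by hand.

define tuo:Rad9Rad53Interaction < tuo:Interaction:
  tuo:hasParticipant some (tuo:playedBy some tuo:Rad9)
  and tuo:hasParticipant some (tuo:playedBy some tuo:Rad53)

define tuo:Rad9Chk1Interaction < tuo:Interaction:
  tuo:hasParticipant some (tuo:playedBy some tuo:Rad9)
  and tuo:hasParticipant some (tuo:playedBy some tuo:Chk1)

define tuo:Rad9Mec1Interaction < tuo:Interaction:
  tuo:hasParticipant some (tuo:playedBy some tuo:Rad9)
  and tuo:hasParticipant some (tuo:playedBy some tuo:Mec1)

define tuo:Rad9Rad17Interaction < tuo:Interaction:
  tuo:hasParticipant some (tuo:playedBy some tuo:Rad9)
  and tuo:hasParticipant some (tuo:playedBy some tuo:Rad17)
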