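# SQWRL-style queries: results are presented, never stored in the graph.

# every process in which a Rad9 protein plays a participant role
query rad9-processes:
  tuo:Rad9(?rad9instance) ^ tuo:plays(?rad9instance, ?participant)
    ^ tuo:hasParticipant(?process, ?participant)
  -> sqwrl:select(?rad9instance, ?process)
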