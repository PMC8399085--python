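# Editor presets: SpCas9-coupled adenine base editors.
# window is the 1-based activity-window span counted from the protospacer
# 5' (PAM-distal) end; conversion is [source, product].
spcas9-abemax:
  pam: NGG
  protospacer_len: 20
  window: [4, 8]
  conversion: [A, G]
spcas9-abe7.10:
  pam: NGG
  protospacer_len: 20
  window: [4, 8]
  conversion: [A, G]
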