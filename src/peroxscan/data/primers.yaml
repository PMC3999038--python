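# Degenerate primer pairs for fungal secretory peroxidase transcript
# surveys.  Sequences are 5'->3' IUPAC with inosine (I); size windows
# bracket the expected gel sizes (~400 bp class II, ~210 bp UPO,
# ~400 bp DyP), primer-inclusive.
CLASS_II:
  forward: {name: peroxiF2, seq: GGYGGIGGIGCBGAYGGYTC}
  reverse: {name: peroxiR2, seq: GGIGTIGARTCGAABGG}
  size_window: [300, 500]
UPO:
  forward: {name: APO_65F, seq: AAYGCIATGGCNAAYCAYGG}
  reverse: {name: APO_130R, seq: GCRTCRTGYTCIATNCC}
  size_window: [150, 280]
DYP:
  forward: {name: DyP360F, seq: TGYCCITTYGCIGCNCAYAT, motif: CPFAAHI}
  reverse: {name: DyP485R, seq: RAARAARTAYTCICCNCC, motif: GGEYFF}
  size_window: [300, 500]
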