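# Default mechanism lexicon: lowercase word stems matched as token prefixes.
# Seeded with canonical discriminating words for each mechanism category
# (deficiency for loss, neomorphic/activation for gain) plus a documented
# set of common OMIM-style phrasing stems. Users can supply their own file
# with the same structure.
loss:
  - deficien        # deficiency, deficient
  - loss
  - inactivat       # inactivation, inactivating
  - absen           # absent, absence
  - truncat         # truncation, truncating
  - "null"            # quoted: bare null is a YAML literal
  - haploinsufficien
  - nonsense
  - frameshift
  - hypomorph
gain:
  - neomorph        # neomorphic
  - activat         # activation, activating (constitutive activation)
  - gain
  - overexpress
  - hypermorph
  - constitutive
  - amplificat
neutral:
  - translocat      # translocation
  - chimeric
  - chimaeric
  - fusion
  - rearrangement
  - inversion
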