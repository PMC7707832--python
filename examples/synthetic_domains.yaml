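# Domain map for assemblies produced by `igageom synth bent-assembly`:
# one chain per pseudo-Fc (A and C), pseudo-JC on chain J.
domains:
  Fc_AB:
    ranges:
      - {chain: A, first: 237, last: 445}
  Fc_AB_CH2:
    ranges:
      - {chain: A, first: 237, last: 341}
  Fc_AB_CH3:
    ranges:
      - {chain: A, first: 342, last: 445}
  Fc_CD:
    ranges:
      - {chain: C, first: 237, last: 445}
  Fc_CD_CH2:
    ranges:
      - {chain: C, first: 237, last: 341}
  Fc_CD_CH3:
    ranges:
      - {chain: C, first: 342, last: 445}
  JC:
    ranges:
      - {chain: J, first: 1, last: 30}
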