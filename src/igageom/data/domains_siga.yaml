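# Default domain map for the deposited mouse SIgA/dIgA models.
# Heavy chains carry IDs A-D, the joining chain is J, secretory component S.
# Residue ranges use author numbering; SC domain boundaries are approximate
# (Ig-like domain limits) -- verify against your local coordinate files and
# override with your own config if the deposition differs.
domains:
  Fc_AB:
    ranges:
      - {chain: A, first: 237, last: 445}
      - {chain: B, first: 237, last: 445}
  Fc_CD:
    ranges:
      - {chain: C, first: 237, last: 445}
      - {chain: D, first: 237, last: 445}
  Fc_AB_CH2:
    ranges:
      - {chain: A, first: 237, last: 341}
      - {chain: B, first: 237, last: 341}
  Fc_AB_CH3:
    ranges:
      - {chain: A, first: 342, last: 445}
      - {chain: B, first: 342, last: 445}
  Fc_CD_CH2:
    ranges:
      - {chain: C, first: 237, last: 341}
      - {chain: D, first: 237, last: 341}
  Fc_CD_CH3:
    ranges:
      - {chain: C, first: 342, last: 445}
      - {chain: D, first: 342, last: 445}
  Tp_A:
    ranges:
      - {chain: A, first: 446, last: 467}
  Tp_B:
    ranges:
      - {chain: B, first: 446, last: 467}
  Tp_C:
    ranges:
      - {chain: C, first: 446, last: 467}
  Tp_D:
    ranges:
      - {chain: D, first: 446, last: 467}
  JC:
    ranges:
      - {chain: J, first: 1, last: 137}
  SC:
    ranges:
      - {chain: S, first: 1, last: 567}
  SC_D1:
    ranges:
      - {chain: S, first: 1, last: 115}
  SC_D2:
    ranges:
      - {chain: S, first: 116, last: 224}
  SC_D3:
    ranges:
      - {chain: S, first: 225, last: 332}
  SC_D4:
    ranges:
      - {chain: S, first: 333, last: 427}
  SC_D5:
    ranges:
      - {chain: S, first: 428, last: 545}
  dIgA_core:
    ranges:
      - {chain: A, first: 237, last: 467}
      - {chain: B, first: 237, last: 467}
      - {chain: C, first: 237, last: 467}
      - {chain: D, first: 237, last: 467}
      - {chain: J, first: 1, last: 137}
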