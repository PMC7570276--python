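# Building-block registry for GIPC assembly.
#
# Schema (version 1):
#   atomic_masses: element symbol -> monoisotopic mass (Da, CODATA/IUPAC)
#   particles:    proton / electron masses used in adduct arithmetic
#   blocks:       name -> {formula: <Hill-style string or element map>, role: <tag>}
#                 Residue formulas are the dehydrated (in-chain) forms.
#   r1_deltas:    terminal-hexose substituent deltas as signed element maps
#                 (OH is the reference state; NH2 swaps O for NH; NAc adds acetyl)
#
# New residues (e.g. pentose for the B-F series) are additions here, not code changes.
version: 1

atomic_masses:
  H: 1.00782503207
  C: 12.0
  N: 14.0030740048
  O: 15.99491461956
  P: 30.97376163
  Na: 22.9897692809

particles:
  proton: 1.00727646688
  electron: 0.00054857991

blocks:
  Hex:       {formula: C6H10O5, role: glycan_residue}     # hexose residue
  HexA:      {formula: C6H8O6,  role: glycan_residue}     # hexuronic acid residue
  Pen:       {formula: C5H8O4,  role: glycan_residue}     # pentose residue (B-F series)
  inositol:  {formula: C6H12O6, role: core}
  HPO3:      {formula: HPO3,    role: core}
  H2O:       {formula: H2O,     role: small}
  CO2:       {formula: CO2,     role: small}
  Hexose:    {formula: C6H12O6, role: neutral_loss}       # terminal hexose incl. glycosidic O
  acetyl:    {formula: C2H2O,   role: modification}

r1_deltas:
  OH:  {}
  NH2: {O: -1, N: 1, H: 1}
  NAc: {N: 1, H: 3, C: 2}   # -O +NH +C2H2O: net oxygen zero
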