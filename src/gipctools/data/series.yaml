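# GIPC glycan series definitions.
#
# Schema (version 1):
#   series: id -> {residues: [block names beyond the inositol-phosphate core,
#                             core-proximal first], r1_terminal: bool}
#
# The terminal (last) residue carries the R1 substituent when r1_terminal is true.
# Series 0 is the bare IPC core. Only series confirmed by diagnostic fragments are
# active; B-F head-group compositions vary between plants and are left as stubs to
# be filled from structural evidence before use.
version: 1

series:
  "0": {residues: [], r1_terminal: false}
  "A": {residues: [HexA, Hex], r1_terminal: true}
  # Unconfirmed stubs -- uncomment and verify residue order before use:
  # "B": {residues: [HexA, Hex, Hex], r1_terminal: true}
  # "C": {residues: [HexA, Hex, Hex, Hex], r1_terminal: true}
  # "D": {residues: [HexA, Hex, Pen, Hex], r1_terminal: true}
  # "E": {residues: [HexA, Hex, Pen, Pen, Hex], r1_terminal: true}
  # "F": {residues: [HexA, Hex, Pen, Pen, Pen, Hex], r1_terminal: true}
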