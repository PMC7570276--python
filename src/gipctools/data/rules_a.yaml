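# Decision rule set for A-series GIPCs (and the series-0 IPC core).
#
# Schema (version 1):
#   fragments: polarity -> name -> recipe
#     recipe:
#       components: list of building-block names or context tokens
#                   (GLYCAN_HEAD = glycan residues + inositol + HPO3 + R1 delta;
#                    CERAMIDE; LCB)
#       losses:     list of building-block names subtracted as neutrals; the
#                   token TERMINAL_HEXOSE means hexose + the candidate's R1 delta
#       ionize:     "-H" (deprotonate), "+H" (protonate), "+Na" (sodiate)
#       requires:   optional gate: r1_bearing | resolved_lcb | trihydroxy_lcb
#     Fragments whose components mention LCB exist only for resolved ceramides.
#   fragment_rules: polarity -> list of {fragment, mandatory}
#   evidence: per polarity, the fragment names establishing each evidence class
#   intensity_rules: optional relations between matched fragments; disabled by
#     default (instrument- and energy-dependent; tune before enabling)
#   tolerances: MS2 peak-match tolerance (ppm with an absolute floor in Da)
version: 1

tolerances:
  ms2_ppm: 10.0
  ms2_da_floor: 0.005

fragments:
  negative:
    PO3:                {components: [HPO3], ionize: "-H"}
    H2PO4:              {components: [HPO3, H2O], ionize: "-H"}
    IP:                 {components: [inositol, HPO3], ionize: "-H"}
    IP-H2O:             {components: [inositol, HPO3], losses: [H2O], ionize: "-H"}
    C3PO3:              {components: [GLYCAN_HEAD], ionize: "-H", requires: r1_bearing}
    # TERMINAL_HEXOSE is the terminal hexose incl. its R1 substituent, so the
    # C1-loss family is R1-independent (shared by exact-mass isobar classes).
    C3PO3-C1:           {components: [GLYCAN_HEAD], losses: [TERMINAL_HEXOSE], ionize: "-H", requires: r1_bearing}
    C3PO3-C1-CO2:       {components: [GLYCAN_HEAD], losses: [TERMINAL_HEXOSE, CO2], ionize: "-H", requires: r1_bearing}
    C3PO3-C1-CO2-H2O:   {components: [GLYCAN_HEAD], losses: [TERMINAL_HEXOSE, CO2, H2O], ionize: "-H", requires: r1_bearing}
    Z0PO3:              {components: [CERAMIDE, HPO3], losses: [H2O], ionize: "-H"}
    Y1-H:               {components: [CERAMIDE, HPO3, inositol], losses: [H2O], ionize: "-H"}
  positive:
    IP+:                {components: [inositol, HPO3], ionize: "+H"}
    IP+Na:              {components: [inositol, HPO3], ionize: "+Na"}
    W:                  {components: [LCB], losses: [H2O], ionize: "+H", requires: resolved_lcb}
    W-H2O:              {components: [LCB], losses: [H2O, H2O], ionize: "+H", requires: resolved_lcb}
    W-2H2O:             {components: [LCB], losses: [H2O, H2O, H2O], ionize: "+H", requires: trihydroxy_lcb}
    Z0:                 {components: [CERAMIDE], losses: [H2O], ionize: "+H"}
    Z0-H2O:             {components: [CERAMIDE], losses: [H2O, H2O], ionize: "+H"}

fragment_rules:
  negative:
    - {fragment: IP, mandatory: true}
    - {fragment: IP-H2O, mandatory: true}
    - {fragment: PO3, mandatory: false}
    - {fragment: H2PO4, mandatory: false}
    - {fragment: C3PO3, mandatory: false}
    - {fragment: C3PO3-C1, mandatory: false}
    - {fragment: C3PO3-C1-CO2, mandatory: false}
    - {fragment: C3PO3-C1-CO2-H2O, mandatory: false}
    - {fragment: Z0PO3, mandatory: false}
    - {fragment: Y1-H, mandatory: false}
  positive:
    - {fragment: IP+, mandatory: false}
    - {fragment: IP+Na, mandatory: false}
    - {fragment: W, mandatory: false}
    - {fragment: W-H2O, mandatory: false}
    - {fragment: W-2H2O, mandatory: false}
    - {fragment: Z0, mandatory: false}
    - {fragment: Z0-H2O, mandatory: false}

evidence:
  negative:
    head: [IP, IP-H2O]
    sugar_specific: [C3PO3, C3PO3-C1-CO2, C3PO3-C1-CO2-H2O]
    ceramide: [Z0PO3, Y1-H]
  positive:
    head: [IP+, IP+Na]
    ceramide: [W, W-H2O, W-2H2O, Z0, Z0-H2O]

intensity_rules:
  enabled: false
  negative:
    - {fragment: IP, relation: ">=", reference: base_peak, fraction: 0.05}
  positive: []
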