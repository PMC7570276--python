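# Methods

## Scope and model

`gipctools` annotates plant glycosyl inositol phospho ceramides (GIPCs) from
high-resolution LC-MS/MS data using declarative decision rules, and performs
relative quantification against an internal standard. A GIPC is modeled as
three parts:

1. a **ceramide**: a long-chain base (LCB, amino-polyol `C_n H_(2n+3-2db) N O_h`
   with `h` ∈ {2 (d), 3 (t), 4 (q)} hydroxyls) amide-linked to a fatty acid
   (`C_n H_(2n-2db) O_2`, +O if α-hydroxylated, prefix h) with loss of one
   water. The resolved LCB/FA form reduces to a sum-level class
   `C_X H_(2X+1-2Y) N O_(h+1)` with X = total carbons, Y = total double bonds;
   e.g. t18:1/h24:0 ≡ q42:1.
2. an **inositol-phosphate core**: ceramide + HPO3 + inositol − H2O (series 0,
   the bare IPC).
3. a **glycan series**: an ordered residue chain on the core; series A is
   HexA then a terminal hexose carrying the substituent R1 ∈ {OH, NH2, NAc}.
   R1 is treated purely as an elemental delta on the terminal hexose
   (NH2: −O+NH; NAc: −O+NH + C2H2O, net {C2 H3 N}); positional isomerism is
   not mass-resolvable and not modeled. Series B–F head groups are not
   confirmed structures and ship only as commented-out configuration stubs.

Atomic monoisotopic masses (CODATA/IUPAC, ≥ 6 decimals) and all building
blocks live in a versioned YAML registry, so new residues are configuration,
not code. Adduct arithmetic uses the proton mass 1.00727647 Da and
Na-minus-electron 22.98922070 Da; this reproduces the reference precursor
values within 0.5 mDa. Supported adducts: [M+H]+, [M+Na]+, [M−H]−, all
singly charged.

## Fragment prediction

Fragment recipes are declarative (component sum, neutral losses, ionization)
with three context tokens: the glycan head (residues + inositol + HPO3 + R1),
the ceramide, and the LCB. Key constructions:

* [IP]− = inositol + HPO3 − H+ (m/z 259.0224; with water loss 241.0119);
  [H2PO4]− 96.9696; [PO3]− 78.9591. These are mandatory in negative mode but
  non-specific (any phosphoinositol lipid produces them).
* [C3PO3]− = glycan head − H+: R1-specific at nominal 597 (OH), 596 (NH2),
  638 (NAc).
* The C1-loss family [C3PO3−C1(−CO2)(−H2O)]− loses the **R1-substituted**
  terminal hexose (hexose + glycosidic oxygen + 2H + R1 delta, i.e. 180.063 Da
  for R1 = OH). Because the lost residue carries R1, these ions (nominal
  417/373/355) are identical for all R1 classes — which is exactly why
  exact-mass isobars share them and why only C3PO3 and the W series
  discriminate.
* Positive mode: [IP]+ 261, [IP+Na]+ 283; the W series = protonated LCB with
  successive water losses (W, W−H2O, and W−2H2O only for trihydroxylated
  bases — so t-bases give three W ions, d-bases exactly two); Z0 family =
  protonated dehydrated ceramide; negative-mode ceramide ions Z0PO3 and Y1−H
  retain the phosphate (and inositol).

W-series fragments require a resolved LCB; for sum-level candidates they are
reported as *omitted* (evidence unavailable), never raised as errors.

## Decision rules and confidence levels

MS2 peak matching is existence-based: the highest-intensity peak within
tolerance (default 10 ppm with a 5 mDa floor, matching ~15,000-resolution
Orbitrap MS2), ties broken by smaller |Δm/z| then lower m/z. Evidence classes
per polarity:

* negative **full** = mandatory {IP, IP−H2O} plus ≥ 1 sugar-specific fragment
  ({C3PO3, C3PO3−C1−CO2, C3PO3−C1−CO2−H2O}); **head-only** = mandatory pair
  without sugar-specific ions.
* positive **full** = an IP+ ion plus ≥ 1 ceramide ion (W or Z0 family);
  **ceramide-only** = ceramide ions without IP+.

A candidate must first be MS1-confirmed: a positive-mode feature matching
[M+H]+ or [M+Na]+ and a negative-mode feature matching [M−H]−, both within
±5 ppm, at retention times within 0.2 min of each other (the cross-polarity
RT tolerance is a package choice; the acquisition literature requires only
"matching" RTs). Confidence levels are then a pure function of the evidence:

| negative \ positive | full | ceramide-only | none |
|---|---|---|---|
| **full**      | 2   | 3** | 3 |
| **head-only** | 3** | 3** | 3** |
| **none**      | 3   | 3** | reject |

Mixed partial evidence across both modes is deliberately conservative (3**):
the published tier definitions only address single-mode MS2, so anything
short of full evidence in a mode is treated as "lacking" that mode's
information. Intensity rules (e.g. IP ≥ 5 % of base peak) are supported but
**disabled by default**: the relation set is instrument- and
collision-energy-dependent and the shipped values are placeholders to be
tuned per platform.

## Isobars, naming and retention order

Amine/N-acetyl classes collide exactly: qX:Y-NH2 and t(X−2):(Y−1)-NAc have
identical elemental formulas. After leveling, annotations sharing a formula
are grouped; a member is kept when its own C3PO3 matched (each candidate's
predicted C3PO3 m/z is already R1-specific) or, failing that, when its LCB
was uniquely pinned by a complete W series. With no discriminating evidence
all members are kept and flagged `isobar_ambiguous` — reported, never
silently dropped. The same philosophy applies to naming: the resolved
LCB/FA name is reported only when exactly one candidate LCB's full W set
matched; otherwise the sum-level name is used.

The retention-order filter implements the reversed-phase equivalent carbon
number heuristic within each series/R1/LCB group: retention must strictly
increase with fatty-acyl carbons at equal double-bond count and decrease
with each added double bond at equal carbons. Violating pairs flag all
participants (`ecn_violation`) rather than rejecting them, keeping
borderline RT noise auditable. An optional isotope-pattern check compares
the observed M+1/M area ratio to the value predicted from the formula
(per-atom first-isotope abundances), with a 30 % relative tolerance by
default; it only runs when the feature table carries an `m1_area` column.

## Quantification

With no commercial GIPC standards, quantification is relative: ratio =
area / (IS area × dry weight), per gram dry weight, using by default the
positive-mode [M+H]+ feature area (configurable choice; summing across
adducts is not assumed). Group means are taken over IS-spiked replicates
only; the unspiked replicate (a control for endogenous internal standard)
is excluded with a warning. Scale equivariance holds by construction:
rescaling all areas cancels, rescaling dry weight divides.

## Synthetic data

The simulator generates what the annotator consumes — paired dual-polarity
MS1 features at theoretical adduct m/z with uniform ppm jitter (default
2 ppm, warned above 5 ppm because recovery is then not guaranteed), and
ddMS2 spectra containing the predicted fragment subset for a chosen evidence
scenario per polarity (full / head-only / shared-only / ceramide-only /
none) plus uniform noise peaks. Intensities are log-normal around
fragment-class base levels (head ions high, W moderate; CV 20 %) — arbitrary
but only exercised through ratio-free fragment rules by default. Retention
times follow rt = 2.7 + 0.55 × (acyl carbons) − 0.8 × (double bonds)
minutes, numbers chosen to land the reference species near 16 min on a
30-min gradient; the linear form gives the ECN filter analytic ground truth.
The default truth panel cycles R1 {NAc, NH2, OH} × LCB {t18:1, t18:0} ×
h16:0–h26:0 acyls with t18:1/h24:0 most abundant, mirroring observed plant
profiles. Everything is driven by one seed; identical configs give
byte-identical files.

What the simulation does **not** emulate: chromatographic peak shapes,
co-elution/co-isolation, isotope envelopes beyond the M+1 ratio, adduct
cross-talk, or matrix-dependent ionization. Passing recovery tests therefore
demonstrates the correctness of the decision logic, not detection
performance on real extracts.

## Numerical and design notes

* Formula arithmetic is exact integer counting; masses are pure functions of
  counts, reproducible to ≥ 6 decimals. Negative counts are legal only in
  transient deltas; stored formulas validate non-negativity.
* Enumeration deduplicates on (name, adduct) and sorts by series, R1, m/z,
  name — same config, byte-identical mass lists. Exact isobars with distinct
  names are preserved.
* The default candidate space is the published acquisition list: LCBs
  {d18:0, d18:1, d18:2, t18:0, t18:1}, acyls h15:0–h26:0, h15:1–h26:1,
  n20:0–n28:0 (33), R1 {OH, NH2, NAc} — 495 compositions per adduct for
  series A. t18:2 (proposed, unconfirmed) is available behind an opt-in
  flag. The acyl list deliberately starts at h15:0 (the acquisition-list
  convention) although observed species start at h16:0.
* One annotation is reported per sum-level composition (the best-scoring
  feature pair); two species sharing a sum composition at different RTs
  would need a per-RT extension.
* Sizes used in the shipped tests and acceptance run: 20 truths + 20 decoys
  against the 495-composition space, which exercises every code path in a
  few seconds.

## Known limitations

* Series B–F require verified residue compositions before activation.
* No FDR estimation, spectral-library scoring, or co-isolation
  deconvolution; features are consumed, not picked from profile data.
* Intensity-rule defaults are placeholders (disabled); real deployments
  should derive them from their own collision-energy behavior.
* Level 3 requires full single-mode evidence; datasets with systematically
  partial evidence will concentrate in 3**.
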