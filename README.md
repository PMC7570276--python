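# gipctools

Automated annotation and relative quantification of plant **glycosyl
inositol phospho ceramides (GIPCs)** from dual-polarity LC-MS/MS data.

GIPCs are the dominant sphingolipids of plants and fungi, yet they have no
commercial standards and almost no database coverage, so their analysis has
relied on manual spectrum reading. `gipctools` implements a rule-based
annotation engine for people running reversed-phase high-resolution LC-MS/MS
on plant extracts: it enumerates candidate compositions
(series-R1-LCB/FA, e.g. `A-OH-t18:1/h24:0`), predicts their diagnostic MS2
fragments, evaluates acquired spectra against declarative fragment and
intensity rules, integrates positive- and negative-mode evidence into
confidence-leveled annotations, resolves exact-mass isobars, checks
retention order, and quantifies relative to an internal standard.

## The method in brief

A GIPC neutral mass is assembled from building blocks:

```
M = ceramide(LCB + FA − H2O) + HPO3 + inositol − H2O + Σ glycan residues + ΔR1
```

with ceramide `C_X H_(2X+1−2Y) N O_(h+1)` (X carbons, Y double bonds, h
hydroxyls: d/t/q = 2/3/4) and, for the A-series, residues HexA + Hex where
the terminal hexose carries R1 ∈ {OH, NH2, NAc}. Candidates are accepted
only if seen by accurate mass (±5 ppm) in **both** ion modes at matching
retention times; MS2 evidence then sets the confidence level:

* **level 2** — diagnostic MS2 in both modes: negative-mode [IP]⁻ (m/z 259)
  and [IP−H2O]⁻ (241) plus a sugar-specific head fragment ([C3PO3]⁻
  597/596/638 for OH/NH2/NAc, or its losses 373/355), and positive-mode
  [IP]⁺ 261/[IP+Na]⁺ 283 plus a ceramide ion (W series or Z0);
* **level 3** — full MS2 evidence in exactly one mode;
* **level 3\*\*** — single-mode MS2 lacking IP information (positive) or
  sugar information (negative).

The W series (protonated LCB with successive water losses) identifies the
long-chain base: trihydroxylated bases give three ions (t18:1: 298/280/262),
dihydroxylated only two (d18:0: 284/266) — this also disambiguates the
exact-mass isobar pair qX:Y-NH2 / t(X−2):(Y−1)-NAc, which share all other
characteristic fragments (241, 259, 355, 373, 417).

## Worked example

Generate a synthetic ground-truth dataset, annotate it, and quantify:

```bash
gipctools simulate --n-truths 10 --n-decoys 6 --seed 5 --out-dir sim
gipctools annotate --features sim/features.csv --spectra sim/spectra.peaks --out ann.tsv
# -> wrote 10 annotations to ann.tsv
head -3 ann.tsv | cut -f1-9
```

```
name                sum_name     level  adduct_pos  mz_pos       ppm_pos  mz_neg       ppm_neg  rt
A-NAc-t18:1/h16:0   A-NAc-q34:1  2      [M+H]+      1191.637689  -1.78    1189.624707  -0.47    10.6894
A-NAc-t18:1/h17:0   A-NAc-q35:1  2      [M+H]+      1205.654584  -0.73    1203.640441  -0.39    11.2469
```

All ten truths come back at level 2 with resolved LCB/FA names (the W series
was present in the simulated positive-mode spectra); the six decoy features
are rejected. Columns report the paired feature m/z with ppm errors, the
matched fragments per polarity, and audit flags (`isobar_ambiguous`,
`ecn_violation`). Quantification against sample metadata:

```bash
printf 'sample,group,dry_weight,is_area,is_spiked\nsynthetic,g1,0.1,500000,True\n' > samples.csv
gipctools quantify --annotations ann.tsv --features sim/features.csv --samples samples.csv --out quant.tsv
```

which writes normalized ratios per gram dry weight,
`ratio = area / (IS area × dry weight)`, averaged over IS-spiked replicates
(for the most abundant simulated species, `A-NAc-t18:1/h24:0`, the printed
ratio is 36.72 /g: area ≈ 1.84e6 over IS 5e5 × 0.1 g).

Library use mirrors the CLI:

```python
from gipctools import make_composition, gipc_formula, adduct_mz, predict_fragments

comp = make_composition("A", "OH", "t18:1", "h24:0")
adduct_mz(gipc_formula(comp), "[M-H]-").mz      # 1260.7239
[(i.name, round(i.mz)) for i in predict_fragments(comp, "-").ions]
# [('PO3', 79), ('H2PO4', 97), ('IP', 259), ('IP-H2O', 241), ('C3PO3', 597), ...]
```

Precursor mass lists and acquisition inclusion lists (default window
500–3000 m/z, one polarity per file) come from `gipctools masslist` and
`gipctools inclusion-list`.

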