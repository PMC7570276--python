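"""Synthetic GIPC datasets with known ground truth.

Emulates the structure of a dual-polarity targeted lipidomics run: for every
true composition, paired MS1 features at the theoretical adduct m/z (with ppm
jitter) at a common retention time, plus ddMS2 spectra containing the
predicted diagnostic fragments — configurable per polarity so that the full
range of confidence levels (2, 3, 3**) and the isobar-ambiguity hazard can be
exercised — along with decoy features that a correct annotator must reject.

Retention times follow a linear equivalent-carbon-number model (minutes):
``rt = base + slope * acyl carbons - db_penalty * total double bonds``, so
retention-order checks have analytic ground truth.  Everything is driven by a
single seed; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .annotate import Evidence, Feature, assign_level, predicted_m1_ratio
from .chem import CeramideSpec, GipcComposition, adduct_mz, default_registry, gipc_formula
from .fragments import predict_fragments
from .rules import Spectrum
from .spaces import default_series_table
from . import io as gio

__all__ = ["RtModel", "TruthSpec", "SimConfig", "SimulatedDataset", "simulate_dataset", "default_truths", "make_composition"]

NEG_EVIDENCE_CHOICES = ("full", "head_only", "shared_only", "none")
POS_EVIDENCE_CHOICES = ("full", "ceramide_only", "none")

# fragment subsets realizing each evidence scenario
_NEG_SUBSETS = {
    "head_only": {"IP", "IP-H2O", "PO3", "H2PO4"},
    "shared_only": {"IP", "IP-H2O", "PO3", "H2PO4", "C3PO3-C1", "C3PO3-C1-CO2", "C3PO3-C1-CO2-H2O"},
}
_POS_SUBSETS = {"ceramide_only": {"W", "W-H2O", "W-2H2O", "Z0", "Z0-H2O"}}


@dataclass(frozen=True)
class RtModel:
    """Linear ECN retention model (minutes)."""

    base: float = 2.7
    slope_per_carbon: float = 0.55
    db_penalty: float = 0.8

    def rt(self, comp: GipcComposition) -> float:
        cer = comp.ceramide
        fa_c = cer.fa.carbons if cer.is_resolved else cer.carbons - 18
        return self.base + self.slope_per_carbon * fa_c - self.db_penalty * cer.double_bonds


def make_composition(series: str, r1: str | None, lcb: str, fa: str) -> GipcComposition:
    sdef = default_series_table().get(series)
    return GipcComposition(
        series, sdef.residues, r1 if sdef.r1_terminal else None, CeramideSpec.resolved(lcb, fa)
    )


@dataclass(frozen=True)
class TruthSpec:
    """One true composition and the MS2 evidence it should exhibit."""

    composition: GipcComposition
    abundance: float = 1.0e6
    neg_evidence: str = "full"
    pos_evidence: str = "full"
    rt_override: float | None = None

    def expected_level(self) -> str:
        neg = {"full": "full", "head_only": "head_only", "shared_only": "full", "none": "none"}[
            self.neg_evidence
        ]
        pos = {"full": "full", "ceramide_only": "ceramide_only", "none": "none"}[self.pos_evidence]
        return assign_level(Evidence(True, neg, pos))

    def expected_name(self) -> str:
        # the LCB is only nameable when the W series was observable
        if self.pos_evidence in ("full", "ceramide_only"):
            return self.composition.name
        return self.composition.sum_name


@dataclass(frozen=True)
class SimConfig:
    truths: tuple[TruthSpec, ...]
    seed: int = 0
    mz_jitter_ppm: float = 2.0
    rt_noise_min: float = 0.02
    intensity_cv: float = 0.2
    noise_peaks: int = 10
    n_near_mass_decoys: int = 0
    n_unpaired_decoys: int = 0
    rt_model: RtModel = field(default_factory=RtModel)
    sample: str = "synthetic"
    with_m1: bool = False


@dataclass
class SimulatedDataset:
    features: list[Feature]
    spectra: list[Spectrum]
    truth: pd.DataFrame

    def write(self, out_dir: str | Path, spectra_format: str = "peaks") -> dict[str, Path]:
        """Write feature CSV, spectra file and truth TSV; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "features": out / "features.csv",
            "spectra": out / ("spectra.mzML" if spectra_format == "mzml" else "spectra.peaks"),
            "truth": out / "truth.tsv",
        }
        gio.write_features(self.features, paths["features"])
        if spectra_format == "mzml":
            gio.write_mzml(self.spectra, paths["spectra"])
        else:
            gio.write_peaklist(self.spectra, paths["spectra"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6f")
        return paths


def _jitter(rng: np.random.Generator, mz: float, ppm: float) -> float:
    return mz * (1.0 + rng.uniform(-ppm, ppm) * 1e-6)


def _intensity(rng: np.random.Generator, base: float, cv: float) -> float:
    if cv <= 0:
        return base
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return float(base * rng.lognormal(-0.5 * sigma * sigma, sigma))


_FRAGMENT_BASE_LEVEL = {
    "IP": 1.0e5, "IP-H2O": 8.0e4, "PO3": 2.0e4, "H2PO4": 3.0e4,
    "C3PO3": 4.0e4, "C3PO3-C1": 2.5e4, "C3PO3-C1-CO2": 3.0e4, "C3PO3-C1-CO2-H2O": 2.0e4,
    "Z0PO3": 1.5e4, "Y1-H": 1.5e4,
    "IP+": 9.0e4, "IP+Na": 4.0e4,
    "W": 5.0e4, "W-H2O": 6.0e4, "W-2H2O": 3.0e4, "Z0": 2.5e4, "Z0-H2O": 2.0e4,
}


def _make_spectrum(
    rng: np.random.Generator,
    cfg: SimConfig,
    comp: GipcComposition,
    polarity: str,
    precursor_mz: float,
    rt: float,
    keep: set[str] | None,
    scan_id: str,
) -> Spectrum:
    predicted = predict_fragments(comp, polarity)
    mzs, intens = [], []
    for ion in predicted.ions:
        if keep is not None and ion.name not in keep:
            continue
        mzs.append(_jitter(rng, ion.mz, cfg.mz_jitter_ppm))
        intens.append(_intensity(rng, _FRAGMENT_BASE_LEVEL.get(ion.name, 1.0e4), cfg.intensity_cv))
    for _ in range(cfg.noise_peaks):
        mzs.append(float(rng.uniform(100.0, max(precursor_mz, 200.0))))
        intens.append(float(rng.uniform(100.0, 5.0e3)))
    return Spectrum(
        precursor_mz=precursor_mz,
        polarity=polarity,
        rt=rt,
        mz=np.array(mzs),
        intensity=np.array(intens),
        scan_id=scan_id,
    )


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate paired features, ddMS2 spectra and a ground-truth table."""
    import warnings

    for t in cfg.truths:
        if t.neg_evidence not in NEG_EVIDENCE_CHOICES:
            raise ValueError(f"unknown negative evidence scenario {t.neg_evidence!r}")
        if t.pos_evidence not in POS_EVIDENCE_CHOICES:
            raise ValueError(f"unknown positive evidence scenario {t.pos_evidence!r}")
    if cfg.mz_jitter_ppm > 5.0:
        warnings.warn("m/z jitter exceeds the 5 ppm MS1 criterion; recovery not guaranteed")

    rng = np.random.default_rng(cfg.seed)
    reg = default_registry()
    features: list[Feature] = []
    spectra: list[Spectrum] = []
    truth_rows = []

    for i, t in enumerate(cfg.truths):
        comp = t.composition
        f = gipc_formula(comp, reg)
        pos_mz = adduct_mz(f, "[M+H]+", reg).mz
        neg_mz = adduct_mz(f, "[M-H]-", reg).mz
        rt = t.rt_override if t.rt_override is not None else cfg.rt_model.rt(comp)
        rt_pos = rt + float(rng.normal(0.0, cfg.rt_noise_min / 2))
        rt_neg = rt + float(rng.normal(0.0, cfg.rt_noise_min / 2))
        pos_area = _intensity(rng, t.abundance, cfg.intensity_cv)
        neg_area = _intensity(rng, 0.8 * t.abundance, cfg.intensity_cv)
        m1 = predicted_m1_ratio(f) * pos_area if cfg.with_m1 else None
        features.append(
            Feature(_jitter(rng, pos_mz, cfg.mz_jitter_ppm), rt_pos, pos_area, "+", cfg.sample, m1)
        )
        features.append(
            Feature(_jitter(rng, neg_mz, cfg.mz_jitter_ppm), rt_neg, neg_area, "-", cfg.sample)
        )
        if t.neg_evidence != "none":
            spectra.append(
                _make_spectrum(
                    rng, cfg, comp, "-", _jitter(rng, neg_mz, cfg.mz_jitter_ppm), rt_neg,
                    _NEG_SUBSETS.get(t.neg_evidence), f"truth{i:03d}_neg",
                )
            )
        if t.pos_evidence != "none":
            spectra.append(
                _make_spectrum(
                    rng, cfg, comp, "+", _jitter(rng, pos_mz, cfg.mz_jitter_ppm), rt_pos,
                    _POS_SUBSETS.get(t.pos_evidence), f"truth{i:03d}_pos",
                )
            )
        truth_rows.append(
            {
                "name": comp.name,
                "sum_name": comp.sum_name,
                "expected_name": t.expected_name(),
                "expected_level": t.expected_level(),
                "rt": rt,
                "mz_pos": pos_mz,
                "mz_neg": neg_mz,
                "neg_evidence": t.neg_evidence,
                "pos_evidence": t.pos_evidence,
                "abundance": t.abundance,
            }
        )

    # near-mass decoys: paired features offset well beyond the ppm gate, with
    # fragment-free spectra — must never be annotated
    for j in range(cfg.n_near_mass_decoys):
        t = cfg.truths[j % len(cfg.truths)]
        f = gipc_formula(t.composition, reg)
        offset = 0.35 + 0.01 * j
        rt = (t.rt_override if t.rt_override is not None else cfg.rt_model.rt(t.composition)) + 0.5
        features.append(
            Feature(adduct_mz(f, "[M+H]+", reg).mz + offset, rt, 2.0e5, "+", cfg.sample)
        )
        features.append(
            Feature(adduct_mz(f, "[M-H]-", reg).mz + offset, rt, 1.5e5, "-", cfg.sample)
        )

    # unpaired decoys: a negative-mode feature at a real candidate mass with
    # no positive partner — must fail MS1 pairing
    for j in range(cfg.n_unpaired_decoys):
        t = cfg.truths[j % len(cfg.truths)]
        f = gipc_formula(t.composition, reg)
        rt = (t.rt_override if t.rt_override is not None else cfg.rt_model.rt(t.composition)) + 3.0
        features.append(Feature(adduct_mz(f, "[M-H]-", reg).mz, rt, 1.0e5, "-", cfg.sample))

    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(features, spectra, truth)


def default_truths(
    n: int = 20,
    neg_evidence: str = "full",
    pos_evidence: str = "full",
    series: str = "A",
) -> tuple[TruthSpec, ...]:
    """A deterministic panel of plausible A-series truths.

    Compositions cycle over R1 {NAc, NH2, OH} x LCB {t18:1, t18:0} x acyls
    h16:0..h26:0, mimicking observed plant profiles; t18:1/h24:0 carries the
    largest abundance, as in real plant samples.
    """
    r1s = ("NAc", "NH2", "OH")
    lcbs = ("t18:1", "t18:0")
    fas = [f"h{c}:0" for c in range(16, 27)]
    truths = []
    k = 0
    for r1 in r1s:
        for lcb in lcbs:
            for fa in fas:
                if k >= n:
                    return tuple(truths)
                comp = make_composition(series, r1, lcb, fa)
                abundance = 2.0e6 if (lcb == "t18:1" and fa == "h24:0") else 1.0e6 / (1 + k % 7)
                truths.append(
                    TruthSpec(comp, abundance, neg_evidence, pos_evidence)
                )
                k += 1
    return tuple(truths)
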