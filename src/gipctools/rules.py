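"""Declarative evaluation of MS2 spectra against GIPC candidates.

A rule set couples fragment recipes with per-polarity fragment rules
(mandatory / optional presence) and optional intensity rules.  Evaluation of
a spectrum yields matched fragments and a per-polarity evidence class:

* negative mode — ``full``: the mandatory inositol-phosphate pair (IP m/z 259,
  IP-H2O m/z 241) plus at least one sugar-specific head fragment (C3PO3 or its
  hexose/CO2/H2O loss products); ``head_only``: mandatory pair present but no
  sugar-specific fragment; ``none`` otherwise.
* positive mode — ``full``: an IP+ ion (261 or the sodiated 283) plus at least
  one ceramide-derived fragment (W series or Z0 family); ``ceramide_only``:
  ceramide fragments without IP+; ``none`` otherwise.

These classes feed the confidence-level assignment (levels 2 / 3 / 3**).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .chem import BlockRegistry, GipcComposition
from .fragments import FragmentRecipe, _parse_recipes, predict_fragments

__all__ = [
    "Spectrum",
    "Peak",
    "FragmentRule",
    "IntensityRule",
    "FragmentMatch",
    "RuleOutcome",
    "RuleSet",
    "default_ruleset",
    "load_ruleset",
    "match_peak",
    "evaluate",
    "EVIDENCE_FULL",
    "EVIDENCE_HEAD_ONLY",
    "EVIDENCE_CERAMIDE_ONLY",
    "EVIDENCE_NONE",
]

EVIDENCE_FULL = "full"
EVIDENCE_HEAD_ONLY = "head_only"
EVIDENCE_CERAMIDE_ONLY = "ceramide_only"
EVIDENCE_NONE = "none"


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """A centroided MS2 spectrum (peaks kept sorted by m/z)."""

    precursor_mz: float
    polarity: str  # '+' or '-'
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError(f"negative intensity in scan {self.scan_id!r}")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class FragmentRule:
    fragment: str
    mandatory: bool = False
    polarity: str = "-"
    tolerance_ppm: float | None = None  # per-rule override


@dataclass(frozen=True)
class IntensityRule:
    """Relation between a fragment's intensity and a reference (another
    fragment or the base peak): intensity(fragment) <relation> fraction * ref."""

    fragment: str
    reference: str  # fragment name or 'base_peak'
    relation: str = ">="
    fraction: float = 0.05


@dataclass(frozen=True)
class FragmentMatch:
    name: str
    theoretical_mz: float
    observed_mz: float
    intensity: float
    ppm_error: float


@dataclass
class RuleOutcome:
    """Result of evaluating one spectrum against one candidate."""

    candidate: GipcComposition
    spectrum_id: str
    polarity: str
    matched: dict[str, FragmentMatch] = field(default_factory=dict)
    omitted: tuple[str, ...] = ()
    failed_mandatory: list[str] = field(default_factory=list)
    failed_intensity: list[str] = field(default_factory=list)
    evidence: str = EVIDENCE_NONE

    @property
    def passed(self) -> bool:
        return not self.failed_mandatory and not self.failed_intensity


@dataclass(frozen=True)
class RuleSet:
    """Fragment recipes + presence rules + evidence classes for one series
    family, per polarity."""

    recipes: Mapping[str, Mapping[str, FragmentRecipe]]
    fragment_rules: Mapping[str, tuple[FragmentRule, ...]]
    evidence_sets: Mapping[str, Mapping[str, tuple[str, ...]]]
    ms2_ppm: float = 10.0
    ms2_da_floor: float = 0.005
    intensity_rules: Mapping[str, tuple[IntensityRule, ...]] = field(
        default_factory=lambda: {"+": (), "-": ()}
    )
    intensity_rules_enabled: bool = False

    @classmethod
    def from_config(cls, cfg: Mapping) -> "RuleSet":
        pol_map = {"positive": "+", "negative": "-"}
        frules = {"+": (), "-": ()}
        for pol_name, rules in cfg.get("fragment_rules", {}).items():
            pol = pol_map[pol_name]
            frules[pol] = tuple(
                FragmentRule(
                    fragment=r["fragment"],
                    mandatory=bool(r.get("mandatory", False)),
                    polarity=pol,
                    tolerance_ppm=r.get("tolerance_ppm"),
                )
                for r in rules
            )
        ev = {"+": {}, "-": {}}
        for pol_name, classes in cfg.get("evidence", {}).items():
            ev[pol_map[pol_name]] = {k: tuple(v) for k, v in classes.items()}
        icfg = cfg.get("intensity_rules", {}) or {}
        irules = {"+": (), "-": ()}
        for pol_name in ("positive", "negative"):
            irules[pol_map[pol_name]] = tuple(
                IntensityRule(
                    fragment=r["fragment"],
                    reference=r.get("reference", "base_peak"),
                    relation=r.get("relation", ">="),
                    fraction=float(r.get("fraction", 0.05)),
                )
                for r in icfg.get(pol_name, []) or []
            )
        tol = cfg.get("tolerances", {})
        return cls(
            recipes=_parse_recipes(cfg["fragments"]),
            fragment_rules=frules,
            evidence_sets=ev,
            ms2_ppm=float(tol.get("ms2_ppm", 10.0)),
            ms2_da_floor=float(tol.get("ms2_da_floor", 0.005)),
            intensity_rules=irules,
            intensity_rules_enabled=bool(icfg.get("enabled", False)),
        )

    def tolerance_da(self, mz: float, ppm_override: float | None = None) -> float:
        ppm = self.ms2_ppm if ppm_override is None else ppm_override
        return max(mz * ppm * 1e-6, self.ms2_da_floor)


def load_ruleset(path) -> RuleSet:
    with open(path) as fh:
        return RuleSet.from_config(yaml.safe_load(fh))


@lru_cache(maxsize=1)
def default_ruleset() -> RuleSet:
    text = resources.files("gipctools.data").joinpath("rules_a.yaml").read_text()
    return RuleSet.from_config(yaml.safe_load(text))


def match_peak(spectrum: Spectrum, target_mz: float, tolerance_da: float) -> Peak | None:
    """Highest-intensity peak within ``tolerance_da`` of ``target_mz``.

    Ties break deterministically by smaller |delta m/z|, then lower m/z.
    Absence is a valid result (None).
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be > 0")
    lo = np.searchsorted(spectrum.mz, target_mz - tolerance_da, side="left")
    hi = np.searchsorted(spectrum.mz, target_mz + tolerance_da, side="right")
    if lo == hi:
        return None
    mzs = spectrum.mz[lo:hi]
    ints = spectrum.intensity[lo:hi]
    # lexicographic: max intensity, then min |dmz|, then min mz
    best = min(
        range(len(mzs)), key=lambda i: (-ints[i], abs(mzs[i] - target_mz), mzs[i])
    )
    return Peak(float(mzs[best]), float(ints[best]))


def _classify_evidence(
    polarity: str, matched: set[str], evidence_sets: Mapping[str, tuple[str, ...]]
) -> str:
    head = set(evidence_sets.get("head", ()))
    if polarity == "-":
        sugar = set(evidence_sets.get("sugar_specific", ()))
        if head and head <= matched:
            return EVIDENCE_FULL if matched & sugar else EVIDENCE_HEAD_ONLY
        return EVIDENCE_NONE
    ceramide = set(evidence_sets.get("ceramide", ()))
    has_head = bool(matched & head)
    has_cer = bool(matched & ceramide)
    if has_head and has_cer:
        return EVIDENCE_FULL
    if has_cer:
        return EVIDENCE_CERAMIDE_ONLY
    return EVIDENCE_NONE


def evaluate(
    spectrum: Spectrum,
    candidate: GipcComposition,
    ruleset: RuleSet | None = None,
    registry: BlockRegistry | None = None,
) -> RuleOutcome:
    """Evaluate one spectrum against one candidate under a rule set.

    The spectrum's polarity must match the rules being applied; matching of
    each predicted fragment is existence-based (best peak within tolerance),
    so adding peaks can never fail a previously passing fragment rule.
    Intensity rules, when enabled, are checked on the matched peaks.
    """
    rs = ruleset or default_ruleset()
    pol = spectrum.polarity
    if pol not in ("+", "-"):
        raise ValueError(f"spectrum polarity must be '+' or '-', got {pol!r}")
    predicted = predict_fragments(candidate, pol, rs.recipes, registry)
    theo = predicted.by_name()
    rule_tol = {r.fragment: r.tolerance_ppm for r in rs.fragment_rules[pol]}

    outcome = RuleOutcome(
        candidate=candidate,
        spectrum_id=spectrum.scan_id,
        polarity=pol,
        omitted=predicted.omitted,
    )
    for name, ion in theo.items():
        tol = rs.tolerance_da(ion.mz, rule_tol.get(name))
        peak = match_peak(spectrum, ion.mz, tol)
        if peak is not None:
            ppm = (peak.mz - ion.mz) / ion.mz * 1e6
            outcome.matched[name] = FragmentMatch(name, ion.mz, peak.mz, peak.intensity, ppm)

    for rule in rs.fragment_rules[pol]:
        if rule.mandatory and rule.fragment in theo and rule.fragment not in outcome.matched:
            outcome.failed_mandatory.append(rule.fragment)

    if rs.intensity_rules_enabled:
        for irule in rs.intensity_rules[pol]:
            m = outcome.matched.get(irule.fragment)
            if m is None:
                continue  # presence is the fragment rules' business
            if irule.reference == "base_peak":
                ref = spectrum.base_peak_intensity
            else:
                ref_match = outcome.matched.get(irule.reference)
                if ref_match is None:
                    continue
                ref = ref_match.intensity
            threshold = irule.fraction * ref
            ok = m.intensity >= threshold if irule.relation == ">=" else m.intensity > threshold
            if not ok:
                outcome.failed_intensity.append(irule.fragment)

    outcome.evidence = _classify_evidence(
        pol, set(outcome.matched), rs.evidence_sets.get(pol, {})
    )
    return outcome
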