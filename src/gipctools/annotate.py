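"""Dual-polarity evidence integration into leveled GIPC annotations.

An annotation is accepted only when the candidate is seen by accurate mass
(default +/- 5 ppm) in MS1 at the same retention time in both polarities;
MS2 evidence then sets the confidence level:

* level 2   — MS1-paired and full MS2 evidence in both polarities,
* level 3   — MS1-paired and full MS2 evidence in exactly one polarity,
* level 3** — MS1-paired with single-polarity MS2 that is partial: positive
  spectra lacking the inositol-phosphate ions (ceramide evidence only) or
  negative spectra lacking sugar-specific fragments (head evidence only).
  Mixed partial evidence across both polarities is also reported here.

Exact-mass isobars (amine qX:Y vs N-acetyl t(X-2):(Y-1)) are disambiguated
via the R1-specific C3PO3 head fragment (m/z 596 vs 638) or the long-chain
base W-fragment series; candidates left undecided carry an ambiguity flag.
A retention-order (equivalent carbon number) filter flags annotations whose
elution order contradicts the reversed-phase model: retention increases
with fatty-acyl chain length and decreases with double bonds.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem import (
    BlockRegistry,
    ElementalFormula,
    GipcComposition,
    adduct_mz,
    default_registry,
    gipc_formula,
)
from .rules import (
    EVIDENCE_CERAMIDE_ONLY,
    EVIDENCE_FULL,
    EVIDENCE_HEAD_ONLY,
    EVIDENCE_NONE,
    RuleOutcome,
    RuleSet,
    Spectrum,
    default_ruleset,
    evaluate,
)

__all__ = [
    "Feature",
    "FeaturePair",
    "Evidence",
    "Annotation",
    "LEVEL_2",
    "LEVEL_3",
    "LEVEL_3SS",
    "REJECT",
    "pair_features",
    "assign_level",
    "disambiguate_isobars",
    "ecn_filter",
    "predicted_m1_ratio",
    "Annotator",
]

LEVEL_2 = "2"
LEVEL_3 = "3"
LEVEL_3SS = "3**"
REJECT = "reject"

_POS_ADDUCTS = ("[M+H]+", "[M+Na]+")
_NEG_ADDUCT = "[M-H]-"


@dataclass(frozen=True)
class Feature:
    """An MS1 feature: centroid m/z, retention time (min), integrated area."""

    mz: float
    rt: float
    area: float
    polarity: str  # '+' or '-'
    sample: str = ""
    m1_area: float | None = None  # optional M+1 isotopologue area

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("feature area must be >= 0")
        if self.rt < 0:
            raise ValueError("feature RT must be >= 0")


@dataclass(frozen=True)
class FeaturePair:
    positive: Feature
    negative: Feature
    pos_adduct: str
    pos_ppm: float
    neg_ppm: float

    @property
    def combined_ppm(self) -> float:
        return abs(self.pos_ppm) + abs(self.neg_ppm)

    @property
    def rt(self) -> float:
        return 0.5 * (self.positive.rt + self.negative.rt)


def _ppm(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


def pair_features(
    pos_features: Sequence[Feature],
    neg_features: Sequence[Feature],
    formula: ElementalFormula,
    ppm_tol: float = 5.0,
    rt_tol: float = 0.2,
    registry: BlockRegistry | None = None,
) -> FeaturePair | None:
    """Best cross-polarity MS1 pair for a neutral formula, or None.

    A candidate is MS1-confirmed iff a positive feature matches [M+H]+ (or
    [M+Na]+) and a negative feature matches [M-H]-, both within ``ppm_tol``,
    at retention times within ``rt_tol`` minutes of each other.  The best
    pair minimizes the combined absolute ppm error.
    """
    reg = registry or default_registry()
    neg_mz = adduct_mz(formula, _NEG_ADDUCT, reg).mz
    pos_mzs = {a: adduct_mz(formula, a, reg).mz for a in _POS_ADDUCTS}

    best: FeaturePair | None = None
    for neg in neg_features:
        if neg.polarity != "-":
            continue
        dneg = _ppm(neg.mz, neg_mz)
        if abs(dneg) > ppm_tol:
            continue
        for pos in pos_features:
            if pos.polarity != "+":
                continue
            if abs(pos.rt - neg.rt) > rt_tol:
                continue
            for adduct, theo in pos_mzs.items():
                dpos = _ppm(pos.mz, theo)
                if abs(dpos) > ppm_tol:
                    continue
                pair = FeaturePair(pos, neg, adduct, dpos, dneg)
                if best is None or pair.combined_ppm < best.combined_ppm:
                    best = pair
    return best


@dataclass(frozen=True)
class Evidence:
    """MS1 pairing state plus the per-polarity MS2 evidence class."""

    paired: bool
    negative: str = EVIDENCE_NONE
    positive: str = EVIDENCE_NONE


def assign_level(evidence: Evidence) -> str:
    """Confidence level from MS1 pairing and per-polarity MS2 evidence.

    Pure function of the evidence; see the module docstring for the tier
    definitions.
    """
    if not evidence.paired:
        return REJECT
    neg_full = evidence.negative == EVIDENCE_FULL
    pos_full = evidence.positive == EVIDENCE_FULL
    neg_partial = evidence.negative == EVIDENCE_HEAD_ONLY
    pos_partial = evidence.positive == EVIDENCE_CERAMIDE_ONLY
    if neg_full and pos_full:
        return LEVEL_2
    if (neg_full and evidence.positive == EVIDENCE_NONE) or (
        pos_full and evidence.negative == EVIDENCE_NONE
    ):
        return LEVEL_3
    if neg_full or pos_full or neg_partial or pos_partial:
        return LEVEL_3SS
    return REJECT


@dataclass
class Annotation:
    """A leveled GIPC annotation with its supporting evidence."""

    composition: GipcComposition
    level: str
    pair: FeaturePair | None = None
    outcomes: dict[str, RuleOutcome | None] = field(default_factory=lambda: {"+": None, "-": None})
    flags: set[str] = field(default_factory=set)
    resolved: bool = False

    @property
    def name(self) -> str:
        return self.composition.name

    @property
    def sum_name(self) -> str:
        return self.composition.sum_name

    @property
    def rt(self) -> float | None:
        return self.pair.rt if self.pair else None

    def matched_fragments(self, polarity: str) -> tuple[str, ...]:
        out = self.outcomes.get(polarity)
        return tuple(sorted(out.matched)) if out else ()


# ---------------------------------------------------------------------------
# Isobar disambiguation
# ---------------------------------------------------------------------------


def _c3po3_matched(ann: Annotation) -> bool:
    out = ann.outcomes.get("-")
    return out is not None and "C3PO3" in out.matched


def disambiguate_isobars(group: Sequence[Annotation]) -> list[Annotation]:
    """Resolve a set of exact-mass isobaric annotations sharing a precursor.

    An isobar member is positively identified when its own R1-specific C3PO3
    head fragment matched (m/z 597 OH / 596 NH2 / 638 NAc — each candidate's
    predicted C3PO3 differs, so a match is already R1-specific), or when its
    long-chain base was resolved by a complete W-fragment series.  If no
    member carries discriminating evidence, all are kept and flagged
    ambiguous rather than silently dropped.
    """
    if len(group) <= 1:
        return list(group)
    by_c3 = [a for a in group if _c3po3_matched(a)]
    if by_c3:
        return by_c3
    by_lcb = [a for a in group if a.resolved]
    if len(by_lcb) == 1:
        return by_lcb
    out = []
    for a in group:
        a.flags.add("isobar_ambiguous")
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# Retention-order (equivalent carbon number) filter
# ---------------------------------------------------------------------------


def ecn_filter(annotations: Iterable[Annotation]) -> None:
    """Flag annotations whose retention order violates the reversed-phase
    equivalent-carbon-number model within each series/R1/LCB group.

    Within a group, at equal fatty-acyl double-bond count the retention time
    must strictly increase with acyl carbons; at equal carbons, each extra
    double bond must elute earlier.  Every annotation participating in a
    violating pair gains an ``ecn_violation`` flag (reported, not dropped).
    """
    groups: dict[tuple, list[Annotation]] = defaultdict(list)
    for a in annotations:
        if a.composition.ceramide.is_resolved and a.rt is not None:
            key = (a.composition.series, a.composition.r1, a.composition.ceramide.lcb)
            groups[key].append(a)
    for members in groups.values():
        for a, b in itertools.combinations(members, 2):
            fa_a, fa_b = a.composition.ceramide.fa, b.composition.ceramide.fa
            if fa_a.hydroxylated != fa_b.hydroxylated:
                continue
            if fa_a.double_bonds == fa_b.double_bonds and fa_a.carbons != fa_b.carbons:
                longer, shorter = (a, b) if fa_a.carbons > fa_b.carbons else (b, a)
                if longer.rt <= shorter.rt:
                    a.flags.add("ecn_violation")
                    b.flags.add("ecn_violation")
            elif fa_a.carbons == fa_b.carbons and fa_a.double_bonds != fa_b.double_bonds:
                more_db, fewer_db = (a, b) if fa_a.double_bonds > fa_b.double_bonds else (b, a)
                if more_db.rt >= fewer_db.rt:
                    a.flags.add("ecn_violation")
                    b.flags.add("ecn_violation")


# ---------------------------------------------------------------------------
# Isotope-pattern plausibility (optional MS1 filter)
# ---------------------------------------------------------------------------

# per-atom M+1/M abundance ratios (13C, 2H, 15N, 17O)
_M1_RATIOS = {"C": 0.010816, "H": 0.000116, "N": 0.003654, "O": 0.000381}


def predicted_m1_ratio(formula: ElementalFormula) -> float:
    """First-isotopologue intensity ratio (M+1)/M predicted from counts."""
    return sum(_M1_RATIOS.get(el, 0.0) * n for el, n in formula.counts)


# ---------------------------------------------------------------------------
# End-to-end annotation
# ---------------------------------------------------------------------------


class Annotator:
    """Integrates MS1 features and dual-polarity MS2 spectra into leveled
    annotations over a candidate list.

    Candidates that share a sum-level composition (same series, R1 and
    ceramide class, hence the same formula) are evaluated as one group; the
    resolved LCB/FA name is reported only when the W-fragment series (or
    other LCB-specific evidence) pins down exactly one long-chain base,
    otherwise the sum-level name is kept.
    """

    def __init__(
        self,
        ruleset: RuleSet | None = None,
        ms1_ppm: float = 5.0,
        rt_tol: float = 0.2,
        isotope_check: bool = False,
        isotope_rel_tol: float = 0.3,
        registry: BlockRegistry | None = None,
    ):
        self.ruleset = ruleset or default_ruleset()
        self.ms1_ppm = ms1_ppm
        self.rt_tol = rt_tol
        self.isotope_check = isotope_check
        self.isotope_rel_tol = isotope_rel_tol
        self.registry = registry or default_registry()

    # -- helpers ---------------------------------------------------------

    def _spectra_for(
        self, spectra: Sequence[Spectrum], mz: float, rt: float, polarity: str
    ) -> list[Spectrum]:
        tol = mz * self.ms1_ppm * 1e-6
        return [
            s
            for s in spectra
            if s.polarity == polarity
            and abs(s.precursor_mz - mz) <= tol
            and abs(s.rt - rt) <= self.rt_tol
        ]

    @staticmethod
    def _evidence_rank(ev: str) -> int:
        return {EVIDENCE_FULL: 3, EVIDENCE_HEAD_ONLY: 2, EVIDENCE_CERAMIDE_ONLY: 2}.get(ev, 0)

    def _best_outcome(
        self, spectra: list[Spectrum], candidate: GipcComposition
    ) -> RuleOutcome | None:
        best, best_key = None, None
        for s in spectra:
            out = evaluate(s, candidate, self.ruleset, self.registry)
            key = (self._evidence_rank(out.evidence), len(out.matched), out.passed)
            if best is None or key > best_key:
                best, best_key = out, key
        return best

    def _lcb_supported(self, outcome: RuleOutcome | None, candidate: GipcComposition) -> bool:
        """True when the candidate's complete W-fragment series matched."""
        if outcome is None or not candidate.ceramide.is_resolved:
            return False
        w_set = {"W", "W-H2O"}
        if candidate.ceramide.lcb.hydroxyls >= 3:
            w_set.add("W-2H2O")
        return w_set <= set(outcome.matched)

    # -- main ------------------------------------------------------------

    def annotate(
        self,
        features: Sequence[Feature],
        spectra: Sequence[Spectrum],
        candidates: Sequence[GipcComposition],
        run_isobar_check: bool = True,
        run_ecn_filter: bool = True,
    ) -> list[Annotation]:
        pos_features = [f for f in features if f.polarity == "+"]
        neg_features = [f for f in features if f.polarity == "-"]

        # group resolved candidates by sum-level composition (same formula)
        groups: dict[str, list[GipcComposition]] = defaultdict(list)
        for c in candidates:
            groups[c.sum_name].append(c)

        annotations: list[Annotation] = []
        for _, members in sorted(groups.items()):
            ann = self._annotate_group(members, pos_features, neg_features, spectra)
            if ann is not None:
                annotations.append(ann)

        if run_isobar_check:
            annotations = self._isobar_pass(annotations)
        if run_ecn_filter:
            ecn_filter(annotations)
        annotations.sort(key=lambda a: (a.rt if a.rt is not None else 0.0, a.name))
        return annotations

    def _annotate_group(
        self,
        members: list[GipcComposition],
        pos_features: list[Feature],
        neg_features: list[Feature],
        spectra: Sequence[Spectrum],
    ) -> Annotation | None:
        formula = gipc_formula(members[0], self.registry)
        pair = pair_features(
            pos_features, neg_features, formula, self.ms1_ppm, self.rt_tol, self.registry
        )
        if pair is None:
            return None

        flags: set[str] = set()
        if self.isotope_check and pair.positive.m1_area is not None and pair.positive.area > 0:
            pred = predicted_m1_ratio(formula)
            obs = pair.positive.m1_area / pair.positive.area
            if pred > 0 and abs(obs - pred) / pred > self.isotope_rel_tol:
                flags.add("isotope_mismatch")

        neg_mz = adduct_mz(formula, _NEG_ADDUCT, self.registry).mz
        pos_mz = adduct_mz(formula, pair.pos_adduct, self.registry).mz
        neg_spectra = self._spectra_for(spectra, neg_mz, pair.negative.rt, "-")
        pos_spectra = self._spectra_for(spectra, pos_mz, pair.positive.rt, "+")

        per_member: list[tuple[GipcComposition, RuleOutcome | None, RuleOutcome | None]] = []
        for m in members:
            neg_out = self._best_outcome(neg_spectra, m)
            pos_out = self._best_outcome(pos_spectra, m)
            per_member.append((m, neg_out, pos_out))

        supported = [
            (m, n, p) for (m, n, p) in per_member if self._lcb_supported(p, m)
        ]
        if len(supported) == 1:
            comp, neg_out, pos_out = supported[0]
            resolved = True
        else:
            # no unique LCB evidence: report at sum level with the best
            # per-polarity evidence among members
            def key(t):
                _, n, p = t
                return (
                    self._evidence_rank(n.evidence if n else EVIDENCE_NONE)
                    + self._evidence_rank(p.evidence if p else EVIDENCE_NONE),
                    len(n.matched) + len(p.matched) if n and p else 0,
                )

            comp_r, neg_out, pos_out = max(per_member, key=key)
            comp = comp_r.to_sum_level()
            resolved = False
            if len(supported) > 1:
                flags.add("lcb_ambiguous")

        evidence = Evidence(
            paired=True,
            negative=(neg_out.evidence if neg_out and neg_out.passed else EVIDENCE_NONE),
            positive=(pos_out.evidence if pos_out and pos_out.passed else EVIDENCE_NONE),
        )
        level = assign_level(evidence)
        if level == REJECT:
            return None
        ann = Annotation(
            composition=comp,
            level=level,
            pair=pair,
            outcomes={"-": neg_out, "+": pos_out},
            flags=flags,
            resolved=resolved,
        )
        return ann

    def _isobar_pass(self, annotations: list[Annotation]) -> list[Annotation]:
        by_formula: dict[tuple, list[Annotation]] = defaultdict(list)
        for a in annotations:
            f = gipc_formula(a.composition, self.registry)
            by_formula[f.counts].append(a)
        kept: list[Annotation] = []
        for group in by_formula.values():
            kept.extend(disambiguate_isobars(group))
        return kept
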