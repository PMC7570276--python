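"""Spectrum-vs-candidate evaluation: peak matching, evidence classes,
monotonicity, and agreement with a brute-force rule checker."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gipctools.fragments import predict_fragments
from gipctools.rules import (
    EVIDENCE_CERAMIDE_ONLY,
    EVIDENCE_FULL,
    EVIDENCE_HEAD_ONLY,
    EVIDENCE_NONE,
    Spectrum,
    default_ruleset,
    evaluate,
    match_peak,
)
from conftest import make_a


def spectrum_from(mzs, intensities=None, polarity="-", precursor=1260.7237, rt=15.9):
    mzs = np.asarray(mzs, dtype=float)
    if intensities is None:
        intensities = np.full(mzs.shape, 1000.0)
    return Spectrum(precursor, polarity, rt, mzs, np.asarray(intensities, float), "s1")


def spectrum_with_fragments(comp, polarity, names, extra=(), **kw):
    theo = predict_fragments(comp, polarity).by_name()
    mzs = [theo[n].mz for n in names] + list(extra)
    return spectrum_from(mzs, polarity=polarity, **kw)


class TestMatchPeak:
    def test_exact_match(self):
        s = spectrum_from([259.0224])
        assert match_peak(s, 259.0224, 0.005).mz == pytest.approx(259.0224)

    def test_highest_intensity_wins(self):
        s = spectrum_from([259.0220, 259.0228], [10.0, 500.0])
        assert match_peak(s, 259.0224, 0.005).mz == pytest.approx(259.0228)

    def test_tie_breaks_by_distance_then_mz(self):
        s = spectrum_from([259.0224, 259.0230], [100.0, 100.0])
        assert match_peak(s, 259.0224, 0.005).mz == pytest.approx(259.0224)
        s2 = spectrum_from([259.0220, 259.0228], [100.0, 100.0])
        assert match_peak(s2, 259.0224, 0.005).mz == pytest.approx(259.0220)

    def test_none_outside_tolerance(self):
        s = spectrum_from([597.30])
        assert match_peak(s, 597.107, 597.107 * 10e-6) is None

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            match_peak(spectrum_from([100.0]), 100.0, 0.0)


class TestEvaluate:
    def test_full_negative_evidence(self, a_oh_t181_h240):
        s = spectrum_with_fragments(
            a_oh_t181_h240,
            "-",
            ["H2PO4", "IP-H2O", "IP", "C3PO3-C1-CO2-H2O", "C3PO3-C1-CO2", "C3PO3-C1", "C3PO3"],
        )
        out = evaluate(s, a_oh_t181_h240)
        assert out.passed and out.evidence == EVIDENCE_FULL
        assert {"IP", "IP-H2O", "C3PO3"} <= set(out.matched)

    def test_head_only_negative_evidence(self, a_oh_t181_h240):
        s = spectrum_with_fragments(a_oh_t181_h240, "-", ["IP", "IP-H2O"])
        out = evaluate(s, a_oh_t181_h240)
        assert out.passed and out.evidence == EVIDENCE_HEAD_ONLY

    def test_missing_mandatory_fails(self, a_oh_t181_h240):
        s = spectrum_with_fragments(a_oh_t181_h240, "-", ["IP", "C3PO3"])  # no 241
        out = evaluate(s, a_oh_t181_h240)
        assert not out.passed
        assert out.failed_mandatory == ["IP-H2O"]
        assert out.evidence == EVIDENCE_NONE

    def test_positive_full_and_ceramide_only(self, a_oh_t181_h240):
        full = spectrum_with_fragments(
            a_oh_t181_h240, "+", ["IP+", "W", "W-H2O", "W-2H2O"], precursor=1262.7389
        )
        assert evaluate(full, a_oh_t181_h240).evidence == EVIDENCE_FULL
        cer = spectrum_with_fragments(
            a_oh_t181_h240, "+", ["W", "W-H2O", "W-2H2O"], precursor=1262.7389
        )
        assert evaluate(cer, a_oh_t181_h240).evidence == EVIDENCE_CERAMIDE_ONLY
        # IP+ alone is non-specific: no evidence class
        ip_only = spectrum_with_fragments(a_oh_t181_h240, "+", ["IP+"], precursor=1262.7389)
        assert evaluate(ip_only, a_oh_t181_h240).evidence == EVIDENCE_NONE

    def test_polarity_validation(self, a_oh_t181_h240):
        s = spectrum_from([259.0])
        s.polarity = "x"
        with pytest.raises(ValueError):
            evaluate(s, a_oh_t181_h240)

    def test_determinism(self, a_oh_t181_h240):
        s = spectrum_with_fragments(a_oh_t181_h240, "-", ["IP", "IP-H2O", "C3PO3"])
        o1, o2 = evaluate(s, a_oh_t181_h240), evaluate(s, a_oh_t181_h240)
        assert o1.matched == o2.matched and o1.evidence == o2.evidence

    def test_intensity_rule_when_enabled(self, a_oh_t181_h240):
        import dataclasses

        rs = dataclasses.replace(default_ruleset(), intensity_rules_enabled=True)
        theo = predict_fragments(a_oh_t181_h240, "-").by_name()
        # IP present but at 1% of the base peak -> fails the 5% relation
        s = spectrum_from(
            [theo["IP"].mz, theo["IP-H2O"].mz, 500.0], [10.0, 900.0, 1000.0]
        )
        out = evaluate(s, a_oh_t181_h240, rs)
        assert out.failed_intensity == ["IP"] and not out.passed
        # disabled by default: same spectrum passes
        assert evaluate(s, a_oh_t181_h240).passed


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

FRAGMENT_CHOICES_NEG = [
    "PO3", "H2PO4", "IP", "IP-H2O", "C3PO3", "C3PO3-C1", "C3PO3-C1-CO2",
    "C3PO3-C1-CO2-H2O", "Z0PO3", "Y1-H",
]
CANDIDATES = [
    make_a("OH", "t18:1", "h24:0"),
    make_a("NH2", "t18:0", "h22:0"),
    make_a("NAc", "d18:1", "n20:0"),
]


@settings(derandomize=True, max_examples=50)
@given(
    ci=st.integers(0, len(CANDIDATES) - 1),
    names=st.sets(st.sampled_from(FRAGMENT_CHOICES_NEG)),
    extra=st.lists(st.floats(100.0, 1200.0), max_size=5),
)
def test_adding_peaks_never_degrades_outcome(ci, names, extra):
    """With intensity rules disabled, fragment matching is existence-based, so
    supersets of peaks can only preserve or improve the outcome."""
    rank = {EVIDENCE_NONE: 0, EVIDENCE_HEAD_ONLY: 1, EVIDENCE_CERAMIDE_ONLY: 1, EVIDENCE_FULL: 2}
    comp = CANDIDATES[ci]
    base = spectrum_with_fragments(comp, "-", sorted(names))
    bigger = spectrum_with_fragments(comp, "-", sorted(names), extra=extra)
    out_base, out_big = evaluate(base, comp), evaluate(bigger, comp)
    assert set(out_base.matched) <= set(out_big.matched)
    assert rank[out_big.evidence] >= rank[out_base.evidence]
    if out_base.passed:
        assert out_big.passed


def brute_force_check(spectrum, candidate, rs):
    """Independent naive checker: every predicted fragment scanned against
    every peak; evidence classes re-derived from first principles."""
    predicted = predict_fragments(candidate, spectrum.polarity, rs.recipes)
    matched = set()
    for ion in predicted.ions:
        tol = max(ion.mz * rs.ms2_ppm * 1e-6, rs.ms2_da_floor)
        if any(abs(float(mz) - ion.mz) <= tol for mz in spectrum.mz):
            matched.add(ion.name)
    available = {i.name for i in predicted.ions}
    failed = sorted(
        r.fragment
        for r in rs.fragment_rules[spectrum.polarity]
        if r.mandatory and r.fragment in available and r.fragment not in matched
    )
    if spectrum.polarity == "-":
        if {"IP", "IP-H2O"} <= matched:
            sugar = matched & {"C3PO3", "C3PO3-C1-CO2", "C3PO3-C1-CO2-H2O"}
            evidence = EVIDENCE_FULL if sugar else EVIDENCE_HEAD_ONLY
        else:
            evidence = EVIDENCE_NONE
    else:
        has_head = bool(matched & {"IP+", "IP+Na"})
        has_cer = bool(matched & {"W", "W-H2O", "W-2H2O", "Z0", "Z0-H2O"})
        evidence = (
            EVIDENCE_FULL if has_head and has_cer
            else EVIDENCE_CERAMIDE_ONLY if has_cer
            else EVIDENCE_NONE
        )
    return matched, failed, evidence


@settings(derandomize=True, max_examples=80)
@given(
    ci=st.integers(0, len(CANDIDATES) - 1),
    polarity=st.sampled_from(["-", "+"]),
    seed=st.integers(0, 10_000),
    n_frag=st.integers(0, 8),
    n_noise=st.integers(0, 10),
)
def test_evaluate_agrees_with_brute_force(ci, polarity, seed, n_frag, n_noise):
    rng = np.random.default_rng(seed)
    comp = CANDIDATES[ci]
    rs = default_ruleset()
    theo = [i.mz for i in predict_fragments(comp, polarity).ions]
    chosen = rng.choice(theo, size=min(n_frag, len(theo)), replace=False) if theo else []
    mzs = list(chosen) + list(rng.uniform(100, 1300, size=n_noise))
    s = spectrum_from(mzs, polarity=polarity)
    out = evaluate(s, comp, rs)
    matched, failed, evidence = brute_force_check(s, comp, rs)
    assert set(out.matched) == matched
    assert sorted(out.failed_mandatory) == failed
    assert out.evidence == evidence
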