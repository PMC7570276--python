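"""MS1 pairing, confidence-level assignment, isobar disambiguation and the
retention-order (ECN) filter."""

import itertools

import pytest

from gipctools.annotate import (
    Annotation,
    Evidence,
    Feature,
    FeaturePair,
    LEVEL_2,
    LEVEL_3,
    LEVEL_3SS,
    REJECT,
    assign_level,
    disambiguate_isobars,
    ecn_filter,
    pair_features,
    predicted_m1_ratio,
)
from gipctools.chem import gipc_formula
from gipctools.rules import (
    EVIDENCE_CERAMIDE_ONLY,
    EVIDENCE_FULL,
    EVIDENCE_HEAD_ONLY,
    EVIDENCE_NONE,
)
from conftest import make_a


class TestPairFeatures:
    def setup_method(self):
        self.formula = gipc_formula(make_a("OH", "t18:1", "h24:0"))

    def test_dual_polarity_pair_within_5ppm(self):
        pos = [Feature(1262.7385, 15.90, 1e6, "+")]
        neg = [Feature(1260.7239, 15.92, 8e5, "-")]
        pair = pair_features(pos, neg, self.formula, ppm_tol=5, rt_tol=0.2)
        assert pair is not None
        assert pair.pos_adduct == "[M+H]+"
        assert abs(pair.pos_ppm) < 5 and abs(pair.neg_ppm) < 5
        assert pair.rt == pytest.approx(15.91)

    def test_rt_gate(self):
        pos = [Feature(1262.7385, 15.9, 1e6, "+")]
        neg = [Feature(1260.7239, 17.5, 8e5, "-")]
        assert pair_features(pos, neg, self.formula) is None

    def test_single_polarity_is_not_confirmed(self):
        neg = [Feature(1260.7239, 15.9, 8e5, "-")]
        assert pair_features([], neg, self.formula) is None

    def test_sodium_adduct_accepted(self):
        pos = [Feature(1284.7204, 15.9, 1e6, "+")]  # [M+Na]+
        neg = [Feature(1260.7239, 15.9, 8e5, "-")]
        pair = pair_features(pos, neg, self.formula)
        assert pair is not None and pair.pos_adduct == "[M+Na]+"

    def test_best_pair_by_combined_ppm(self):
        pos = [Feature(1262.7385, 15.9, 1e6, "+"), Feature(1262.7435, 15.9, 1e6, "+")]
        neg = [Feature(1260.7239, 15.9, 8e5, "-")]
        pair = pair_features(pos, neg, self.formula)
        assert pair.positive.mz == pytest.approx(1262.7385)


# exhaustive truth table, frozen literally from the tier definitions
LEVEL_TABLE = {
    (EVIDENCE_FULL, EVIDENCE_FULL): LEVEL_2,
    (EVIDENCE_FULL, EVIDENCE_CERAMIDE_ONLY): LEVEL_3SS,
    (EVIDENCE_FULL, EVIDENCE_NONE): LEVEL_3,
    (EVIDENCE_HEAD_ONLY, EVIDENCE_FULL): LEVEL_3SS,
    (EVIDENCE_HEAD_ONLY, EVIDENCE_CERAMIDE_ONLY): LEVEL_3SS,
    (EVIDENCE_HEAD_ONLY, EVIDENCE_NONE): LEVEL_3SS,
    (EVIDENCE_NONE, EVIDENCE_FULL): LEVEL_3,
    (EVIDENCE_NONE, EVIDENCE_CERAMIDE_ONLY): LEVEL_3SS,
    (EVIDENCE_NONE, EVIDENCE_NONE): REJECT,
}


class TestAssignLevel:
    def test_exhaustive_truth_table(self):
        for (neg, pos), expected in LEVEL_TABLE.items():
            assert assign_level(Evidence(True, neg, pos)) == expected, (neg, pos)

    def test_unpaired_always_rejects(self):
        for neg, pos in itertools.product(
            [EVIDENCE_FULL, EVIDENCE_HEAD_ONLY, EVIDENCE_NONE],
            [EVIDENCE_FULL, EVIDENCE_CERAMIDE_ONLY, EVIDENCE_NONE],
        ):
            assert assign_level(Evidence(False, neg, pos)) == REJECT

    def test_paper_examples(self):
        assert assign_level(Evidence(True, EVIDENCE_FULL, EVIDENCE_FULL)) == LEVEL_2
        assert assign_level(Evidence(True, EVIDENCE_FULL, EVIDENCE_NONE)) == LEVEL_3
        # positive MS2 with W fragments but no IP+ ions
        assert (
            assign_level(Evidence(True, EVIDENCE_NONE, EVIDENCE_CERAMIDE_ONLY)) == LEVEL_3SS
        )


def _ann(comp, rt, level=LEVEL_2, resolved=True):
    pos = Feature(1000.0, rt, 1e6, "+")
    neg = Feature(998.0, rt, 1e6, "-")
    pair = FeaturePair(pos, neg, "[M+H]+", 0.0, 0.0)
    return Annotation(composition=comp, level=level, pair=pair, resolved=resolved)


class TestEcnFilter:
    def test_consistent_carbon_order_passes(self):
        anns = [
            _ann(make_a("OH", "t18:1", "h22:0"), 14.8),
            _ann(make_a("OH", "t18:1", "h23:0"), 15.3),
            _ann(make_a("OH", "t18:1", "h24:0"), 15.9),
        ]
        ecn_filter(anns)
        assert all(not a.flags for a in anns)

    def test_carbon_inversion_flags_both(self):
        anns = [
            _ann(make_a("OH", "t18:1", "h22:0"), 15.9),
            _ann(make_a("OH", "t18:1", "h24:0"), 14.8),
        ]
        ecn_filter(anns)
        assert all("ecn_violation" in a.flags for a in anns)

    def test_double_bond_elutes_earlier_is_consistent(self):
        # t18:1 (extra double bond) before t18:0 at equal acyl: no flag —
        # but these sit in different LCB groups, so compare within one LCB
        anns = [
            _ann(make_a("OH", "t18:1", "h24:0"), 15.9),
            _ann(make_a("OH", "t18:1", "h24:1"), 15.1),
        ]
        ecn_filter(anns)
        assert all(not a.flags for a in anns)

    def test_double_bond_inversion_flags(self):
        anns = [
            _ann(make_a("OH", "t18:1", "h24:0"), 15.0),
            _ann(make_a("OH", "t18:1", "h24:1"), 15.8),
        ]
        ecn_filter(anns)
        assert all("ecn_violation" in a.flags for a in anns)

    def test_different_lcb_groups_not_compared(self):
        anns = [
            _ann(make_a("OH", "t18:0", "h24:0"), 16.1),
            _ann(make_a("OH", "t18:1", "h24:0"), 15.9),
        ]
        ecn_filter(anns)
        assert all(not a.flags for a in anns)


class TestIsobarDisambiguation:
    def _pair(self):
        nh2 = _ann(make_a("NH2", "t18:1", "h24:0"), 15.9, resolved=False)
        nac = _ann(make_a("NAc", "t18:0", "n22:0"), 15.9, resolved=False)
        return nh2, nac

    def test_c3po3_match_keeps_only_that_member(self, a_oh_t181_h240):
        from gipctools.fragments import predict_fragments
        from gipctools.rules import Spectrum, evaluate
        import numpy as np

        nh2, nac = self._pair()
        # spectrum carrying the NAc discriminator at nominal 638
        theo = predict_fragments(nac.composition, "-").by_name()
        mzs = [theo[n].mz for n in ("IP", "IP-H2O", "C3PO3-C1-CO2", "C3PO3")]
        s = Spectrum(1260.72, "-", 15.9, np.array(mzs), np.full(4, 1000.0), "s")
        nac.outcomes["-"] = evaluate(s, nac.composition)
        nh2.outcomes["-"] = evaluate(s, nh2.composition)
        kept = disambiguate_isobars([nh2, nac])
        assert kept == [nac]
        assert not nac.flags

    def test_shared_fragments_only_flags_both(self):
        import numpy as np
        from gipctools.fragments import predict_fragments
        from gipctools.rules import Spectrum, evaluate

        nh2, nac = self._pair()
        theo = predict_fragments(nh2.composition, "-").by_name()
        mzs = [theo[n].mz for n in ("IP", "IP-H2O", "C3PO3-C1-CO2")]  # 241/259/373
        s = Spectrum(1260.72, "-", 15.9, np.array(mzs), np.full(3, 1000.0), "s")
        for a in (nh2, nac):
            a.outcomes["-"] = evaluate(s, a.composition)
        kept = disambiguate_isobars([nh2, nac])
        assert len(kept) == 2
        assert all("isobar_ambiguous" in a.flags for a in kept)

    def test_w_series_resolves_lcb(self):
        nh2, nac = self._pair()
        nh2.resolved = True  # trihydroxylated LCB pinned by a triple W set
        kept = disambiguate_isobars([nh2, nac])
        assert kept == [nh2]

    def test_singleton_untouched(self):
        a = _ann(make_a("OH", "t18:1", "h24:0"), 15.9)
        assert disambiguate_isobars([a]) == [a]


def test_predicted_m1_ratio_tracks_carbon_count(a_oh_t181_h240):
    f = gipc_formula(a_oh_t181_h240)  # C60
    ratio = predicted_m1_ratio(f)
    assert 0.6 < ratio < 0.75
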