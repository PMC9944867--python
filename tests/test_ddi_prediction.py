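"""Mechanistic static model: AUCR forms, bounds, CI propagation, orchestration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transddi import (
    ExposureSet,
    InvalidInputError,
    KiInput,
    VictimModel,
    VictimPathway,
    aucr_combined,
    aucr_single,
    basic_static_flags,
    defaults,
    fraction_of_max_effect,
    overall_aucr,
    predict,
    propagate_ci,
    theoretical_max_aucr,
)
from transddi.util import round_half_up


class TestSinglePathway:
    def test_intestinal_efflux_example(self):
        assert round_half_up(aucr_single(0.5, 142.0, 42.2), 2) == 1.63

    def test_hepatic_uptake_example(self):
        assert round_half_up(aucr_single(0.38, 1.21, 9.53), 2) == 1.04

    def test_no_inhibitor_no_effect(self):
        for fe in (0.0, 0.3, 0.9):
            assert aucr_single(fe, 0.0, 1.0) == pytest.approx(1.0)

    def test_invalid_ki(self):
        with pytest.raises(InvalidInputError):
            aucr_single(0.5, 1.0, 0.0)


class TestCombinedHepatic:
    def test_pathway_weighted_reproduces_reference_values(self):
        atz = aucr_combined([0.38, 0.11, 0.21], 4.90, [0.734, 1.86, 65.6])
        lpv = aucr_combined([0.38, 0.11, 0.21], 0.450, [0.220, 5.04, 20.3])
        assert round_half_up(atz, 2) == 1.74
        assert round_half_up(lpv, 2) == 1.37

    def test_shared_denominator_form_differs(self):
        """The alternative form overstates the combined interaction."""
        weighted = aucr_combined([0.38, 0.11, 0.21], 4.90, [0.734, 1.86, 65.6])
        shared = aucr_combined(
            [0.38, 0.11, 0.21], 4.90, [0.734, 1.86, 65.6], form="shared_denominator"
        )
        assert shared > weighted
        assert round_half_up(shared, 2) == pytest.approx(2.72, abs=0.01)

    def test_single_pathway_reduction(self):
        assert aucr_combined([0.38], 1.5, [0.7]) == pytest.approx(
            aucr_single(0.38, 1.5, 0.7), rel=1e-12
        )

    def test_equal_potency_collapses_to_total_fe(self):
        fes = [0.38, 0.11, 0.21]
        combined = aucr_combined(fes, 2.0, [1.0, 1.0, 1.0])
        assert combined == pytest.approx(aucr_single(sum(fes), 2.0, 1.0), rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            aucr_combined([0.38, 0.11], 1.0, [1.0])


class TestOverall:
    def test_rounded_intermediate_product(self):
        assert round_half_up(overall_aucr([1.6272, 1.7386]), 2) == 2.84
        assert round_half_up(overall_aucr([1.5777, 1.3676]), 2) == 2.16

    def test_conventions_can_differ_in_final_digit(self):
        # darunavir: 1.20 × 1.04 = 1.248 -> 1.25 vs unrounded 1.2033 × 1.0447 -> 1.26
        site = [1.2033, 1.0447]
        assert round_half_up(overall_aucr(site, "table"), 2) == 1.25
        assert round_half_up(overall_aucr(site, "full"), 2) == 1.26

    def test_single_site_identity(self):
        assert overall_aucr([1.5], "full") == 1.5


class TestTheoreticalMax:
    @pytest.mark.parametrize(
        "fe, expected", [(0.7, 3.33), (0.0, 1.0), (0.38, 1.61), (0.5, 2.0)]
    )
    def test_limit_values(self, fe, expected):
        assert round_half_up(theoretical_max_aucr(fe), 2) == expected

    def test_complete_dependence_signalled(self):
        with pytest.raises(InvalidInputError):
            theoretical_max_aucr(1.0)


class TestFractionOfMax:
    def test_near_saturation(self):
        assert fraction_of_max_effect(1.09, 1.12) == pytest.approx(0.75)

    def test_small_perturbation(self):
        assert fraction_of_max_effect(1.01, 1.27) == pytest.approx(0.04, abs=0.005)

    def test_no_effect(self):
        assert fraction_of_max_effect(1.0, 1.5) == 0.0

    def test_degenerate_max(self):
        with pytest.raises(InvalidInputError):
            fraction_of_max_effect(1.0, 1.0)


class TestCIPropagation:
    def test_single_pathway_interval(self):
        lo, hi = propagate_ci(0.5, 142.0, (26.0, 58.4))
        assert round_half_up(lo, 2) == 1.55
        assert round_half_up(hi, 2) == 1.73

    def test_degenerate_interval(self):
        lo, hi = propagate_ci(0.38, 1.0, (2.0, 2.0))
        assert lo == hi == pytest.approx(aucr_single(0.38, 1.0, 2.0))

    def test_combined_interval_brackets_point(self):
        fes = [0.38, 0.11, 0.21]
        kis = [0.734, 1.86, 65.6]
        cis = [(0.294, 1.17), (0.620, 3.10), (39.0, 92.2)]
        lo, hi = propagate_ci(fes, 4.90, cis)
        point = aucr_combined(fes, 4.90, kis)
        assert lo <= point <= hi
        assert round_half_up(lo, 2) == 1.63
        assert round_half_up(hi, 2) == 1.92


class TestBasicStaticFlags:
    EXPOSURES = ExposureSet(igut=1702.0, ig=142.0, iin_max=35.0, iin_max_u=4.90, cmax_u=1.22)

    def test_hepatic_r_value_flagged(self):
        out = basic_static_flags("OATP1B1", "hepatic", self.EXPOSURES, 0.734)
        assert round_half_up(out["r_value"], 2) == 7.68
        assert out["flagged"]

    def test_intestinal_ratio_flagged(self):
        ex = ExposureSet(igut=2545.0, ig=42.4, iin_max=22.5, iin_max_u=0.450, cmax_u=0.292)
        out = basic_static_flags("BCRP", "intestinal", ex, 15.5)
        assert round_half_up(out["intestinal_ratio"], 0) == 164
        assert out["flagged"]

    def test_hepatic_below_threshold_not_flagged(self):
        ex = ExposureSet(igut=2545.0, ig=42.4, iin_max=22.5, iin_max_u=0.450, cmax_u=0.292)
        out = basic_static_flags("NTCP", "hepatic", ex, 20.3)
        assert round_half_up(out["r_value"], 2) == 1.02
        assert not out["flagged"]


class TestPredictOrchestration:
    def test_screen_negative_pathways_contribute_unity(self, victim, predictions):
        p = predictions["darunavir"]
        na = {a.transporter for a in p.assessments if a.no_inhibition}
        assert na == {"OATP1B3", "NTCP", "OAT3"}
        assert round_half_up(p.overall_aucr, 2) == 1.25

    def test_missing_pathway_evidence_names_transporter(self, victim, perpetrators):
        ex = defaults.report_exposure_set(perpetrators["atazanavir"])
        with pytest.raises(InvalidInputError, match="OATP1B3"):
            predict("atazanavir", victim, {"BCRP": KiInput(42.2), "OATP1B1": KiInput(0.734),
                                           "NTCP": KiInput(65.6), "OAT3": KiInput(1000.0)},
                    ex, screen_results={})

    def test_universal_non_inhibitor_predicts_unity(self, victim, perpetrators):
        ex = defaults.report_exposure_set(perpetrators["ritonavir"])
        huge = {p.transporter: KiInput(1e12) for p in victim.pathways}
        p = predict("nobody", victim, huge, ex)
        assert round_half_up(p.overall_aucr, 2) == 1.00

    def test_fold_accuracy_against_clinical(self, predictions):
        p = predictions["atazanavir"]
        assert p.clinical_aucr == 3.10
        assert p.fold_accuracy == pytest.approx(p.overall_aucr / 3.10)

    def test_empty_victim_model_rejected(self):
        with pytest.raises(InvalidInputError):
            VictimModel("empty", pathways=())

    def test_overall_bounded_by_theoretical_maxima(self, victim, predictions):
        cap = 1.0
        for site in ("intestinal", "hepatic", "renal"):
            fes = victim.site_pathways(site)
            cap *= theoretical_max_aucr(sum(p.fe for p in fes))
        for p in predictions.values():
            assert 1.0 <= p.overall_aucr <= cap
            lo, hi = p.overall_ci
            assert lo <= p.overall_aucr <= hi


@settings(max_examples=60, deadline=None)
@given(
    fe=st.floats(0.0, 0.95),
    ki=st.floats(0.01, 1e3),
    i1=st.floats(0.0, 1e4),
    i2=st.floats(0.0, 1e4),
)
def test_aucr_monotone_in_inhibitor_concentration(fe, ki, i1, i2):
    lo, hi = sorted((i1, i2))
    a_lo, a_hi = aucr_single(fe, lo, ki), aucr_single(fe, hi, ki)
    assert a_lo <= a_hi + 1e-12
    assert 1.0 <= a_lo <= theoretical_max_aucr(fe) + 1e-12


@settings(max_examples=60, deadline=None)
@given(
    fe=st.floats(0.01, 0.95),
    ki1=st.floats(0.01, 1e3),
    ki2=st.floats(0.01, 1e3),
    i=st.floats(0.0, 1e4),
)
def test_aucr_antimonotone_in_ki(fe, ki1, ki2, i):
    lo, hi = sorted((ki1, ki2))
    assert aucr_single(fe, i, lo) >= aucr_single(fe, i, hi) - 1e-12


def test_saturation_approaches_theoretical_max():
    for fe in (0.11, 0.38, 0.7):
        assert aucr_single(fe, 1e5, 1.0) == pytest.approx(
            theoretical_max_aucr(fe), rel=1e-3
        )


@settings(max_examples=40, deadline=None)
@given(
    i=st.floats(0.0, 1e3),
    k1=st.floats(0.01, 1e3),
    k2=st.floats(0.01, 1e3),
    k3=st.floats(0.01, 1e3),
)
def test_combined_bounded_by_total_fe_ceiling(i, k1, k2, k3):
    fes = [0.38, 0.11, 0.21]
    combined = aucr_combined(fes, i, [k1, k2, k3])
    assert 1.0 - 1e-12 <= combined <= 1.0 / (1.0 - sum(fes)) + 1e-12
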