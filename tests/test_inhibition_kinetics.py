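"""4PL fitting, IC50→Ki interpretation, occasion statistics, screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import grid_search_4pl
from transddi import (
    GroundTruth,
    InvalidInputError,
    ProbeAssayDesign,
    aggregate_occasions,
    fit_4pl,
    fit_occasions,
    fourpl,
    generate_flux_dataset,
    ic50_as_ki,
    interpret_screen,
    reduce_flux,
    report_rounded,
    t_quantile_975,
)


class TestFourPL:
    def test_midpoint_at_ic50(self):
        assert fourpl(10.0, 100.0, 0.0, 10.0, 1.0) == pytest.approx(50.0)

    def test_top_at_zero_concentration(self):
        assert fourpl(0.0, 98.0, 3.0, 10.0, 2.0) == pytest.approx(98.0)

    def test_hand_value(self):
        assert fourpl(30.0, 100.0, 0.0, 10.0, 1.0) == pytest.approx(25.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            fourpl(-1.0, 100.0, 0.0, 10.0, 1.0)


def synthetic_activity(ic50, hill=1.0, noise_cv=0.0, seed=0, n_occasions=1):
    truth = GroundTruth(ic50=ic50, hill=hill, noise_cv=noise_cv, occasion_cv=0.0)
    series = np.geomspace(ic50 / 100, ic50 * 100, 7)
    wells = generate_flux_dataset(truth, series, n_occasions=n_occasions, seed=seed)
    return reduce_flux(wells)


class TestFit4PL:
    def test_noise_free_self_consistency(self):
        activity = synthetic_activity(ic50=10.0)
        fit = fit_4pl(activity)
        assert fit.converged
        assert fit.ic50 == pytest.approx(10.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-5)

    def test_noisy_recovery_within_15_percent(self):
        activity = synthetic_activity(ic50=10.0, noise_cv=0.05, seed=42)
        fit = fit_4pl(activity)
        assert abs(fit.ic50 - 10.0) / 10.0 < 0.15

    @pytest.mark.parametrize("seed,true_ic50", [(1, 3.0), (2, 10.0), (3, 30.0)])
    def test_agrees_with_grid_search_oracle(self, seed, true_ic50):
        """The least-squares optimum matches an exhaustive (IC50, Hill) grid."""
        activity = synthetic_activity(ic50=true_ic50, noise_cv=0.08, seed=seed)
        fit = fit_4pl(activity)
        conc = activity["inhibitor_conc_uM"].to_numpy()
        y = activity["percent_control"].to_numpy()
        g_ic50, g_hill, *_, step = grid_search_4pl(
            conc, y, true_ic50 / 100, true_ic50 * 100
        )
        assert abs(np.log10(fit.ic50) - np.log10(g_ic50)) <= step

    @pytest.mark.parametrize("scale", [0.01, 1.0, 250.0])
    def test_scale_equivariance(self, scale):
        activity = synthetic_activity(ic50=10.0, noise_cv=0.05, seed=9)
        ref = fit_4pl(activity)
        scaled = activity.copy()
        scaled["inhibitor_conc_uM"] *= scale
        fit = fit_4pl(scaled)
        assert fit.ic50 == pytest.approx(scale * ref.ic50, rel=1e-4)
        assert fit.hill == pytest.approx(ref.hill, rel=1e-4)

    def test_extrapolation_flagged_when_curve_barely_drops(self):
        """Tested range far below the IC50: activity never falls under 50%."""
        truth = GroundTruth(ic50=500.0, noise_cv=0.02, occasion_cv=0.0)
        wells = generate_flux_dataset(truth, [0.3, 1.0, 3.0, 10.0, 30.0],
                                      n_occasions=1, seed=8)
        fit = fit_4pl(reduce_flux(wells))
        assert fit.extrapolated

    def test_too_few_concentrations_rejected(self):
        df = pd.DataFrame(
            {"inhibitor_conc_uM": [0, 1, 10, 100], "percent_control": [100, 80, 50, 20]}
        )
        with pytest.raises(InvalidInputError):
            fit_4pl(df)

    def test_one_fit_per_occasion(self):
        activity = synthetic_activity(ic50=10.0, noise_cv=0.05, seed=4, n_occasions=3)
        fits = fit_occasions(activity)
        assert set(fits) == {"occ1", "occ2", "occ3"}


class TestKiInterpretation:
    def test_low_probe_concentration_accepts_ic50(self):
        design = ProbeAssayDesign("BCRP", "estrone 3-sulfate", probe_conc=1.0, probe_km=7.4)
        est = ic50_as_ki(42.2, design)
        assert est.condition_ok
        assert est.ki == 42.2

    def test_probe_at_km_annotates_half(self):
        design = ProbeAssayDesign("X", "probe", probe_conc=5.0, probe_km=5.0)
        est = ic50_as_ki(10.0, design)
        assert not est.condition_ok
        assert est.cheng_prusoff_adjusted == pytest.approx(5.0)

    def test_vanishing_probe_concentration_limit(self):
        design = ProbeAssayDesign("X", "probe", probe_conc=1e-6, probe_km=10.0)
        est = ic50_as_ki(10.0, design)
        assert est.cheng_prusoff_adjusted == pytest.approx(10.0, rel=1e-6)


class TestTQuantile:
    @pytest.mark.parametrize("df, expected", [(3, 3.182), (2, 4.303)])
    def test_small_sample_values(self, df, expected):
        assert t_quantile_975(df) == pytest.approx(expected, abs=5e-4)

    def test_normal_limit(self):
        assert t_quantile_975(10**6) == pytest.approx(1.960, abs=1e-3)

    def test_invalid_df(self):
        with pytest.raises(InvalidInputError):
            t_quantile_975(0)


class TestAggregateOccasions:
    def test_four_occasion_row(self):
        s = aggregate_occasions([49.8, 30.3, 51.5, 37.1])
        r = report_rounded(s)
        assert (r["mean"], r["sd"], r["cv_percent"]) == (42.2, 10.2, 24.2)
        assert r["ci95"] == (26.0, 58.4)
        assert s.t_quantile == pytest.approx(3.182, abs=5e-4)

    def test_three_occasion_row(self):
        s = aggregate_occasions([5.14, 5.04, 4.95])
        r = report_rounded(s)
        assert (r["mean"], r["sd"], r["cv_percent"]) == (5.04, 0.0950, 1.9)
        assert r["ci95"] == (4.80, 5.28)

    def test_identical_replicates(self):
        s = aggregate_occasions([7.0, 7.0, 7.0])
        assert s.sd == 0.0
        assert s.ci95 == (7.0, 7.0)

    def test_single_occasion_has_mean_only(self):
        s = aggregate_occasions([12.0])
        assert s.mean == 12.0
        assert s.sd is None and s.ci95 is None

    def test_ci_brackets_mean(self, ki_summaries):
        for s in ki_summaries.values():
            lo, hi = s.ci95
            assert lo < s.mean < hi


class TestScreens:
    def test_no_inhibition_gives_no_ddi_potential(self):
        res = interpret_screen(100.0, tested_conc=15.0, transporter="OATP1B3")
        assert not res.inhibitor
        assert res.no_ddi_potential
        assert res.ki_lower_bound == 15.0

    def test_inhibition_escalates(self):
        res = interpret_screen(40.0, tested_conc=15.0)
        assert res.inhibitor and res.ki_lower_bound is None

    def test_exactly_fifty_percent_is_not_an_inhibitor(self):
        assert not interpret_screen(50.0, tested_conc=5.0).inhibitor


@settings(max_examples=30, deadline=None)
@given(
    mean=st.floats(0.1, 100.0),
    spread=st.floats(0.01, 0.5),
    n=st.integers(2, 6),
)
def test_cv_is_scale_free(mean, spread, n):
    """Multiplying all occasion IC50s by a constant leaves CV% unchanged."""
    vals = [mean * (1 + spread * ((-1) ** i) * (i / n)) for i in range(n)]
    a = aggregate_occasions(vals)
    b = aggregate_occasions([10 * v for v in vals])
    assert b.cv_percent == pytest.approx(a.cv_percent, rel=1e-9)
    assert b.mean == pytest.approx(10 * a.mean, rel=1e-12)
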