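"""Control band, activity classification, Hill fitting, AC50/AC_F rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import escreen as es
from escreen.doseresponse import (
    DomainError,
    InsufficientControlsError,
    ac_f,
    classify_activity,
    control_band,
)
from escreen.simulate import ZERO_NOISE

from conftest import hill_response, recovery_table

CONC = np.array([0.0125, 0.125, 1.25, 12.5])


def make_series(values, conc=CONC, controls=(1.0, 1.0, 1.0), axis="differentiation"):
    return es.ResponseSeries("X", axis, np.asarray(conc, float),
                             np.asarray(values, float), np.asarray(controls, float))


class TestControlBand:
    def test_zero_variance(self):
        band = control_band([1.0, 1.0, 1.0])
        assert band.low == band.high == band.mean == 1.0

    def test_arithmetic(self):
        band = control_band([0.9, 1.0, 1.1])
        assert band.mean == pytest.approx(1.0)
        assert band.sd == pytest.approx(0.1)
        assert band.low == pytest.approx(0.8)
        assert band.high == pytest.approx(1.2)

    def test_requires_two_controls(self):
        with pytest.raises(InsufficientControlsError):
            control_band([1.0])

    @given(st.lists(st.floats(0.1, 10.0), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_low_never_exceeds_high(self, values):
        band = control_band(values)
        assert band.low <= band.mean <= band.high


class TestClassifyActivity:
    # controls chosen so mean/SD are exactly representable: band = [0.5, 1.5]
    BAND = control_band([0.75, 1.0, 1.25])

    def test_within_band_is_none(self):
        assert classify_activity(make_series([1.0, 1.0, 1.0, 1.0]), self.BAND) == "none"

    def test_downward_trend(self):
        assert classify_activity(make_series([1.0, 0.9, 0.45, 0.1]), self.BAND) == "down"

    def test_upward_trend(self):
        assert classify_activity(make_series([1.0, 1.1, 1.6, 1.9]), self.BAND) == "up"

    def test_both_sided_is_ushape(self):
        assert classify_activity(make_series([1.6, 1.7, 0.4, 0.3]), self.BAND) == "ushape"

    def test_band_edges_inclusive(self):
        assert classify_activity(make_series([0.5, 1.5, 0.5, 1.5]), self.BAND) == "none"

    def test_duplicate_means_absorb_single_excursions(self):
        conc = np.repeat(CONC, 2)
        values = np.array([1.8, 0.9, 1.0, 1.0, 0.4, 0.3, 0.2, 0.1])
        series = make_series(values, conc=conc)
        assert classify_activity(series, self.BAND) == "down"
        assert classify_activity(series, self.BAND, aggregate=None) == "ushape"


class TestHillFit:
    @pytest.mark.parametrize("trend,ac50,slope,me", [
        ("down", 1.25, 1.0, 1.0),
        ("down", 0.3, 2.0, 0.8),
        ("up", 0.6, 1.2, 1.0),
        ("up", 2.5, 0.9, 0.7),
    ])
    def test_exact_data_recovery(self, trend, ac50, slope, me):
        conc = np.repeat(CONC, 2)
        values = hill_response(conc, ac50, slope, me, trend)
        fit = es.fit_hill(make_series(values, conc=conc), trend)
        assert fit.converged
        assert fit.ac50_param == pytest.approx(ac50, rel=0.01)
        assert fit.hillslope == pytest.approx(slope, rel=0.05)

    def test_upward_doubling_plateau_top_near_one(self):
        values = hill_response(CONC, 0.05, 2.0, 1.0, "up")  # saturates at 2.0
        fit = es.fit_hill(make_series(values), "up")
        assert fit.top == pytest.approx(1.0, abs=0.02)

    def test_flat_data_yields_no_crossing(self):
        fit = es.fit_hill(make_series([1.0, 1.0, 1.0, 1.0]), "down")
        assert fit.ac50_change() is None

    def test_requires_four_points(self):
        with pytest.raises(DomainError):
            es.HillCurveModel([1.0, 2.0, 3.0], [1, 1, 1], "down")

    def test_fitted_curves_are_monotone(self):
        rng = np.random.default_rng(4)
        conc = np.repeat(CONC, 2)
        values = hill_response(conc, 0.8, 1.3, 0.9, "down") * rng.lognormal(0, 0.05, conc.size)
        fit = es.fit_hill(make_series(values, conc=conc), "down")
        grid = fit.predict(np.logspace(-3, 2, 200))
        assert np.all(np.diff(grid) <= 1e-12)

    def test_unit_equivariance(self):
        conc_uM = np.repeat(CONC, 2)
        values = hill_response(conc_uM, 0.8, 1.3, 0.9, "down")
        fit_uM = es.fit_hill(make_series(values, conc=conc_uM), "down")
        fit_M = es.fit_hill(make_series(values, conc=conc_uM * 1e-6), "down")
        assert fit_M.ac50_change() * 1e6 == pytest.approx(fit_uM.ac50_change(), rel=1e-6)
        assert fit_M.hillslope == pytest.approx(fit_uM.hillslope, rel=1e-6)

    def test_summary_mentions_fit_quality(self):
        values = hill_response(CONC, 1.25, 1.0, 1.0, "down")
        fit = es.fit_hill(make_series(values), "down")
        text = fit.summary()
        assert "AC50" in text and "Hill slope" in text


class TestACF:
    def test_midpoint_fixed_point(self):
        assert ac_f(3.7, 2.2, 50.0) == pytest.approx(3.7)

    def test_known_values(self):
        assert ac_f(9.0, 1.0, 10.0) == pytest.approx(1.0)
        assert ac_f(1.0, 2.0, 90.0) == pytest.approx(3.0)

    def test_domain_errors(self):
        for bad_F in (0.0, 100.0, -5.0, 120.0):
            with pytest.raises(DomainError):
                ac_f(1.0, 1.0, bad_F)
        with pytest.raises(DomainError):
            ac_f(-1.0, 1.0, 50.0)
        with pytest.raises(DomainError):
            ac_f(1.0, 0.0, 50.0)

    @given(st.floats(0.01, 100.0), st.floats(0.3, 8.0),
           st.floats(1.0, 98.0), st.floats(0.5, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_F(self, ac50, slope, F, dF):
        assert ac_f(ac50, slope, min(F + dF, 99.0)) >= ac_f(ac50, slope, F)

    def test_consistent_with_fitted_curve_rootfinding(self):
        conc = np.repeat(CONC, 2)
        values = hill_response(conc, 0.9, 1.4, 1.0, "down")
        fit = es.fit_hill(make_series(values, conc=conc), "down")
        for F in (10.0, 30.0, 50.0, 80.0):
            target = 1.0 - F / 100.0
            root = brentq(lambda c: fit.predict(c) - target, 1e-8, 1e8, xtol=1e-12)
            assert ac_f(fit.ac50_change(), fit.hillslope, F) == pytest.approx(root, rel=1e-6)


class TestCallScreen:
    def test_zero_noise_null_chemicals_all_inactive(self, zero_noise_screen):
        _, truth, _, calls = zero_noise_screen
        inactive_chems = set(truth.loc[truth["endpoint"] == "none", "chemical"])
        assert inactive_chems  # sampler produces some inactives
        sub = calls[calls["chemical"].isin(inactive_chems)]
        assert not sub["active"].any()
        assert (sub["ac50_M"] == 1.0).all()

    def test_single_effect_chemical_called_only_there(self):
        chem = es.TruthChemical("A", (es.Effect("diff_decrease", 1.0, 1.2, 0.9),))
        none = es.TruthChemical("B", ())
        wells = es.generate_plate(es.PlateLayoutSpec(), [chem, none], ZERO_NOISE)
        calls = es.call_screen(es.process_screen(wells))
        a = calls[calls["chemical"] == "A"].set_index("endpoint")
        assert bool(a.loc["diff_decrease", "active"])
        assert not a.drop(index="diff_decrease")["active"].any()
        assert a.loc["diff_decrease", "ac50_M"] == pytest.approx(
            a.loc["diff_decrease", "ac50_uM"] * 1e-6)

    def test_inactive_calls_carry_exact_default(self, screen50):
        _, _, _, calls = screen50
        inactive = calls[~calls["active"]]
        assert (inactive["ac50_M"] == 1.0).all()

    def test_extrapolated_flag_definition(self, screen50):
        _, _, _, calls = screen50
        active = calls[calls["active"]]
        assert (active["extrapolated"] == (active["ac50_uM"] > 12.5)).all()

    def test_ushape_reported_without_ac50(self):
        chem = es.TruthChemical("U", (es.Effect("ushape", 0.5, 2.0, 0.8,
                                                axis="differentiation"),))
        wells = es.generate_plate(es.PlateLayoutSpec(), [chem], ZERO_NOISE)
        calls = es.call_screen(es.process_screen(wells))
        diff_rows = calls[(calls["chemical"] == "U")
                          & calls["endpoint"].str.startswith("diff")]
        assert (diff_rows["shape"] == "ushape").all()
        assert not diff_rows["active"].any()
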