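"""Tests for Q10 coefficients, the recruitment profile and egg-diameter fits."""

import numpy as np
import pandas as pd
import pytest

import copetherm as ct
from conftest import rate_frame, survival_frame


def _fit_from_params(p: ct.TPCParams, line: float) -> ct.TPCFit:
    """Wrap known cardinal parameters in a converged TPCFit."""
    return ct.TPCFit(
        rearing_temp=line, rmax=p.rmax, topt=p.topt, tmin=p.tmin, tmax=p.tmax,
        converged=True, ctmax=p.tmax, safety_margin=p.topt - line,
    )


def _survival_fit(a, b, c, line=19.0, duration=168.0) -> ct.SurvivalFit:
    return ct.SurvivalFit(
        rearing_temp=line, duration_h=duration, a=a, b=b, c=c,
        lt50=b, lt90=b + np.log(9) / a, converged=True,
    )


class TestQ10Regression:
    def test_exponential_rates_give_exact_q10(self):
        # R(T) = e^{0.105 T}  =>  Q10 = e^{1.05} for any grid of >= 2 points
        for temps in ([11, 19], [11.0, 15.0, 22.0, 26.0], [5.0, 6.0, 7.0]):
            temps = np.asarray(temps, float)
            slope, q10 = ct.q10_from_rates(temps, np.exp(0.105 * temps))
            assert slope == pytest.approx(0.105, abs=1e-12)
            assert q10 == pytest.approx(np.exp(1.05), rel=1e-12)

    def test_doubling_over_ten_degrees_gives_two(self):
        slope, q10 = ct.q10_from_rates([15.0, 25.0], [10.0, 20.0])
        assert q10 == pytest.approx(2.0, rel=1e-12)

    def test_flat_rates_give_unity(self):
        _, q10 = ct.q10_from_rates([10.0, 20.0, 30.0], [7.0, 7.0, 7.0])
        assert q10 == pytest.approx(1.0, abs=1e-12)

    def test_identity_exp_ten_slope(self, control_tpc):
        fit = _fit_from_params(control_tpc, 19.0)
        for phase in ("global", "cooling", "warming"):
            res = ct.q10(fit, phase, 19.0, ct.PAPER_GRID)
            assert res.q10 == pytest.approx(np.exp(10 * res.slope), rel=1e-12)

    def test_phase_windows(self, control_tpc):
        fit = _fit_from_params(control_tpc, 19.0)
        g = ct.q10(fit, "global", 19.0, ct.PAPER_GRID)
        c = ct.q10(fit, "cooling", 19.0, ct.PAPER_GRID)
        w = ct.q10(fit, "warming", 19.0, ct.PAPER_GRID)
        assert g.temperature_window == (11.0, control_tpc.topt)
        assert c.temperature_window == (11.0, 19.0)
        assert w.temperature_window == (19.0, control_tpc.topt)

    def test_cooling_exceeds_warming_below_optimum(self, control_tpc, warm_tpc):
        # below Topt the ln-rate curve is concave, so the cold flank is
        # steeper than the stretch between rearing temperature and Topt
        for p, rearing in ((control_tpc, 19.0), (warm_tpc, 25.0)):
            fit = _fit_from_params(p, rearing)
            cooling = ct.q10(fit, "cooling", rearing, ct.PAPER_GRID)
            warming = ct.q10(fit, "warming", rearing, ct.PAPER_GRID)
            assert warming.q10 < cooling.q10

    def test_unknown_phase_rejected(self, control_tpc):
        with pytest.raises(ct.ParameterError):
            ct.q10(_fit_from_params(control_tpc, 19.0), "sideways", 19.0, ct.PAPER_GRID)

    def test_window_without_two_positive_points_rejected(self, control_tpc):
        fit = _fit_from_params(control_tpc, 19.0)
        with pytest.raises((ct.InsufficientDataError, ct.ParameterError)):
            ct.q10(fit, "cooling", 19.0, [33.0, 34.0])


class TestRecruitment:
    def test_identical_lines_give_unit_fold(self, control_tpc):
        s = _survival_fit(2.75, 31.1, 0.85)
        t = _fit_from_params(control_tpc, 19.0)
        prof = ct.recruitment_profile(s, s, t, t)
        fold = prof.table["fold_change"].dropna()
        assert len(fold) > 0
        np.testing.assert_allclose(fold, 1.0, rtol=1e-12)

    def test_survival_ratio_drives_fold(self, control_tpc):
        # same fecundity curve; control survives 50% and warm ~100% at T = 25
        t = _fit_from_params(control_tpc, 19.0)
        s_control = _survival_fit(2.0, 25.0, 1.0)   # S(25) = 0.5
        s_warm = _survival_fit(2.0, 60.0, 1.0)      # S(25) ~ 1
        prof = ct.recruitment_profile(s_control, s_warm, t, t)
        assert prof.fold_at(25.0) == pytest.approx(2.0, abs=1e-6)

    def test_fold_scale_invariance(self, control_tpc, warm_tpc):
        s_c, s_w = _survival_fit(2.75, 31.1, 0.85), _survival_fit(1.7, 31.4, 0.85)
        base = ct.recruitment_profile(
            s_c, s_w, _fit_from_params(control_tpc, 19.0),
            _fit_from_params(warm_tpc, 25.0),
        )
        scaled = ct.recruitment_profile(
            s_c, s_w,
            _fit_from_params(ct.TPCParams(3 * 98.2, 26.4, 6.0, 32.1), 19.0),
            _fit_from_params(ct.TPCParams(3 * 83.5, 26.9, 6.0, 32.4), 25.0),
        )
        np.testing.assert_allclose(
            base.table["fold_change"], scaled.table["fold_change"], rtol=1e-9
        )

    def test_warm_advantage_at_hot_tail_only(self, control_tpc, warm_tpc):
        # warm line: higher survival midpoint and higher Tmax -> fold > 1 only
        # in the hot tail, < 1 at mid-range where control fecundity dominates
        s_c = _survival_fit(2.75, 31.1, 0.85)
        s_w = _survival_fit(1.7, 31.4, 0.85)
        prof = ct.recruitment_profile(
            s_c, s_w, _fit_from_params(control_tpc, 19.0),
            _fit_from_params(warm_tpc, 25.0),
        )
        assert prof.fold_at(25.0) < 1.0
        assert prof.fold_at(31.8) > 1.0

    def test_recruitment_zero_where_fecundity_zero(self, control_tpc):
        s = _survival_fit(2.0, 31.0, 0.9)
        t = _fit_from_params(control_tpc, 19.0)
        prof = ct.recruitment_profile(s, s, t, t)
        first = prof.table.iloc[0]
        assert first["temperature"] == pytest.approx(control_tpc.tmin)
        assert first["recruitment_control"] == 0.0

    def test_undefined_fold_is_nan_not_zero_or_inf(self, control_tpc):
        s = _survival_fit(2.0, 31.0, 0.9)
        t = _fit_from_params(control_tpc, 19.0)
        prof = ct.recruitment_profile(s, s, t, t)
        undefined = prof.table[
            prof.table["recruitment_control"] <= prof.fold_floor
        ]["fold_change"]
        assert undefined.isna().all()

    def test_unconverged_fit_rejected(self, control_tpc):
        s = _survival_fit(2.0, 31.0, 0.9)
        bad = _fit_from_params(control_tpc, 19.0)
        bad.converged = False
        with pytest.raises(ct.ParameterError):
            ct.recruitment_profile(s, s, bad, _fit_from_params(control_tpc, 19.0))


class TestEggDiameter:
    def _frame(self, d0=80.0, k=0.004, sd=0.0, seed=0, lines=(19.0, 25.0),
               n_eggs=5):
        design = ct.ExperimentDesign(
            rearing_temperatures=lines,
            exposure_durations=(24.0,) if len(lines) == 1 else (24.0, 168.0),
        )
        truth = ct.TruthParameters(
            survival={(line, d): ct.SurvivalParams(3.0, 32.5, 0.98)
                      for line in lines for d in design.exposure_durations},
            tpc={line: ct.TPCParams(98.2, 26.4, 6.0, 32.1) for line in lines},
            egg_diameter=ct.EggDiameterTruth(d0=d0, k=k, sd=sd),
        )
        return ct.generate_egg_diameters(design, truth, n_eggs, seed)

    def test_noiseless_fit_is_exact(self):
        df = self._frame()
        fit = ct.fit_egg_diameter(df, 19.0)
        assert fit.slope == pytest.approx(-0.004, abs=1e-12)
        assert fit.intercept == pytest.approx(np.log(80.0), abs=1e-12)
        assert fit.d0 == pytest.approx(80.0, rel=1e-10)
        assert fit.k == pytest.approx(0.004, abs=1e-12)

    def test_nonpositive_diameters_rejected(self):
        df = self._frame()
        df.loc[0, "diameter_um"] = 0.0
        with pytest.raises(ct.ParameterError):
            ct.fit_egg_diameter(df, 19.0)

    def test_comparison_reports_f_statistics_in_standard_format(self):
        import re

        df = self._frame(sd=1.5, seed=3)
        cmp = ct.compare_egg_diameter(df)
        assert re.fullmatch(r"F_1,\d+ = \d+\.\d\d; P = .+",
                            cmp.format_interaction())
        assert 0.0 <= cmp.interaction_p <= 1.0
        assert 0.0 <= cmp.offset_p <= 1.0

    def test_identical_truth_rarely_flags_significance(self):
        # type-I error of the slope-difference test stays near alpha = 0.05
        hits = 0
        n_sims = 200
        for seed in range(n_sims):
            df = self._frame(sd=1.5, seed=seed, n_eggs=10)
            cmp = ct.compare_egg_diameter(df)
            hits += cmp.interaction_p < 0.05
        assert 0.01 * n_sims <= hits <= 0.10 * n_sims

    def test_too_few_temperatures_rejected(self):
        df = self._frame()
        df = df[df["test_temp"].isin([19.0, 25.0])]
        with pytest.raises(ct.InsufficientDataError):
            ct.fit_egg_diameter(df, 19.0)
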