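"""Calibration, phase segmentation, exponential fitting, pH response."""

import numpy as np
import pytest

from valveform import kinetics as kin
from valveform import synthetic as syn
from valveform.imaging import FluorescenceTrace


def _trace(times, signal, cell_id=0):
    return FluorescenceTrace(
        cell_id=cell_id,
        times=np.asarray(times, dtype=float),
        signal=np.asarray(signal, dtype=float),
        clipped=np.zeros(len(times), dtype=bool),
    )


class TestIntensityCalibration:
    def test_exact_line_recovered(self):
        c = np.array([0.0, 10.0, 20.0, 30.0])
        line = kin.fit_intensity_calibration(c, 2.0 * c + 5.0)
        assert line.slope == pytest.approx(2.0)
        assert line.intercept == pytest.approx(5.0)
        assert line.r2 == pytest.approx(1.0)

    def test_nine_point_design_slope_within_five_percent(self):
        # the 9-level 0-62.5 µM design with replicate noise
        rng = np.random.default_rng(0)
        table = syn.generate_dilution_series(
            slope=50.0, intercept=120.0, noise=40.0, n_replicates=50, seed=1
        )
        model = kin.IntensityCalibrationModel.from_dataframe(table)
        line = model.fit()
        assert line.domain == (0.0, 62.5)
        assert line.slope == pytest.approx(50.0, rel=0.05)

    def test_insufficient_levels_rejected(self):
        with pytest.raises(ValueError):
            kin.fit_intensity_calibration([1.0, 1.0, 1.0], [2.0, 2.1, 1.9])
        with pytest.raises(ValueError):
            kin.fit_intensity_calibration([1.0, 2.0], [2.0, 4.0])


class TestToConcentration:
    def _calib(self):
        return kin.CalibrationLine(
            slope=2.0, intercept=10.0, domain=(0.0, 60.0), r2=1.0,
            slope_stderr=0.0, residual_std=0.0,
        )

    def test_signal_at_intercept_is_zero(self):
        tr = _trace([0, 5, 10, 15, 20], [10.0] * 5)
        out = kin.to_concentration(tr, self._calib(), biovolume_um3=2.0)
        assert np.all(out.concentration == 0.0)

    def test_doubling_biovolume_halves_concentration(self):
        tr = _trace([0, 5, 10], [30.0, 50.0, 70.0])
        c1 = kin.to_concentration(tr, self._calib(), 1.0).concentration
        c2 = kin.to_concentration(tr, self._calib(), 2.0).concentration
        assert np.allclose(c1, 2 * c2)

    def test_round_trip_with_dilution_series(self):
        table = syn.generate_dilution_series(slope=50.0, intercept=120.0, noise=0.0)
        line = kin.IntensityCalibrationModel.from_dataframe(table).fit()
        conc = np.array([5.0, 25.0, 50.0])
        tr = _trace([0, 5, 10], line.intensity(conc))
        out = kin.to_concentration(tr, line, biovolume_um3=1.0)
        assert np.allclose(out.concentration, conc)

    def test_extrapolation_flagged(self):
        tr = _trace([0, 5, 10], [10.0, 50.0, 200.0])
        out = kin.to_concentration(tr, self._calib(), 1.0)
        assert out.extrapolated[2]  # (200-10)/2 = 95 µM > 60 µM domain end
        assert not out.extrapolated[1]


class TestSegmentPhases:
    def test_strictly_increasing_has_no_decay(self, default_times):
        tr = _trace(default_times, np.exp(0.01 * default_times))
        seg = kin.segment_phases(tr)
        assert seg.i_f2 is None
        assert seg.i_f1 == len(default_times) - 1

    def test_two_phase_trace_f1_within_one_frame(
        self, default_times, two_phase_params
    ):
        f = syn.simulate_trace(two_phase_params, default_times)
        seg = kin.segment_phases(_trace(default_times, f))
        assert abs(default_times[seg.i_f1] - 90.0) <= 5.0
        assert seg.i_f2 is not None
        assert abs((default_times[seg.i_f2] - default_times[seg.i_f1]) - 47.0) <= 5.0

    def test_pre_peak_rule_excludes_late_starters(self, two_phase_params):
        # trace starts 60 min in: only 30 min of data before the maximum
        times = np.arange(60.0, 155.0, 5.0)
        f = syn.simulate_trace(two_phase_params, times)
        seg = kin.segment_phases(_trace(times - times[0], f))
        assert not seg.pre_peak_ok

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            kin.segment_phases(_trace([0, 5, 10, 15], [1, 2, 3, 4]))


class TestExponentialPhaseFit:
    def test_pure_exponential_recovered_exactly(self, default_times):
        tr = _trace(default_times, 3.0 * np.exp(0.02 * default_times))
        fit = kin.fit_exponential_phase(tr)
        assert fit.k == pytest.approx(0.02)
        assert fit.F0 == pytest.approx(3.0)
        assert fit.fit_r == pytest.approx(1.0)
        assert fit.accepted

    def test_noisy_k_unbiased_within_two_percent(self, default_times):
        rng = np.random.default_rng(3)
        ks = []
        for _ in range(200):
            f = 3.0 * np.exp(0.02 * default_times[:20])
            y = f * (1 + rng.normal(0, 0.1, 20))
            fit = kin.fit_exponential_phase(
                _trace(default_times[:20], np.clip(y, 1e-6, None))
            )
            assert abs(fit.k - 0.02) / 0.02 < 0.35
            ks.append(fit.k)
        assert abs(np.mean(ks) - 0.02) / 0.02 < 0.02

    def test_white_noise_rejected_by_r_filter(self, default_times):
        rng = np.random.default_rng(4)
        accepted = 0
        for _ in range(50):
            y = np.abs(rng.normal(100, 10, len(default_times))) + 1
            try:
                fit = kin.fit_exponential_phase(_trace(default_times, y))
                accepted += fit.accepted
            except ValueError:
                pass
        assert accepted == 0

    def test_nonpositive_window_raises(self, default_times):
        y = np.linspace(-1.0, 10.0, len(default_times))
        with pytest.raises(ValueError, match="non-positive"):
            kin.fit_exponential_phase(_trace(default_times, y))

    def test_time_shift_changes_f0_not_k(self, default_times, two_phase_params):
        f = syn.simulate_trace(two_phase_params, default_times)
        fit0 = kin.fit_exponential_phase(_trace(default_times, f))
        fit1 = kin.fit_exponential_phase(_trace(default_times + 30.0, f))
        assert fit1.k == pytest.approx(fit0.k, rel=1e-9)
        assert fit1.F0 == pytest.approx(fit0.F0 * np.exp(-fit0.k * 30.0), rel=1e-6)
        assert fit1.F1 - fit1.F0 != pytest.approx(0.0)
        assert fit1.t_exp == pytest.approx(fit0.t_exp)
        assert fit1.t_dec == pytest.approx(fit0.t_dec)

    def test_scale_equivariance(self, default_times, two_phase_params):
        f = syn.simulate_trace(two_phase_params, default_times)
        fit0 = kin.fit_exponential_phase(_trace(default_times, f))
        fit5 = kin.fit_exponential_phase(_trace(default_times, 5 * f))
        assert fit5.k == pytest.approx(fit0.k, rel=1e-9)
        assert fit5.fit_r == pytest.approx(fit0.fit_r, rel=1e-9)
        assert fit5.F0 == pytest.approx(5 * fit0.F0, rel=1e-6)
        assert fit5.F1 == pytest.approx(5 * fit0.F1, rel=1e-9)
        assert fit5.F2 == pytest.approx(5 * fit0.F2, rel=1e-9)

    def test_summary_prints_key_fields(self, default_times, two_phase_params):
        f = syn.simulate_trace(two_phase_params, default_times)
        text = kin.fit_exponential_phase(_trace(default_times, f)).summary()
        assert "k  [1/min]" in text and "t_Exp" in text and "accepted" in text


class TestPhaseDeltas:
    def test_deltas_and_no_decay_flag(self, default_times, two_phase_params):
        f = syn.simulate_trace(two_phase_params, default_times)
        fit = kin.fit_exponential_phase(_trace(default_times, f))
        d_exp, d_dec = kin.phase_deltas(fit)
        assert d_exp == pytest.approx(fit.F1 - fit.F0)
        assert d_dec == pytest.approx(fit.F1 - fit.F2)
        assert d_exp >= 0 and d_dec >= 0
        # monotone trace: decay delta undefined
        tr = _trace(default_times, np.exp(0.01 * default_times))
        fit2 = kin.fit_exponential_phase(tr)
        assert kin.phase_deltas(fit2)[1] is None

    def test_cohort_deltas_match_truth_within_ten_percent(self, default_times):
        rng = np.random.default_rng(5)
        p = syn.KineticParams(k=0.013, F0=200.0, t_peak=90.0, t_dec=47.0)
        f = syn.simulate_trace(p, default_times)
        sigma = syn.trace_noise_sigma(f.max(), 6.0, 10.0)
        d_exp_true = f.max() - 200.0
        d_dec_true = f.max() * 0.5
        d_exps, d_decs = [], []
        for _ in range(100):
            y = np.clip(f + rng.normal(0, sigma, f.shape), 1e-6, None)
            fit = kin.fit_exponential_phase(_trace(default_times, y))
            de, dd = kin.phase_deltas(fit)
            d_exps.append(de)
            if dd is not None:
                d_decs.append(dd)
        assert np.median(d_exps) == pytest.approx(d_exp_true, rel=0.10)
        assert np.median(d_decs) == pytest.approx(d_dec_true, rel=0.10)


class TestPHResponse:
    PH_GRID = (6.4, 6.8, 7.3, 7.8, 8.2)

    def test_exact_exponential_recovered(self):
        ph = np.array(self.PH_GRID)
        y = 1.1e-3 * np.exp(0.32 * ph)
        fit = kin.fit_ph_dependence(ph, y)
        assert fit.a == pytest.approx(1.1e-3, rel=1e-6)
        assert fit.b == pytest.approx(0.32, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_fold_change_identity(self):
        ph = np.array(self.PH_GRID)
        fit = kin.fit_ph_dependence(ph, 2.0 * np.exp(1.5 * ph))
        assert fit.fold_change() == pytest.approx(np.exp(1.5 * 1.8), rel=1e-6)

    def test_most_basic_level_excluded_from_domain(self):
        ph = np.array(list(self.PH_GRID) + [8.5])
        y = 1e-4 * np.exp(1.5 * ph)
        y[-1] = 1e-12  # a wild outlier at pH 8.5 must not perturb the fit
        fit = kin.fit_ph_dependence(ph, y, domain=(6.4, 8.2))
        assert fit.b == pytest.approx(1.5, rel=1e-6)
        assert fit.n_levels == 5

    def test_noisy_levels_recover_b_within_ten_percent(self):
        rng = np.random.default_rng(6)
        ph = np.repeat(self.PH_GRID, 30)
        y = 1.1e-3 * np.exp(0.32 * ph) * (1 + rng.normal(0, 0.2, len(ph)))
        fit = kin.fit_ph_dependence(ph, np.clip(y, 1e-9, None))
        assert fit.b == pytest.approx(0.32, rel=0.10)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            kin.fit_ph_dependence([6.4, 7.0], [1.0, 2.0])
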