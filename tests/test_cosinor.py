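"""Cosinor rhythmometry: parameter recovery, zero-amplitude test, group
aggregation with circular acrophase statistics."""

import numpy as np
import pytest

from cardiotel import (
    ChannelSeries,
    CircadianGenSpec,
    ExperimentDesign,
    acrophase_to_hours,
    cosinor_by_condition,
    fit_cosinor,
    gen_circadian,
    gen_experiment,
    group_cosinor,
)
from cardiotel.cosinor import CosinorFit, _population_mean_test, wrap_angle


def make_series(hours, values, design, channel="temperature_subcutaneous", subject="m01"):
    t0 = np.datetime64("2022-02-07T00:00:00")
    t = t0 + (np.asarray(hours) * 3600e9).astype("timedelta64[ns]")
    return ChannelSeries.build(t, values, channel, subject, design)


class TestFit:
    def test_exact_recovery_simple_cosine(self, design):
        h = np.arange(0, 72, 2.0)
        y = 10 + 2 * np.cos(2 * np.pi * h / 24)
        fit = fit_cosinor(make_series(h, y, design))
        assert fit.mesor == pytest.approx(10.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.acrophase == pytest.approx(0.0, abs=1e-9)
        assert fit.p_rhythm == 0.0  # noiseless fit underflows

    def test_recovery_of_control_temperature_parameters(self, design):
        """Noiseless generation at (33.81, 0.78, -0.69) on a 2 h grid over
        3 days is recovered to machine precision."""
        spec = CircadianGenSpec(mesor=33.81, amplitude=0.78, acrophase=-0.69,
                                sampling_interval_min=120.0, days=3)
        fit = fit_cosinor(gen_circadian(spec, design))
        assert fit.mesor == pytest.approx(33.81, abs=1e-9)
        assert fit.amplitude == pytest.approx(0.78, abs=1e-9)
        assert fit.acrophase == pytest.approx(-0.69, abs=1e-9)

    def test_constant_shift_moves_only_mesor(self, design):
        h = np.arange(0, 48, 1.0)
        y = 5 + 1.5 * np.cos(2 * np.pi * h / 24 + 1.0)
        f1 = fit_cosinor(make_series(h, y, design))
        f2 = fit_cosinor(make_series(h, y + 7.25, design))
        assert f2.mesor == pytest.approx(f1.mesor + 7.25, abs=1e-9)
        assert f2.amplitude == pytest.approx(f1.amplitude, abs=1e-9)
        assert f2.acrophase == pytest.approx(f1.acrophase, abs=1e-9)

    def test_time_shift_moves_acrophase_by_omega_delta(self, design):
        h = np.arange(0, 48, 0.5)
        y = 3 + np.cos(2 * np.pi * h / 24 - 0.4)
        f1 = fit_cosinor(make_series(h, y, design))
        delta = 5.0  # shift timestamps later by 5 h
        f2 = fit_cosinor(make_series(h + delta, y, design))
        expected = wrap_angle(f1.acrophase - 2 * np.pi * delta / 24)
        assert f2.acrophase == pytest.approx(expected, abs=1e-9)
        assert f2.amplitude == pytest.approx(f1.amplitude, abs=1e-9)

    def test_residuals_orthogonal_to_regressors(self, design):
        rng = np.random.default_rng(3)
        h = np.arange(0, 72, 1.0)
        y = 20 + 3 * np.cos(2 * np.pi * h / 24 + 0.7) + rng.normal(0, 1, len(h))
        fit = fit_cosinor(make_series(h, y, design))
        omega = 2 * np.pi / 24
        resid = y - (fit.mesor + fit.beta * np.cos(omega * h) + fit.gamma * np.sin(omega * h))
        scale = np.abs(y).max() * len(h)
        for reg in (np.ones_like(h), np.cos(omega * h), np.sin(omega * h)):
            assert abs(resid @ reg) < 1e-6 * scale

    def test_guards(self, design):
        h = np.arange(0, 12, 2.0)  # only half a period
        with pytest.raises(ValueError, match="full period"):
            fit_cosinor(make_series(h, np.ones_like(h), design))
        h = np.array([0.0, 24.0, 48.0, 72.0])  # single clock time
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_cosinor(make_series(h, np.ones(4), design))
        with pytest.raises(ValueError, match=">= 4 samples"):
            fit_cosinor(make_series([0.0, 8, 25], np.ones(3), design))

    def test_acrophase_hours_conversion(self):
        assert acrophase_to_hours(0.0) == 0.0
        assert acrophase_to_hours(-np.pi / 2) == pytest.approx(6.0)
        assert acrophase_to_hours(np.pi) == pytest.approx(12.0)


class TestRhythmTest:
    def test_type_one_error_calibration_quick(self, design):
        """Null (A=0) rejection rate at alpha=.05 over 200 series."""
        rng = np.random.default_rng(0)
        h = np.arange(0, 72, 2.0)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            y = 10 + rng.normal(0, 1, len(h))
            fit = fit_cosinor(make_series(h, y, design))
            rejections += fit.p_rhythm < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.04)

    def test_power_at_strong_rhythm(self, design):
        """A/sigma = 5 at n = 36 detects the rhythm essentially always."""
        rng = np.random.default_rng(1)
        h = np.arange(36) * 2.0
        hits = 0
        for _ in range(50):
            y = 10 + 5 * np.cos(2 * np.pi * h / 24 + 0.3) + rng.normal(0, 1, 36)
            fit = fit_cosinor(make_series(h, y, design))
            hits += fit.p_rhythm < 0.001
        assert hits >= 49


class TestGroup:
    def _fit(self, phi, beta=None, gamma=None, subject="m01"):
        beta = np.cos(phi) if beta is None else beta
        gamma = -np.sin(phi) if gamma is None else gamma
        return CosinorFit(mesor=10.0, amplitude=float(np.hypot(beta, gamma)),
                          acrophase=phi, period_h=24.0, beta=beta, gamma=gamma,
                          rss=1.0, mss=5.0, n=36, p_rhythm=0.01,
                          channel="hr", subject_id=subject)

    def test_identical_fits_have_zero_dispersion(self):
        g = group_cosinor([self._fit(0.5, subject=f"m{i}") for i in range(4)])
        assert g.mesor_sd == 0.0
        assert g.amplitude_sd == 0.0
        assert g.acrophase_mean == pytest.approx(0.5)
        assert g.acrophase_sd == pytest.approx(0.0, abs=1e-12)

    def test_circular_mean_across_branch_cut(self):
        # arithmetic mean of {+3, -3} is 0; the circular mean is pi
        g = group_cosinor([self._fit(3.0), self._fit(-3.0), self._fit(3.0),
                           self._fit(-3.0)])
        assert abs(g.acrophase_mean) == pytest.approx(np.pi, abs=1e-9)

    def test_mixed_channels_rejected(self):
        a = self._fit(0.1)
        b = self._fit(0.1)
        b.channel = "sbp"
        with pytest.raises(ValueError, match="mixed channels"):
            group_cosinor([a, b])

    def test_population_mean_test_calibration(self):
        """Null (beta, gamma) scatter about zero: p uniform-ish, signal
        concentrated away from zero: p tiny."""
        rng = np.random.default_rng(2)
        null_p = [
            _population_mean_test(rng.normal(0, 1, 8), rng.normal(0, 1, 8))
            for _ in range(200)
        ]
        assert 0.01 < np.mean(np.array(null_p) < 0.05) < 0.12
        strong = _population_mean_test(rng.normal(5, 0.3, 8), rng.normal(-3, 0.3, 8))
        assert strong < 1e-6

    def test_group_recovery_from_synthetic_cohort(self, design):
        spec = CircadianGenSpec(mesor=33.81, amplitude=0.78, acrophase=-0.69,
                                noise_sd=0.3, sampling_interval_min=30.0, days=3)
        fits = []
        for i in range(8):
            s = gen_circadian(
                CircadianGenSpec(**{**spec.__dict__, "seed": i}), design,
                subject_id=f"m{i:02d}")
            fits.append(fit_cosinor(s))
        g = group_cosinor(fits)
        se_m = g.mesor_sd / np.sqrt(8)
        assert abs(g.mesor_mean - 33.81) < 2 * se_m + 1e-6
        assert abs(g.amplitude_mean - 0.78) < 0.1
        assert abs(g.acrophase_mean - (-0.69)) < 0.1
        assert g.p_rhythm_group < 0.01


class TestByCondition:
    def test_amplitude_attenuation_recovered(self, design):
        data = gen_experiment(n_subjects=4, seed=9, include_beats=False)
        temps = [s for s in data.channels if s.channel == "temperature_subcutaneous"]
        table, groups = cosinor_by_condition(temps, design)
        ctrl = table.loc["Amplitude", "Control"]
        hu = table.loc["Amplitude", "Unloading"]
        assert hu / ctrl == pytest.approx(0.3, abs=0.12)
        assert table.loc["MESOR", "Unloading"] < table.loc["MESOR", "Control"]
        assert table.loc["n", "Control"] == 4

    def test_short_phase_left_missing(self, design):
        # only control days present: Unloading/Recovery cells stay NaN
        spec = CircadianGenSpec(sampling_interval_min=60.0, days=3)
        series = [gen_circadian(CircadianGenSpec(**{**spec.__dict__, "seed": i}),
                                design, subject_id=f"m{i}") for i in range(3)]
        table, groups = cosinor_by_condition(series, design)
        assert "Unloading" not in groups
        assert np.isnan(table.loc["MESOR", "Unloading"])
        assert not np.isnan(table.loc["MESOR", "Control"])
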