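"""HRV: cleaning rule, time domain, tachogram resampling, Welch bands,
triplicate protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiotel import (
    BANDS,
    BeatSeries,
    CleaningParams,
    RRGenSpec,
    band_powers,
    clean_rr,
    gen_rr,
    resample_tachogram,
    time_domain,
    triplicate_hrv,
    welch_psd,
)


class TestCleaning:
    def test_uniform_series_untouched(self, uniform_beats):
        out = clean_rr(uniform_beats)
        assert out.valid.all()
        np.testing.assert_array_equal(out.rr, uniform_beats.rr)
        # input untouched (new series returned)
        assert out is not uniform_beats

    def test_injected_ectopics_flagged_per_truth_mask(self):
        spec = RRGenSpec(mean_rr=100.0, lf_component=None, hf_component=None,
                         duration=120.0, ectopic_rate=0.01, seed=8)
        beats, truth = gen_rr(spec)
        out = clean_rr(beats)
        # every truth interval (60 ms early beat, 140 ms pause) deviates by
        # 40 ms > 20 ms tolerance and must be flagged; nothing else is
        np.testing.assert_array_equal(~out.valid, truth)

    def test_idempotence(self):
        beats, _ = gen_rr(RRGenSpec(duration=60.0, noise_sd=2.0,
                                    ectopic_rate=0.02, seed=3))
        once = clean_rr(beats)
        twice = clean_rr(once)
        np.testing.assert_array_equal(once.valid, twice.valid)
        np.testing.assert_array_equal(once.rr, twice.rr)

    def test_high_artifact_fraction_sets_quality_flag(self):
        rng = np.random.default_rng(0)
        rr = np.where(rng.random(50) < 0.4, 160.0, 100.0)
        beats = BeatSeries(t=np.concatenate(([0], np.cumsum(rr) / 1e3)), rr=rr)
        out = clean_rr(beats)
        assert out.meta.get("quality_flag") == "high_artifact_fraction"

    def test_tolerance_must_be_positive(self):
        with pytest.raises(ValueError):
            CleaningParams(tolerance_ms=0.0)


class TestTimeDomain:
    def test_constant_series(self):
        rr = np.array([100.0, 100.0, 100.0])
        beats = BeatSeries(t=np.concatenate(([0], np.cumsum(rr) / 1e3)), rr=rr)
        td = time_domain(beats)
        assert td.mean_rr == 100.0
        assert td.sdnn == 0.0
        assert td.rmssd == 0.0

    def test_hand_computed_example(self):
        # SDNN = sd([100,110,105], n-1) = 5; RMSSD = sqrt((10^2+5^2)/2) = 7.906
        rr = np.array([100.0, 110.0, 105.0])
        beats = BeatSeries(t=np.concatenate(([0], np.cumsum(rr) / 1e3)), rr=rr)
        td = time_domain(beats)
        assert td.sdnn == pytest.approx(5.000, abs=1e-9)
        assert td.rmssd == pytest.approx(np.sqrt(125 / 2), abs=1e-9)
        assert td.rmssd == pytest.approx(7.906, abs=5e-4)

    def test_shuffle_leaves_sdnn_changes_rmssd(self):
        rng = np.random.default_rng(1)
        rr = 100 + rng.normal(0, 5, 200)
        sh = rng.permutation(rr)
        mk = lambda r: BeatSeries(t=np.concatenate(([0], np.cumsum(r) / 1e3)), rr=r)
        a, b = time_domain(mk(rr)), time_domain(mk(sh))
        assert a.sdnn == pytest.approx(b.sdnn, abs=1e-9)
        assert a.rmssd != pytest.approx(b.rmssd, abs=1e-6)

    @given(st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=25)
    def test_scale_equivariance(self, c):
        rr = np.array([95.0, 102.0, 110.0, 99.0, 104.0])
        mk = lambda r: BeatSeries(t=np.concatenate(([0], np.cumsum(r) / 1e3)), rr=r)
        a, b = time_domain(mk(rr)), time_domain(mk(rr * c))
        assert b.sdnn == pytest.approx(c * a.sdnn, rel=1e-9)
        assert b.rmssd == pytest.approx(c * a.rmssd, rel=1e-9)

    def test_pairs_spanning_invalid_beat_excluded(self):
        rr = np.array([100.0, 100.0, 160.0, 100.0, 100.0])
        valid = np.array([True, True, False, True, True])
        beats = BeatSeries(t=np.concatenate(([0], np.cumsum(rr) / 1e3)), rr=rr, valid=valid)
        td = time_domain(beats)
        assert td.rmssd == 0.0  # only the (100,100) pairs remain
        assert td.n_excluded == 1

    def test_too_few_valid_intervals(self):
        beats = BeatSeries(t=[0.0, 0.1, 0.2], rr=[100.0, 100.0],
                           valid=[True, False])
        with pytest.raises(ValueError):
            time_domain(beats)


class TestResampling:
    def test_constant_tachogram(self, uniform_beats):
        grid, vals = resample_tachogram(uniform_beats)
        assert np.all(vals == 100.0)
        assert grid[1] - grid[0] == pytest.approx(0.02)

    def test_linear_ramp_midpoint(self):
        beats = BeatSeries(t=[0.0, 0.1, 0.3], rr=[100.0, 200.0])
        grid, vals = resample_tachogram(beats, fs=10.0)
        mid = np.interp(0.2, grid, vals)
        assert mid == pytest.approx(150.0, abs=1e-9)

    def test_mean_preserved_within_one_percent(self):
        beats, _ = gen_rr(RRGenSpec(duration=120.0, seed=4))
        _, vals = resample_tachogram(beats)
        assert abs(vals.mean() - beats.rr.mean()) / beats.rr.mean() < 0.01


class TestWelch:
    def test_parseval_on_white_noise(self):
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(10):
            x = rng.normal(0, 3.0, 4096)
            sp = welch_psd(x)
            ratios.append(np.trapezoid(sp.psd, sp.freqs) / x.var())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_sinusoid_power_closed_form(self):
        fs, a = 50.0, 4.0
        t = np.arange(8192) / fs
        sp = welch_psd(a * np.cos(2 * np.pi * 2.5 * t))
        assert sp.hf == pytest.approx(a**2 / 2, rel=0.05)
        assert sp.lf < 0.01 * sp.hf

    def test_constant_series_has_zero_bands(self):
        with pytest.warns(RuntimeWarning, match="LF/HF undefined"):
            sp = welch_psd(np.full(2048, 123.4))
        assert sp.vlf == sp.lf == 0.0
        assert np.isnan(sp.lf_hf)  # hf == 0 guard

    def test_short_series_error_names_minimum_duration(self):
        with pytest.raises(ValueError, match="20.48 s"):
            welch_psd(np.zeros(100))

    def test_band_sum_below_total_power(self):
        rng = np.random.default_rng(5)
        sp = welch_psd(rng.normal(0, 2, 4096))
        total = np.trapezoid(sp.psd, sp.freqs)
        assert sp.vlf + sp.lf + sp.hf <= total + 1e-12


class TestBandPowers:
    def test_mass_at_half_hertz_is_lf(self):
        freqs = np.array([0.3, 0.5, 0.7])
        psd = np.array([0.0, 10.0, 0.0])
        pw = band_powers(freqs, psd)
        assert pw["lf"] > 0
        assert pw["hf"] == 0.0

    def test_boundary_frequency_belongs_to_upper_band(self):
        # half-open [low, high): mass exactly at 1.00 Hz counts as HF
        freqs = np.array([0.9, 1.0, 1.1])
        psd = np.array([0.0, 10.0, 0.0])
        pw = band_powers(freqs, psd)
        assert pw["lf"] == 0.0
        assert pw["hf"] > 0

    def test_spectral_localization_of_single_modulation(self):
        """>= 90% of LF+HF lands in the band containing the IPFM input."""
        for f, band in [(0.4, "lf"), (2.5, "hf")]:
            comp = (f, 5.0)
            spec = RRGenSpec(
                lf_component=comp if band == "lf" else None,
                hf_component=comp if band == "hf" else None,
                duration=120.0, seed=6,
            )
            beats, _ = gen_rr(spec)
            _, vals = resample_tachogram(beats)
            sp = welch_psd(vals)
            share = getattr(sp, band) / (sp.lf + sp.hf)
            assert share >= 0.90


@pytest.fixture(scope="module")
def recording():
    from datetime import datetime

    beats, _ = gen_rr(RRGenSpec(duration=900.0, noise_sd=1.0, seed=10))
    beats.anchor = datetime(2022, 2, 7, 8, 0)
    return beats


class TestTriplicate:

    def test_stationary_triplicate_close_to_full_interval(self, recording, design):
        trip = triplicate_hrv(recording, design=design)
        cleaned = clean_rr(recording)
        full = time_domain(cleaned)
        assert trip.time_domain.mean_rr == pytest.approx(full.mean_rr, rel=0.01)
        assert trip.time_domain.sdnn == pytest.approx(full.sdnn, rel=0.25)
        assert len(trip.window_starts) == 3

    def test_corrupted_region_never_selected(self, design):
        from datetime import datetime

        beats, _ = gen_rr(RRGenSpec(duration=900.0, noise_sd=1.0, seed=11))
        beats.anchor = datetime(2022, 2, 7, 8, 0)
        sel = (beats.t[1:] > 300) & (beats.t[1:] <= 500)
        rng = np.random.default_rng(0)
        corrupted = beats.rr.copy()
        corrupted[sel] += np.where(rng.random(sel.sum()) < 0.3, 80.0, 0.0)
        bad = BeatSeries(t=np.concatenate(([0], np.cumsum(corrupted) / 1e3)),
                         rr=corrupted, anchor=beats.anchor)
        trip = triplicate_hrv(bad, design=design)
        for start in trip.window_starts:
            assert not (300 <= start < 500 or 300 < start + 180 <= 500)

    def test_single_window_equals_plain_analysis(self, recording, design):
        trip = triplicate_hrv(recording, design=design, n_windows=1)
        assert len(trip.per_window_time) == 1
        assert trip.time_domain.sdnn == trip.per_window_time[0].sdnn

    def test_too_short_recording_reports_count(self, design):
        from datetime import datetime

        beats, _ = gen_rr(RRGenSpec(duration=400.0, seed=12))
        beats.anchor = datetime(2022, 2, 7, 8, 0)
        with pytest.raises(ValueError, match=r"only \d qualifying"):
            triplicate_hrv(beats, design=design, n_windows=5)
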