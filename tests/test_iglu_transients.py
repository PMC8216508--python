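"""Transient quantification: ΔF/F, active area, peaks/PPR, decay, diameter."""

import numpy as np
import pandas as pd
import pytest

from boutonquant import iglu_transients as it
from boutonquant.iglu_transients import (
    DecayFitError,
    compute_dff,
    correlate_parameters,
    fit_decay_tau,
    longitudinal_track,
    peak_and_ppr,
    trace_parameters,
    virtual_diameter,
)
from boutonquant.synthetic_data import BoutonSimConfig, simulate_bouton_movie

from conftest import make_movie


class TestComputeDff:
    def test_constant_movie_is_zero(self, constant_movie):
        d = compute_dff(constant_movie)
        assert np.allclose(d.dff, 0.0, atol=1e-9)
        assert np.allclose(d.baseline_sd, 0.0, atol=1e-9)

    def test_fifty_percent_step(self):
        """Baseline 100 a.u., post-stimulus 150 a.u. → ΔF/F = 50%."""
        data = np.full((320, 5, 5), 100.0)
        data[120:] = 150.0  # step well after the 60-ms stimulus onset frame
        movie = make_movie(data, stimulus_times=(60.0,))
        d = compute_dff(movie, filter_cutoff=None)
        assert np.allclose(d.dff[200:], 50.0)

    def test_gain_invariance(self):
        rng = np.random.default_rng(0)
        data = 100.0 + rng.normal(0, 3, (160, 7, 7)) + 50.0 * (
            np.arange(160)[:, None, None] > 100)
        m1 = make_movie(data)
        m2 = make_movie(data * 7.3)
        d1, d2 = compute_dff(m1), compute_dff(m2)
        np.testing.assert_allclose(d1.dff, d2.dff, atol=1e-8)
        np.testing.assert_allclose(d1.baseline_sd, d2.baseline_sd, atol=1e-10)

    def test_matches_generator_noise_free(self):
        """ΔF/F at the release-site pixel equals the generator's analytic
        value (generator is the oracle; unfiltered path is exact)."""
        cfg = BoutonSimConfig(n_release_sites=1, site_release_prob=1.0,
                              noise_sd=0.0, seed=2)
        movie, truth = simulate_bouton_movie(cfg)
        d = compute_dff(movie, filter_cutoff=None)
        np.testing.assert_allclose(d.dff, truth.noise_free_dff, atol=1e-8)

    def test_short_baseline_rejected(self):
        movie = make_movie(np.full((160, 5, 5), 10.0), stimulus_times=(30.0,))
        with pytest.raises(ValueError, match="50"):
            compute_dff(movie)

    def test_zero_baseline_pixel_identified(self):
        data = np.full((160, 5, 5), 10.0)
        data[:, 2, 3] = 0.0
        with pytest.raises(ValueError, match=r"row=2, col=3"):
            compute_dff(make_movie(data))


class TestTraceParameters:
    def test_all_zero_dff(self, constant_movie):
        tr = trace_parameters(compute_dff(constant_movie))
        assert np.all(tr.active_area == 0)
        assert np.all(tr.cumulative == 0)
        assert np.all(np.isnan(tr.mean_amp))

    def test_four_active_pixels(self):
        """4 pixels at {10,20,30,40}% with 0.2-μm pixels: area 0.16 μm²,
        cumulative 100, mean 25, max 40."""
        data = np.full((160, 5, 5), 100.0)
        vals = (10, 20, 30, 40)
        for i, v in enumerate(vals):
            data[130:, 0, i] = 100.0 * (1 + v / 100.0)
        d = compute_dff(make_movie(data), filter_cutoff=None)
        tr = trace_parameters(d)
        f = 150
        assert tr.active_area[f] == pytest.approx(4 * 0.2**2)
        assert tr.cumulative[f] == pytest.approx(100.0)
        assert tr.mean_amp[f] == pytest.approx(25.0)
        assert tr.max_amp[f] == pytest.approx(40.0)

    def test_cumulative_equals_mean_times_count(self):
        rng = np.random.default_rng(1)
        data = 100.0 + rng.normal(0, 5, (240, 9, 9))
        tr = trace_parameters(compute_dff(make_movie(data)))
        n = tr.active_mask_per_frame.sum(axis=(1, 2))
        ok = n > 0
        np.testing.assert_allclose(tr.cumulative[ok],
                                   tr.mean_amp[ok] * n[ok], rtol=1e-12)

    @pytest.mark.parametrize("k_lo,k_hi", [(1.0, 2.0), (2.0, 3.0), (3.0, 5.0)])
    def test_threshold_monotonicity(self, k_lo, k_hi):
        rng = np.random.default_rng(7)
        data = 100.0 + rng.normal(0, 4, (200, 9, 9))
        movie = make_movie(data)
        lo = trace_parameters(compute_dff(movie, threshold_k=k_lo))
        hi = trace_parameters(compute_dff(movie, threshold_k=k_hi))
        assert np.all(hi.active_area <= lo.active_area)

    def test_false_positive_rate_at_3sd(self):
        """One-sided 3-SD threshold on Gaussian noise: P ≈ Φ(−3) = 0.00135,
        checked over > 1e5 pixel-frames within 3 binomial SDs (the SD is the
        known generating value, isolating the thresholding rule)."""
        from boutonquant.iglu_transients import DffMovie

        rng = np.random.default_rng(11)
        sigma = 4.0
        shape = (700, 13, 13)  # 118,300 pixel-frames
        dff = rng.normal(0, sigma, shape)
        d = DffMovie(dff=dff, baseline_mean=np.full(shape[1:], 100.0),
                     baseline_sd=np.full(shape[1:], sigma),
                     frame_interval=0.625, pixel_size=0.2,
                     stimulus_times=(60.0,),
                     bouton_mask=np.ones(shape[1:], bool))
        tr = trace_parameters(d)
        n = np.prod(shape)
        p = 0.0013498980316300933  # standard normal tail at 3
        rate = tr.active_mask_per_frame.sum() / n
        tol = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(rate - p) < tol


class TestPeaksAndPpr:
    def _traces_from_cumulative(self, cum, stims=(60.0, 110.0)):
        n = len(cum)
        z = np.zeros(n)
        return it.TransientTraces(
            time=np.arange(n) * 0.625, active_area=z, active_fraction=z,
            cumulative=np.asarray(cum, float), mean_amp=z, max_amp=z,
            has_active=np.ones(n, bool),
            active_mask_per_frame=np.zeros((n, 1, 1), bool),
            pixel_size=0.2, stimulus_times=stims)

    def test_control_ppr_value(self):
        """Cumulative peaks 2.0 then 2.9 give PPR 1.45, the control average."""
        cum = np.zeros(320)
        cum[100] = 2.0   # 62.5 ms
        cum[180] = 2.9   # 112.5 ms
        s = peak_and_ppr(self._traces_from_cumulative(cum))
        assert s.ppr["cumulative"] == pytest.approx(1.45)

    def test_identical_responses_give_unity(self):
        cum = np.zeros(320)
        cum[100] = cum[180] = 5.0
        s = peak_and_ppr(self._traces_from_cumulative(cum))
        assert s.ppr["cumulative"] == pytest.approx(1.0)

    def test_absent_second_response_gives_zero(self):
        cum = np.zeros(320)
        cum[100] = 5.0
        s = peak_and_ppr(self._traces_from_cumulative(cum))
        assert s.ppr["cumulative"] == 0.0

    def test_zero_first_peak_reported_missing(self):
        cum = np.zeros(320)
        cum[180] = 5.0
        s = peak_and_ppr(self._traces_from_cumulative(cum))
        assert s.ppr["cumulative"] is None
        assert "zero" in s.ppr_missing_reason["cumulative"]


class TestDecayFit:
    def _exp_traces(self, tau, noise_sd=0.0, rng=None, c=0.0):
        t = np.arange(400) * 0.625
        cum = np.zeros_like(t)
        onset = t >= 62.5
        cum[onset] = 10.0 * np.exp(-(t[onset] - 62.5) / tau) + c
        if noise_sd:
            cum = cum + rng.normal(0, noise_sd, cum.shape)
        z = np.zeros_like(t)
        return it.TransientTraces(
            time=t, active_area=z, active_fraction=z, cumulative=cum,
            mean_amp=z, max_amp=z, has_active=np.ones_like(t, bool),
            active_mask_per_frame=np.zeros((len(t), 1, 1), bool),
            pixel_size=0.2, stimulus_times=(60.0,))

    def test_exact_exponential_recovered(self):
        tau, _ = fit_decay_tau(self._exp_traces(10.0))
        assert tau == pytest.approx(10.0, rel=1e-3)

    def test_noisy_recovery_median_within_5pct(self):
        """τ = 10 ms at SNR 10: median recovery error < 5% over 100 seeds."""
        taus = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tau, _ = fit_decay_tau(self._exp_traces(10.0, noise_sd=1.0, rng=rng))
            taus.append(tau)
        assert abs(np.median(taus) - 10.0) / 10.0 < 0.05

    def test_constant_tail_raises(self):
        tr = self._exp_traces(10.0)
        tr.cumulative[:] = 5.0
        with pytest.raises(DecayFitError):
            fit_decay_tau(tr)


class TestVirtualDiameter:
    def test_closed_forms(self):
        # 100 pixels at 0.1 μm → area 1 μm² → d = 2/√π
        mask = np.zeros((20, 20), bool)
        mask[:10, :10] = True
        assert virtual_diameter(mask, 0.1) == pytest.approx(2 / np.sqrt(np.pi))
        one = np.zeros((5, 5), bool)
        one[2, 2] = True
        assert virtual_diameter(one, 0.1) == pytest.approx(0.11283791, abs=1e-6)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            virtual_diameter(np.zeros((5, 5), bool), 0.1)


class TestCorrelogram:
    def test_perfect_and_anti_correlation(self):
        x = np.arange(1.0, 21.0)
        df = pd.DataFrame({"a": x, "b": 2 * x, "c": -x})
        out = correlate_parameters(df, pairs=[("a", "b"), ("a", "c")])
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 1e-20
        assert out.loc[1, "r"] == pytest.approx(-1.0)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        out = correlate_parameters(df, pairs=[("a", "b")])
        assert np.isnan(out.loc[0, "r"])
        assert "constant" in out.loc[0, "flag"]

    def test_null_false_positive_rate(self):
        """Independent columns: |r| exceeds the α=0.05 critical value in
        ≈5% of seeds (n = 50 per column, 200 seeds)."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"a": rng.normal(size=50),
                               "b": rng.normal(size=50)})
            out = correlate_parameters(df, pairs=[("a", "b")])
            hits += out.loc[0, "p"] < 0.05
        assert 2 <= hits <= 22  # 3 binomial SDs around 10/200


class TestLongitudinal:
    def _movie(self, scale=1.0, noise_scale=1.0, seed=0):
        rng = np.random.default_rng(seed)
        data = scale * 100.0 + noise_scale * rng.normal(0, 2, (240, 7, 7))
        data[110:130] += 30.0
        return make_movie(data, stimulus_times=(60.0,))

    def test_identical_movies_all_unity(self):
        movies = [(t, self._movie(seed=3)) for t in (-12.0, -6.0, 0.0, 6.0)]
        out = longitudinal_track(movies, treatment_time=3.0)
        for col in ("baseline_f_norm", "baseline_sd_norm",
                    "peak1_cumulative_norm"):
            np.testing.assert_allclose(out[col], 1.0, rtol=1e-9)

    def test_bleaching_halves_baseline(self):
        movies = [(-6.0, self._movie(seed=4)), (6.0, self._movie(scale=0.5, seed=4))]
        out = longitudinal_track(movies, treatment_time=0.0)
        assert out["baseline_f_norm"].iloc[1] == pytest.approx(0.5, rel=1e-2)

    def test_noise_scaling_tracks_baseline_sd(self):
        movies = [(-6.0, self._movie(seed=5)),
                  (6.0, self._movie(noise_scale=1.25, seed=5))]
        out = longitudinal_track(movies, treatment_time=0.0)
        assert out["baseline_sd_norm"].iloc[1] == pytest.approx(1.25, rel=0.05)

    def test_nonincreasing_timepoints_rejected(self):
        movies = [(0.0, self._movie()), (0.0, self._movie())]
        with pytest.raises(ValueError):
            longitudinal_track(movies, treatment_time=1.0)
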