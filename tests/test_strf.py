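import numpy as np
import pytest

from conftest import FINE_SAMPLE_DT, on_grid_bf
from ncrkit import (EncoderSpec, SpikeTrain, bf_centered_profile, build_strf,
                    extract_strf_features, generate_tone_schedule,
                    partition_by_tuning, precise_encoder,
                    render_tone_spectrogram, simulate_lnp, simulate_poisson)
from ncrkit.strf import STRF, average_bf_profiles


@pytest.fixture(scope="module")
def schedule(axis):
    return generate_tone_schedule(axis, seed=3)


@pytest.fixture(scope="module")
def tone_stim(schedule, axis):
    return render_tone_spectrogram(schedule, axis, dt=1e-3)


def make_strf(psth, freqs, mask=None, baseline_mean=0.0, baseline_sd=1.0):
    return STRF(psth=psth, smoothed=psth, freqs_hz=freqs, bin_dt=1e-3,
                baseline_mean=baseline_mean, baseline_sd=baseline_sd,
                significance_mask=(np.zeros_like(psth, dtype=bool)
                                   if mask is None else mask))


class TestBuildStrf:
    def test_zero_spike_train(self, schedule):
        u = SpikeTrain(times=np.array([]), duration=schedule.duration)
        strf = build_strf(u, schedule)
        assert not strf.psth.any()
        assert not strf.significance_mask.any()
        assert strf.features["bandwidth"] == 0.0
        assert np.isnan(strf.features["best_frequency"])

    def test_bf_recovery(self, schedule, tone_stim, axis):
        bf = on_grid_bf(axis, 16_000.0)
        for seed in range(5):
            spec = EncoderSpec(kind="lnp", baseline_rate=2.0, gain=400.0,
                               bf=bf, bandwidth=0.5, latency=0.015,
                               kernel_width=0.005, seed=seed)
            u = simulate_lnp(spec, tone_stim, sample_dt=FINE_SAMPLE_DT)
            strf = build_strf(u, schedule)
            err = abs(np.log2(strf.features["best_frequency"] / bf))
            assert err <= 0.25

    def test_latency_and_duration(self, schedule, tone_stim, axis):
        bf = on_grid_bf(axis, 16_000.0)
        u = simulate_lnp(precise_encoder(bf=bf, latency=0.015, seed=2),
                         tone_stim, sample_dt=FINE_SAMPLE_DT)
        strf = build_strf(u, schedule)
        assert strf.features["first_spike_latency"] == pytest.approx(15, abs=4)
        # tones last 50 ms; the response ends with them
        assert strf.features["response_duration"] == pytest.approx(50, abs=15)

    def test_untuned_poisson_rarely_significant(self, schedule):
        # specificity of the 6-SD rule: frozen simulation, <= 10% positives
        hits = sum(
            build_strf(simulate_poisson(10.0, schedule.duration, seed=s),
                       schedule).features["significant"]
            for s in range(40))
        assert hits <= 4

    def test_smoothing_conserves_mass(self, schedule, tone_stim, axis):
        u = simulate_lnp(precise_encoder(bf=on_grid_bf(axis, 8000.0), seed=5),
                         tone_stim, sample_dt=FINE_SAMPLE_DT)
        strf = build_strf(u, schedule)
        assert strf.smoothed.sum() == pytest.approx(strf.psth.sum(), rel=0.01)

    def test_window_exceeding_interval_rejected(self, schedule):
        u = SpikeTrain(times=np.array([1.0]), duration=schedule.duration)
        with pytest.raises(ValueError):
            build_strf(u, schedule, analysis_window=0.5)


class TestExtractFeatures:
    def test_disjoint_peaks_bandwidth_adds(self, axis):
        n_f, n_t = 45, 100
        psth = np.zeros((n_f, n_t))
        mask = np.zeros((n_f, n_t), dtype=bool)
        # two significant runs: 9 and 5 channels -> (9+5)*0.125 octaves
        mask[5:14, 40:60] = True
        mask[30:35, 40:60] = True
        psth[10, 50] = 100.0
        strf = make_strf(psth, axis.centers, mask)
        feats = extract_strf_features(strf)
        spacing = strf.channel_spacing_octaves
        assert feats["bandwidth"] == pytest.approx((9 + 5) * spacing)
        assert feats["best_frequency"] == axis.centers[10]

    def test_flat_grid_unreliable(self, axis):
        strf = make_strf(np.ones((45, 50)), axis.centers)
        feats = extract_strf_features(strf)
        assert feats["bandwidth"] == 0.0
        assert np.isnan(feats["best_frequency"])
        assert not feats["significant"]

    def test_single_gaussian_peak_argmax(self, axis):
        t = np.arange(80)
        f = np.arange(45)
        psth = (np.exp(-0.5 * ((f[:, None] - 20) / 3) ** 2)
                * np.exp(-0.5 * ((t[None, :] - 30) / 5) ** 2)) * 50
        mask = psth > 25
        strf = make_strf(psth, axis.centers, mask)
        feats = extract_strf_features(strf)
        assert feats["best_frequency"] == axis.centers[20]
        assert feats["max_rate"] == pytest.approx(50.0)


class TestPartition:
    def test_uniform_profile_equal_means(self, axis):
        mask = np.zeros((45, 50), dtype=bool)
        mask[20:25, 10:20] = True
        strf = make_strf(np.zeros((45, 50)), axis.centers, mask)
        part = partition_by_tuning(np.full(45, 0.4), strf)
        for v in (part.below, part.within, part.above):
            assert v == pytest.approx(0.4)

    def test_constructed_regional_means(self, axis):
        mask = np.zeros((45, 50), dtype=bool)
        mask[20:25, :] = True
        profile = np.where(np.arange(45) < 20, 0.2,
                           np.where(np.arange(45) <= 24, 0.6, 0.1))
        strf = make_strf(np.zeros((45, 50)), axis.centers, mask)
        part = partition_by_tuning(profile, strf)
        assert (part.below, part.within, part.above) == \
            pytest.approx((0.2, 0.6, 0.1))
        assert part.n_bins == {"below": 20, "within": 5, "above": 20}

    def test_full_axis_mask_flags_empty_regions(self, axis):
        mask = np.ones((45, 50), dtype=bool)
        strf = make_strf(np.zeros((45, 50)), axis.centers, mask)
        part = partition_by_tuning(np.full(45, 0.3), strf)
        assert np.isnan(part.below) and np.isnan(part.above)
        assert part.n_bins["below"] == 0

    def test_empty_mask_rejected(self, axis):
        strf = make_strf(np.zeros((45, 50)), axis.centers)
        with pytest.raises(ValueError):
            partition_by_tuning(np.full(45, 0.3), strf)


class TestBFProfile:
    def test_peak_at_bf_normalized(self, axis):
        profile = np.exp(-0.5 * ((np.arange(45) - 22) / 4.0) ** 2)
        bfp = bf_centered_profile(profile, axis.centers[22], axis)
        i0 = int(np.argmin(np.abs(bfp.offsets_octaves)))
        assert bfp.offsets_octaves[i0] == pytest.approx(0.0, abs=1e-9)
        assert bfp.values[i0] == pytest.approx(1.0)
        assert np.nanmax(bfp.values) == pytest.approx(1.0)

    def test_bf_at_lowest_channel_offsets_positive(self, axis):
        profile = np.linspace(1, 0.1, 45)
        bfp = bf_centered_profile(profile, axis.centers[0], axis)
        assert np.all(bfp.offsets_octaves >= -1e-9)

    def test_all_zero_profile_sentinel(self, axis):
        bfp = bf_centered_profile(np.zeros(45), axis.centers[5], axis)
        assert np.all(np.isnan(bfp.values))

    def test_population_average_missing_aware(self, axis):
        p1 = bf_centered_profile(
            np.exp(-0.5 * ((np.arange(45) - 10) / 3.0) ** 2),
            axis.centers[10], axis)
        p2 = bf_centered_profile(
            np.exp(-0.5 * ((np.arange(45) - 35) / 3.0) ** 2),
            axis.centers[35], axis)
        grid, mean = average_bf_profiles([p1, p2], axis)
        i0 = int(np.argmin(np.abs(grid)))
        assert mean[i0] == pytest.approx(1.0)
        assert np.isnan(mean[0])  # offsets never covered stay missing
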