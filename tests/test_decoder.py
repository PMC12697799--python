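import numpy as np
import pytest

from conftest import FINE_SAMPLE_DT
from ncrkit import (CapacityError, SpikeTrain, Spectrogram, calibrate_null,
                    decode, find_neighbors, make_windows, precise_encoder,
                    reconstruct, scan_lags, scan_window_sizes, score,
                    simulate_lnp)
from ncrkit.decoder import DecodedStimulus, NeighborTable
from ncrkit.stimulus import FrequencyAxis


def train(times, duration=2.0, unit_id="u"):
    return SpikeTrain(times=np.sort(np.asarray(times, dtype=float)),
                      duration=duration, unit_id=unit_id)


class TestFindNeighbors:
    def test_identical_pattern_ranks_first(self):
        # the same two-spike motif at 0.2 s and 1.4 s; all other windows
        # differ, so the non-overlapping twin is the nearest neighbor
        u = train([0.21, 0.25, 1.41, 1.45, 0.8])
        w = make_windows([u], "temporal", length=0.1, stride=0.05)
        nb = find_neighbors(w, k=3, query_indices=np.array([4]))  # t=0.2
        assert nb.neighbor_indices[0, 0] == 28  # window at t=1.4
        assert nb.distances[0, 0] == pytest.approx(0.0, abs=1e-3)

    def test_total_tie_reproducible_under_seed(self):
        u = train([], duration=3.0)
        w = make_windows([u], "temporal", length=0.1, stride=0.05)
        a = find_neighbors(w, k=5, tie_seed=7)
        b = find_neighbors(w, k=5, tie_seed=7)
        c = find_neighbors(w, k=5, tie_seed=8)
        assert np.array_equal(a.neighbor_indices, b.neighbor_indices)
        assert not np.array_equal(a.neighbor_indices, c.neighbor_indices)
        assert np.allclose(a.distances, 0.0)

    def test_overlap_exclusion(self):
        u = train([0.5], duration=2.0)
        w = make_windows([u], "temporal", length=0.1, stride=0.05)
        nb = find_neighbors(w, k=10)
        gaps = np.abs(nb.neighbor_starts - nb.query_starts[:, None])
        assert np.all(gaps >= 0.1 - 1e-9)

    def test_capacity_error(self):
        u = train([0.5], duration=0.5)
        w = make_windows([u], "temporal", length=0.1, stride=0.1)
        with pytest.raises(CapacityError):
            find_neighbors(w, k=w.n_windows + 1)

    def test_distances_non_decreasing(self, stim60, burst_unit):
        w = make_windows([burst_unit], "temporal")
        nb = find_neighbors(w, k=20, query_indices=np.arange(0, 500, 50))
        assert np.all(np.diff(nb.distances, axis=1) >= -1e-9)


def tiny_stimulus(n_time=40, seed=0):
    axis = FrequencyAxis(np.array([4000.0, 8000.0, 16000.0]))
    rng = np.random.default_rng(seed)
    return Spectrogram(energy=rng.random((3, n_time)), dt=5e-3, axis=axis)


def manual_neighbors(query_starts, neighbor_starts, length=0.05):
    q = np.asarray(query_starts, dtype=float)
    nb = np.asarray(neighbor_starts, dtype=float)
    return NeighborTable(query_indices=np.arange(q.size),
                         neighbor_indices=np.zeros_like(nb, dtype=int),
                         distances=np.zeros_like(nb), query_starts=q,
                         neighbor_starts=nb, window_length=length,
                         k=nb.shape[1], exclusion_halfwidth=length, tie_seed=0)


class TestReconstruct:
    def test_identical_segments_reproduced_exactly(self):
        stim = tiny_stimulus()
        nb = manual_neighbors([0.05], [[0.1, 0.1, 0.1]])
        dec = reconstruct(nb, stim, lags=(0.0,))
        seg = stim.energy[:, 20:30]
        assert np.allclose(dec.predicted[:, 10:20], seg)
        assert dec.coverage[10:20].tolist() == [1] * 10

    def test_half_half_average(self):
        stim = tiny_stimulus()
        nb = manual_neighbors([0.05], [[0.1, 0.1, 0.15, 0.15]])
        dec = reconstruct(nb, stim, lags=(0.0,))
        expect = 0.5 * (stim.energy[:, 20:30] + stim.energy[:, 30:40])
        assert np.allclose(dec.predicted[:, 10:20], expect)

    def test_constant_stimulus_invariant_to_lags(self):
        axis = FrequencyAxis(np.array([4000.0, 8000.0]))
        stim = Spectrogram(energy=np.full((2, 60), 0.3), dt=5e-3, axis=axis)
        nb = manual_neighbors([0.1], [[0.15, 0.2]])
        dec = reconstruct(nb, stim, lags=(-0.01, 0.0))
        cov = dec.coverage > 0
        assert np.allclose(dec.predicted[:, cov], 0.3)

    def test_empty_lags_rejected(self):
        with pytest.raises(ValueError):
            reconstruct(manual_neighbors([0.0], [[0.1]]), tiny_stimulus(),
                        lags=())

    def test_edge_segments_dropped(self):
        stim = tiny_stimulus()
        nb = manual_neighbors([0.1], [[0.0, 0.1]])
        dec = reconstruct(nb, stim, lags=(-0.01,))
        assert dec.n_dropped_segments == 1  # 0.0 - 10 ms falls off the grid


class TestScore:
    def make_decoded(self, predicted, coverage=None):
        cov = (np.ones(predicted.shape[1], dtype=np.int64)
               if coverage is None else coverage)
        return DecodedStimulus(predicted=predicted, coverage=cov,
                               lags=(0.0,), dt=5e-3)

    def test_perfect_prediction(self):
        stim = tiny_stimulus()
        res = score(stim, self.make_decoded(stim.energy.copy()))
        assert res.corr_signed == pytest.approx(1.0)
        assert res.ncr == pytest.approx(0.0, abs=1e-12)
        cov = np.isfinite(res.corr_t)
        assert np.allclose(res.corr_t[cov], 1.0)
        assert np.allclose(res.corr_f, 1.0)

    def test_negated_prediction_equivalent(self):
        # anti-correlated predictions carry the same information
        stim = tiny_stimulus()
        res = score(stim, self.make_decoded(-stim.energy))
        assert res.corr_signed == pytest.approx(-1.0)
        assert res.ncr == pytest.approx(0.0, abs=1e-12)

    def test_independent_noise_scores_low(self):
        # Monte-Carlo oracle: >= 1e4 pixels of seeded noise must land below
        # ncr = -1.5 (|r| ~ 1/sqrt(n) ~ 0.006)
        axis = FrequencyAxis.default()
        rng = np.random.default_rng(3)
        stim = Spectrogram(energy=rng.random((45, 500)), dt=5e-3, axis=axis)
        for _ in range(5):
            res = score(stim, self.make_decoded(rng.random((45, 500))))
            assert res.ncr < -1.5

    def test_constant_prediction_sentinel(self):
        stim = tiny_stimulus()
        res = score(stim, self.make_decoded(np.full((3, 40), 0.2)))
        assert res.ncr == float("-inf") and np.isnan(res.corr_signed)

    def test_empty_coverage_rejected(self):
        stim = tiny_stimulus()
        dec = self.make_decoded(np.full((3, 40), np.nan),
                                coverage=np.zeros(40, dtype=np.int64))
        with pytest.raises(ValueError):
            score(stim, dec)


class TestDecode:
    def test_self_pair_invariance(self, stim60, burst_unit):
        r1 = decode([burst_unit], stim60, "temporal", tie_seed=5)
        r2 = decode([burst_unit, burst_unit], stim60, "temporal", tie_seed=5)
        assert r1.ncr == r2.ncr  # bit-identical

    def test_ncr_nonpositive_and_consistent(self, stim60, burst_unit):
        for ck in ("temporal", "rate"):
            res = decode([burst_unit], stim60, ck)
            assert res.ncr <= 0
            assert 10 ** res.ncr == pytest.approx(abs(res.corr_signed))
            ok = np.isfinite(res.corr_t)
            assert np.all(np.abs(res.corr_t[ok]) <= 1)

    def test_silent_unit_silence_mask_equals_full(self, stim60):
        # a unit that never fires is "silent" everywhere: restricting to
        # silence changes nothing and decoding is a pure total-tie draw
        u = SpikeTrain(times=np.array([]), duration=60.0, unit_id="quiet")
        full = decode([u], stim60, "temporal", tie_seed=3)
        sil = decode([u], stim60, "temporal", tie_seed=3, mask="silence")
        assert full.ncr == sil.ncr
        assert sil.mask_kind == "silence"

    def test_masked_capacity_error(self, stim60, burst_unit):
        with pytest.raises(CapacityError):
            # silence-restricted candidate pool cannot possibly reach k when
            # k exceeds the total window count
            decode([burst_unit], stim60, "temporal", k=6000, mask="silence")

    def test_mutual_information_consistency(self):
        # for bivariate-normal surrogates, NCR = log10(rho) must increase
        # with the Gaussian MI = -0.5*ln(1-rho^2)
        rng = np.random.default_rng(0)
        rhos = [0.1, 0.3, 0.5, 0.7, 0.9]
        ncrs, mis = [], []
        for rho in rhos:
            cov = [[1, rho], [rho, 1]]
            x, y = rng.multivariate_normal([0, 0], cov, size=20_000).T
            r = abs(np.corrcoef(x, y)[0, 1])
            ncrs.append(np.log10(r))
            mis.append(-0.5 * np.log(1 - r ** 2))
        assert np.all(np.diff(ncrs) > 0) and np.all(np.diff(mis) > 0)


class TestScans:
    def test_flat_profile_returns_smallest_delay(self):
        # constant stimulus: every delay yields the no-information sentinel,
        # so the tie rule must return the smallest delay
        axis = FrequencyAxis(np.array([4000.0, 8000.0]))
        stim = Spectrogram(energy=np.full((2, 400), 0.3), dt=5e-3, axis=axis)
        u = train([0.5, 0.9, 1.4], duration=2.0)
        ncr_map, best = scan_lags([u], stim, "temporal",
                                  delays=(0.0, 0.01, 0.02), k=50)
        assert best == 0.0
        assert all(v == float("-inf") for v in ncr_map.values())

    def test_empty_grids_rejected(self, stim60, burst_unit):
        with pytest.raises(ValueError):
            scan_lags([burst_unit], stim60, "temporal", delays=())
        with pytest.raises(ValueError):
            scan_window_sizes([burst_unit], stim60, "temporal", sizes=())

    def test_window_size_exceeding_duration_rejected(self, stim60, burst_unit):
        with pytest.raises(ValueError):
            scan_window_sizes([burst_unit], stim60, "temporal", sizes=(61.0,))

    def test_window_scan_reproducible(self, stim60, burst_unit):
        kw = dict(sizes=(0.048, 0.1), k=50, tie_seed=2)
        a = scan_window_sizes([burst_unit], stim60, "temporal", **kw)
        b = scan_window_sizes([burst_unit], stim60, "temporal", **kw)
        assert a == b


class TestCalibrateNull:
    def test_argument_errors(self, stim60):
        with pytest.raises(ValueError):
            calibrate_null(stim60, n_trains=0)
        with pytest.raises(ValueError):
            calibrate_null(stim60, rates=(0.0, 10.0), n_trains=2)

    def test_small_calibration_structure(self, stim60):
        calib = calibrate_null(stim60, rates=(5.0, 20.0), n_trains=3, seed=1,
                               k=50)
        pooled = calib.pooled()
        assert pooled.size == 6  # both codes
        assert np.all(pooled <= 0)
        assert calib.threshold == pytest.approx(
            np.percentile(pooled[np.isfinite(pooled)], 95.0))
        assert calib.rates.size == 3

    def test_explicit_rates_used_verbatim(self, stim60):
        calib = calibrate_null(stim60, rates=(4.0, 8.0, 16.0), n_trains=3,
                               seed=0, k=50, code_kinds=("rate",))
        assert np.array_equal(calib.rates, [4.0, 8.0, 16.0])


class TestSignalDetection:
    def test_driven_unit_beats_small_null(self, stim60, stim60_fine):
        # an informative unit must exceed the null on the same stimulus
        calib = calibrate_null(stim60, rates=(2.0, 40.0), n_trains=4, seed=3)
        u = simulate_lnp(precise_encoder(bf=8000.0, seed=9), stim60_fine,
                         sample_dt=FINE_SAMPLE_DT)
        res = decode([u], stim60, "temporal")
        assert res.ncr > calib.threshold + 0.5

    def test_latency_recovered_by_lag_scan(self, stim60, stim60_fine):
        u = simulate_lnp(precise_encoder(bf=16_000.0, latency=0.015, seed=1),
                         stim60_fine, sample_dt=FINE_SAMPLE_DT)
        _, best = scan_lags([u], stim60, "temporal",
                            delays=np.arange(0.0, 0.0501, 0.005))
        assert abs(best - 0.015) <= 0.005
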