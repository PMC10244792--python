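"""GFP, modified k-means, GEV/CV oracles, backfitting and parameters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hhtmicrostate import (
    EEGRecording,
    LabelSequence,
    MicrostateModel,
    backfit,
    cv_criterion,
    extract_peak_maps,
    find_gfp_peaks,
    gev,
    gfp,
    make_templates,
    microstate_parameters,
    modified_kmeans,
    segment_runs,
    select_k,
)
from hhtmicrostate.microstate import GFPSeries

from conftest import FS


# ---------------------------------------------------------------------------
# brute-force oracles: direct loops over the definitions
# ---------------------------------------------------------------------------


def oracle_gev(X, templates, labels):
    """Direct evaluation: GEV = sum (GFP_n corr_n)^2 / sum GFP_n^2."""
    n, c = X.shape
    num_per_class = np.zeros(templates.shape[0])
    den = 0.0
    for i in range(n):
        x = X[i] - X[i].mean()
        g = np.sqrt(np.mean(x**2))
        den += g**2
        a = templates[labels[i]] - templates[labels[i]].mean()
        corr = np.dot(x, a) / (np.linalg.norm(x) * np.linalg.norm(a))
        num_per_class[labels[i]] += (g * corr) ** 2
    return num_per_class.sum() / den, num_per_class / den


def oracle_cv(X, templates, labels):
    """Direct evaluation: sigma^2 ((C-1)/(C-K-1))^2."""
    n, c = X.shape
    K = templates.shape[0]
    s = 0.0
    for i in range(n):
        x = X[i] - X[i].mean()
        a = templates[labels[i]]
        s += x @ x - (a @ x) ** 2
    sigma2 = s / (n * (c - 1))
    return sigma2 * ((c - 1) / (c - K - 1)) ** 2


def _toy_instance(seed=0, n=3, c=3, K=2):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, c))
    X -= X.mean(axis=1, keepdims=True)
    T = rng.standard_normal((K, c))
    T -= T.mean(axis=1, keepdims=True)
    T /= np.linalg.norm(T, axis=1, keepdims=True)
    labels = rng.integers(0, K, size=n)
    return X, T, labels


class TestGfp:
    def test_equal_channels_zero(self):
        rec = EEGRecording(np.vstack([np.ones(10)] * 3) * 4.2, 100)
        np.testing.assert_allclose(gfp(rec).values, 0.0, atol=1e-12)

    def test_two_channel_hand_value(self):
        # map (1, -1): mean 0, sqrt((1+1)/2) = 1
        rec = EEGRecording(np.array([[1.0, 2.0], [-1.0, -2.0]]), 100)
        assert gfp(rec).values[0] == pytest.approx(1.0)
        assert gfp(rec).values[1] == pytest.approx(2.0)

    def test_common_offset_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((5, 50))
        a = gfp(EEGRecording(data, 100)).values
        b = gfp(EEGRecording(data + 7.5, 100)).values
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestGfpPeaks:
    def test_triangular_bump_apex(self):
        v = np.array([0.0, 1, 2, 3, 2, 1, 0])
        peaks = find_gfp_peaks(GFPSeries(v, 100.0))
        np.testing.assert_array_equal(peaks, [3])

    def test_monotone_has_no_peaks(self):
        peaks = find_gfp_peaks(GFPSeries(np.arange(10.0), 100.0))
        assert peaks.size == 0

    def test_oscillatory_gfp_peak_rate(self):
        # a template scaled by a 10 Hz sinusoid has |sin|-shaped GFP:
        # two peaks per cycle
        t = np.arange(int(FS)) / FS
        template = make_templates(8, 1, seed=0)[0]
        rec = EEGRecording(np.outer(template, np.sin(2 * np.pi * 10 * t)), FS)
        peaks = find_gfp_peaks(gfp(rec))
        assert 18 <= peaks.size <= 22

    def test_min_distance_keeps_highest(self):
        v = np.array([0.0, 3, 0, 2, 0, 5, 0])
        peaks = find_gfp_peaks(GFPSeries(v, 100.0), min_distance_samples=3)
        assert 5 in peaks and 3 not in peaks


class TestExtractPeakMaps:
    def test_rows_are_centred_topographies(self, small_recording):
        peaks = np.array([0, 10, 20])
        pm = extract_peak_maps(small_recording, peaks)
        assert pm.n_maps == 3
        expected = small_recording.data[:, 0] - small_recording.data[:, 0].mean()
        np.testing.assert_allclose(pm.maps[0], expected)
        assert np.max(np.abs(pm.maps.sum(axis=1))) <= 1e-9 * np.max(np.abs(pm.maps))

    def test_empty_peaks_rejected(self, small_recording):
        with pytest.raises(ValueError):
            extract_peak_maps(small_recording, np.array([], dtype=int))


class TestModifiedKmeans:
    def test_planted_orthogonal_recovery(self):
        templates = make_templates(16, 4, max_xcorr=1e-9, seed=1)
        rng = np.random.default_rng(2)
        reps = np.repeat(templates, 30, axis=0)
        signs = rng.choice([-1.0, 1.0], size=len(reps))[:, None]
        maps = reps * signs * rng.uniform(0.5, 2.0, size=(len(reps), 1))
        model = modified_kmeans(maps, 4, seed=3)
        match = np.abs(model.templates @ templates.T)
        assert np.all(match.max(axis=0) > 1 - 1e-9)
        assert model.gev_total == pytest.approx(1.0, abs=1e-9)

    def test_polarity_invariance(self):
        rng = np.random.default_rng(4)
        maps = rng.standard_normal((60, 10))
        model_a = modified_kmeans(maps, 3, seed=5)
        flip = rng.choice([-1.0, 1.0], size=(60, 1))
        model_b = modified_kmeans(maps * flip, 3, seed=5)
        sim = np.abs(model_a.templates @ model_b.templates.T)
        assert np.all(sim.max(axis=1) > 1 - 1e-9)
        assert model_b.gev_total == pytest.approx(model_a.gev_total, abs=1e-9)

    def test_k1_is_dominant_eigenvector(self):
        rng = np.random.default_rng(6)
        maps = rng.standard_normal((40, 8))
        maps -= maps.mean(axis=1, keepdims=True)
        model = modified_kmeans(maps, 1, n_restarts=1, seed=7)
        evals, evecs = np.linalg.eigh(maps.T @ maps)
        dominant = evecs[:, -1]
        assert abs(np.dot(model.templates[0], dominant)) > 1 - 1e-9

    def test_unit_norm_templates(self):
        rng = np.random.default_rng(8)
        model = modified_kmeans(rng.standard_normal((50, 12)), 4, seed=9)
        np.testing.assert_allclose(np.linalg.norm(model.templates, axis=1), 1.0,
                                   atol=1e-9)

    def test_sigma2_monotone_within_restart(self):
        rng = np.random.default_rng(10)
        model = modified_kmeans(rng.standard_normal((80, 10)), 3,
                                n_restarts=3, seed=11)
        traj = model.meta["sigma2_trajectory"]
        assert all(b <= a + 1e-12 for a, b in zip(traj, traj[1:]))

    def test_k_out_of_range(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError):
            modified_kmeans(rng.standard_normal((20, 5)), 4, seed=0)


class TestGevCv:
    def test_perfect_fit_limits(self):
        templates = make_templates(8, 2, max_xcorr=1e-9, seed=13)
        scales = np.array([1.0, 2.0, 3.0, 0.5])
        labels = np.array([0, 1, 0, 1])
        X = templates[labels] * scales[:, None]
        total, per_class = gev(X, templates, labels)
        assert total == pytest.approx(1.0, abs=1e-12)
        assert cv_criterion(X, templates, labels) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_gev_matches_bruteforce(self, seed):
        X, T, labels = _toy_instance(seed, n=5, c=4, K=2)
        total, per_class = gev(X, T, labels)
        o_total, o_per = oracle_gev(X, T, labels)
        assert total == pytest.approx(o_total, abs=1e-9)
        np.testing.assert_allclose(per_class, o_per, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cv_matches_bruteforce(self, seed):
        X, T, labels = _toy_instance(seed, n=2, c=5, K=2)
        assert cv_criterion(X, T, labels) == pytest.approx(
            oracle_cv(X, T, labels), abs=1e-9)

    def test_per_class_sums_to_total(self):
        X, T, labels = _toy_instance(3, n=50, c=6, K=3)
        total, per_class = gev(X, T, labels)
        assert per_class.sum() == pytest.approx(total, abs=1e-9)

    def test_cv_requires_small_k(self):
        X, T, labels = _toy_instance(0, n=4, c=3, K=2)
        with pytest.raises(ValueError):
            cv_criterion(X, T, labels)


class TestSelectK:
    def test_planted_k_selected(self):
        templates = make_templates(20, 4, max_xcorr=0.2, seed=14)
        rng = np.random.default_rng(15)
        labels = rng.integers(0, 4, size=400)
        amps = rng.uniform(1.0, 2.0, size=400)
        maps = templates[labels] * amps[:, None]
        maps += (amps[:, None] / 15.0) * rng.standard_normal(maps.shape)  # SNR ~ 15
        best_k, table, _ = select_k(maps, range(2, 9), seed=16)
        assert best_k == 4

    def test_gev_non_decreasing_in_k(self):
        rng = np.random.default_rng(17)
        maps = rng.standard_normal((150, 12))
        _, table, _ = select_k(maps, range(2, 7), seed=18)
        gevs = table["gev_total"].to_numpy()
        assert np.all(np.diff(gevs) >= -0.01)

    def test_single_value_range(self):
        rng = np.random.default_rng(19)
        best_k, table, _ = select_k(rng.standard_normal((40, 8)), [3], seed=20)
        assert best_k == 3 and len(table) == 1


class TestBackfit:
    def test_single_template_recording(self):
        template = make_templates(6, 1, seed=21)[0]
        wave = np.abs(np.sin(2 * np.pi * 5 * np.arange(500) / FS)) + 0.1
        rec = EEGRecording(np.outer(template, wave), FS)
        other = make_templates(6, 2, max_xcorr=1e-9, seed=22)
        model = MicrostateModel(np.vstack([template, other[1]]),
                                np.array([]), 0, np.zeros(2), 0)
        seq = backfit(model, rec)
        assert np.all(seq.labels == 0)

    def test_sign_flip_invariance(self, planted_eeg):
        rec, truth = planted_eeg
        model = MicrostateModel(truth.templates, np.array([]), 0,
                                np.zeros(truth.templates.shape[0]), 0)
        a = backfit(model, rec).labels
        flipped = EEGRecording(-rec.data, rec.fs)
        b = backfit(model, flipped).labels
        np.testing.assert_array_equal(a, b)

    def test_alternating_blocks_recovered(self):
        templates = make_templates(10, 2, max_xcorr=1e-9, seed=23)
        blocks = np.kron(np.tile([0, 1], 10), np.ones(25, dtype=int))
        wave = 0.5 + np.abs(np.sin(2 * np.pi * 7 * np.arange(500) / FS))
        rec = EEGRecording((templates[blocks] * wave[:, None]).T, FS)
        model = MicrostateModel(templates, np.array([]), 0, np.zeros(2), 0)
        seq = backfit(model, rec)
        np.testing.assert_array_equal(seq.labels, blocks)

    def test_channel_mismatch(self, small_recording):
        model = MicrostateModel(make_templates(5, 2, seed=24), np.array([]),
                                0, np.zeros(2), 0)
        with pytest.raises(ValueError):
            backfit(model, small_recording)

    def test_min_segment_absorbs_short_runs(self):
        templates = make_templates(10, 2, max_xcorr=1e-9, seed=25)
        labels = np.zeros(200, dtype=int)
        labels[50:53] = 1  # 3-sample blip
        rec = EEGRecording((templates[labels] * 2.0).T, FS)
        model = MicrostateModel(templates, np.array([]), 0, np.zeros(2), 0)
        seq = backfit(model, rec, min_segment_samples=5)
        assert np.all(seq.labels == 0)


class TestParameters:
    def _params_for(self, labels, K=2, fs=FS, seed=26):
        templates = make_templates(8, K, max_xcorr=1e-9, seed=seed)
        rec = EEGRecording((templates[labels] * 2.0).T, fs)
        model = MicrostateModel(templates, np.array([]), 0, np.zeros(K), 0)
        return microstate_parameters(LabelSequence(np.asarray(labels), fs), rec, model)

    def test_hand_counted_example(self):
        labels = np.array([0] * 5 + [1] * 5)
        params = self._params_for(labels)
        for k in range(2):
            row = params.per_class(k)
            assert row["MD_ms"] == pytest.approx(20.0)
            assert row["OPS_per_s"] == pytest.approx(25.0)
            assert row["TCR"] == pytest.approx(0.5)

    def test_single_class_covers_everything(self):
        n = 300
        params = self._params_for(np.zeros(n, dtype=int))
        row = params.per_class(0)
        assert row["TCR"] == pytest.approx(1.0)
        assert row["OPS_per_s"] == pytest.approx(FS / n)
        assert row["MD_ms"] == pytest.approx(n * 1000.0 / FS)

    def test_absent_class_reported_missing(self):
        params = self._params_for(np.zeros(100, dtype=int), K=2)
        row = params.per_class(1)
        assert np.isnan(row["MD_ms"])
        assert row["OPS_per_s"] == 0.0
        assert row["TCR"] == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_tcr_identity(self, seed):
        """TCR == OPS * MD / 1000 for every class on random label sequences."""
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, size=200)
        params = self._params_for(labels, K=3, seed=27)
        for k in range(3):
            row = params.per_class(k)
            if row["TCR"] > 0:
                assert row["TCR"] == pytest.approx(
                    row["OPS_per_s"] * row["MD_ms"] / 1000.0, abs=1e-9)


def test_segment_runs_tile_labels():
    labels = np.array([0, 0, 1, 2, 2, 2, 0])
    runs = segment_runs(labels)
    assert runs == [(0, 0, 2), (1, 2, 1), (2, 3, 3), (0, 6, 1)]
    assert sum(r[2] for r in runs) == len(labels)
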