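"""Microstate analysis against independent brute-force oracles and
hand-traced examples."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msstm import microstate as ms
from msstm.synthetic_data import (
    class_dynamics,
    make_prototypes,
    simulate_recording,
    simulate_state_sequence,
)


# --- independent oracles -----------------------------------------------------

def gfp_oracle(data):
    """Direct per-sample transcription of the spatial-SD formula."""
    c, n = data.shape
    out = np.empty(n)
    for t in range(n):
        v = data[:, t]
        out[t] = np.sqrt(np.sum((v - v.mean()) ** 2) / c)
    return out


def corr_oracle(x, p):
    x = x - x.mean()
    p = p - p.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(p)
    return 0.0 if denom == 0 else float(x @ p / denom)


def gev_oracle(data, prototypes, labels):
    """Sample-by-sample recomputation of GFP-weighted squared correlation."""
    gfp = gfp_oracle(data)
    num = 0.0
    for i in range(data.shape[1]):
        num += (corr_oracle(data[:, i], prototypes[labels[i]]) * gfp[i]) ** 2
    return num / np.sum(gfp**2)


def cv_oracle(data, prototypes, labels, c, k):
    """Direct transcription of the residual-variance CV criterion."""
    n = data.shape[1]
    total = 0.0
    for i in range(n):
        x = data[:, i] - data[:, i].mean()
        a = prototypes[labels[i]] - prototypes[labels[i]].mean()
        a = a / np.linalg.norm(a)
        total += x @ x - (a @ x) ** 2
    sigma2 = total / (n * (c - 1))
    return sigma2 * ((c - 1) / (c - k - 1)) ** 2


# --- GFP ---------------------------------------------------------------------

class TestGFP:
    def test_constant_map_is_zero(self):
        data = np.ones((4, 10))
        gfp = ms.compute_gfp(data, 100.0)
        np.testing.assert_allclose(gfp.values, 0.0)

    def test_two_channel_hand_value(self):
        data = np.array([[1.0], [-1.0]])
        gfp = ms.compute_gfp(data, 100.0)
        assert np.isclose(gfp.values[0], 1.0)

    def test_matches_formula_oracle(self, rng):
        data = rng.standard_normal((28, 50))
        gfp = ms.compute_gfp(data, 250.0)
        np.testing.assert_allclose(gfp.values, gfp_oracle(data), atol=1e-12)

    def test_peaks_are_strict_local_maxima(self, rng):
        data = rng.standard_normal((28, 500))
        gfp = ms.compute_gfp(data, 250.0)
        v = gfp.values
        for p in gfp.peak_indices:
            assert 0 < p < len(v) - 1
            assert v[p] > v[p - 1] and v[p] > v[p + 1]

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            ms.compute_gfp(np.ones((1, 10)), 100.0)


# --- clustering --------------------------------------------------------------

class TestClustering:
    def test_orthogonal_maps_recovered_exactly(self, prototypes5):
        maps = np.repeat(prototypes5, 10, axis=0)
        ps = ms.cluster_microstates(maps, 5, n_init=10, seed=0)
        assert ps.gev_total > 0.999999
        corr = np.abs(ms.spatial_correlation(prototypes5.T, ps.maps))
        assert np.all(corr.max(axis=0) > 0.999)

    def test_k_equals_n_maps_saturates(self, prototypes5):
        ps = ms.cluster_microstates(prototypes5, 5, n_init=5, seed=1)
        assert np.isclose(ps.gev_total, 1.0, atol=1e-9)

    def test_matches_exhaustive_partition_oracle(self, rng):
        # 12 maps around two centers, k=2: enumerate every 2-partition and
        # maximize GEV; the clustering must attain the enumerated optimum
        centers = ms.normalize_maps(rng.standard_normal((2, 6)))
        maps = np.repeat(centers, 6, axis=0) + 0.3 * rng.standard_normal((12, 6))
        ps = ms.cluster_microstates(maps, 2, n_init=50, seed=2)

        def partition_gev(assign):
            # same centroid estimator as the algorithm (mean of unit-norm
            # maps); the enumeration independently checks the *search*
            maps_n = ms.normalize_maps(maps)
            protos = []
            for j in (0, 1):
                members = maps_n[np.asarray(assign) == j]
                if members.shape[0] == 0:
                    return -1.0
                protos.append(members.mean(axis=0))
            return gev_oracle(maps.T, ms.normalize_maps(np.array(protos)), list(assign))

        best = max(
            partition_gev(assign)
            for assign in itertools.product((0, 1), repeat=12)
        )
        assert ps.gev_total >= best - 1e-9

    def test_invalid_k(self, prototypes5):
        with pytest.raises(ValueError):
            ms.cluster_microstates(prototypes5, 0)
        with pytest.raises(ValueError):
            ms.cluster_microstates(prototypes5, 6)  # more clusters than maps


# --- GEV / CV ----------------------------------------------------------------

class TestGEV:
    def test_perfect_fit_is_one(self, prototypes5):
        labels = np.array([0, 1, 2, 3, 4] * 3)
        data = (prototypes5[labels] * 2.5).T  # positive scale
        gev = ms.compute_gev(data, prototypes5, labels)
        assert np.isclose(gev, 1.0, atol=1e-12)

    def test_orthogonal_assignment_is_zero(self, prototypes5):
        labels = np.array([1, 2, 3, 4, 0])  # every sample gets an orthogonal map
        data = prototypes5.T
        gev = ms.compute_gev(data, prototypes5, labels)
        assert gev < 1e-20

    def test_matches_oracle(self, rng):
        data = rng.standard_normal((10, 30))
        protos = ms.normalize_maps(rng.standard_normal((3, 10)))
        labels = rng.integers(0, 3, 30)
        assert np.isclose(
            ms.compute_gev(data, protos, labels),
            gev_oracle(data, protos, labels),
            atol=1e-12,
        )

    def test_zero_gfp_rejected(self, prototypes5):
        with pytest.raises(ValueError):
            ms.compute_gev(np.ones((28, 5)), prototypes5, np.zeros(5, dtype=int))


class TestCV:
    def test_perfect_fit_zero_residual(self, prototypes5):
        labels = np.array([0, 1, 2, 3, 4])
        data = (prototypes5[labels] * 3.0).T
        cv = ms.compute_cv(data, prototypes5, labels, n_channels=28, k=5)
        assert cv < 1e-12

    def test_matches_oracle(self, rng):
        data = rng.standard_normal((12, 20))
        protos = ms.normalize_maps(rng.standard_normal((4, 12)))
        labels = rng.integers(0, 4, 20)
        assert np.isclose(
            ms.compute_cv(data, protos, labels, n_channels=12, k=4),
            cv_oracle(data, protos, labels, 12, 4),
            atol=1e-10,
        )

    def test_residual_decreases_with_k_on_toy(self, rng):
        # 5-sample toy: more clusters -> residual variance cannot grow
        data = rng.standard_normal((10, 5))
        sigmas = []
        for k in (2, 3):
            ps = ms.cluster_microstates(data.T, k, n_init=20, seed=0)
            seg = ms.backfit(data, ps, 100.0)
            cv = ms.compute_cv(data, ps.maps, seg.labels, n_channels=10, k=k)
            sigmas.append(cv / ((10 - 1) / (10 - k - 1)) ** 2)  # unpenalized part
        assert sigmas[1] <= sigmas[0] + 1e-12

    def test_degrees_of_freedom_guard(self, rng):
        data = rng.standard_normal((4, 10))
        protos = ms.normalize_maps(rng.standard_normal((3, 4)))
        with pytest.raises(ValueError):
            ms.compute_cv(data, protos, np.zeros(10, dtype=int), n_channels=4, k=3)


# --- model selection ---------------------------------------------------------

class TestSelectK:
    def test_recovers_generator_k(self, prototypes5):
        trans, dwell = class_dynamics(1, 5)
        labels = simulate_state_sequence(trans[0], dwell[0], 2500, 250.0, seed=8)
        rec = simulate_recording(prototypes5, labels, 250.0, 10.0, seed=8)
        gfp = ms.compute_gfp(rec.data, 250.0)
        maps = ms.peak_maps(rec.data, gfp)
        chosen, table = ms.select_k(maps, range(2, 8), n_init=10, seed=0)
        assert chosen == 5
        assert set(table.columns) == {"k", "gev", "cv"}

    def test_zero_threshold_picks_minimum(self, rng):
        maps = rng.standard_normal((40, 10))
        chosen, _ = ms.select_k(maps, range(2, 5), gev_threshold=0.0, n_init=5, seed=0)
        assert chosen == 2

    def test_gev_at_true_k_explains_most_variance(self, prototypes5):
        # five maps explain >= 85% of a five-state synthetic signal at snr >= 5
        trans, dwell = class_dynamics(1, 5)
        labels = simulate_state_sequence(trans[0], dwell[0], 2500, 250.0, seed=9)
        rec = simulate_recording(prototypes5, labels, 250.0, 5.0, seed=9)
        ps = ms.cluster_microstates(
            ms.peak_maps(rec.data, ms.compute_gfp(rec.data, 250.0)), 5,
            n_init=10, seed=0,
        )
        seg = ms.backfit(rec.data, ps, 250.0)
        gev = ms.compute_gev(rec.data, ps.maps, seg.labels)
        assert gev >= 0.85

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError):
            ms.select_k(rng.standard_normal((10, 5)), [])


# --- backfitting and smoothing ----------------------------------------------

class TestBackfit:
    def test_prototype_sample_gets_its_label(self, prototypes5):
        data = prototypes5.T
        seg = ms.backfit(data, prototypes5, 250.0)
        np.testing.assert_array_equal(seg.labels, np.arange(5))
        np.testing.assert_allclose(seg.correlations, 1.0, atol=1e-9)

    def test_polarity_invariant_sign_flip(self, prototypes5):
        data = -prototypes5.T
        seg = ms.backfit(data, prototypes5, 250.0, polarity_invariant=True)
        np.testing.assert_array_equal(seg.labels, np.arange(5))

    def test_matches_per_sample_argmax_oracle(self, rng, prototypes5):
        data = rng.standard_normal((28, 40))
        seg = ms.backfit(data, prototypes5, 250.0, polarity_invariant=True)
        for i in range(40):
            cs = [abs(corr_oracle(data[:, i], p)) for p in prototypes5]
            assert seg.labels[i] == int(np.argmax(cs))

    def test_scale_invariance(self, rng, prototypes5):
        data = rng.standard_normal((28, 100))
        a = ms.backfit(data, prototypes5, 250.0)
        b = ms.backfit(3.7 * data, prototypes5, 250.0)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestSmoothing:
    def _seg(self, labels, k=3):
        labels = np.asarray(labels)
        score = np.ones((k, labels.size))
        return ms.MicrostateSegmentation(
            labels=labels, correlations=np.ones(labels.size),
            sampling_rate=1000.0, all_correlations=score,
        )

    def test_zero_duration_is_identity(self):
        seg = self._seg([0, 1, 0, 2, 1])
        out = ms.smooth_labels(seg, 0.0)
        np.testing.assert_array_equal(out.labels, seg.labels)

    def test_hand_traced_single_sample_segment(self):
        # at 1000 Hz, 2 ms minimum = 2 samples; the lone 1 is absorbed
        seg = self._seg([0, 0, 1, 0, 0])
        out = ms.smooth_labels(seg, 2.0)
        np.testing.assert_array_equal(out.labels, [0, 0, 0, 0, 0])

    def test_idempotent(self, rng, prototypes5):
        data = rng.standard_normal((28, 300))
        seg = ms.backfit(data, prototypes5, 250.0)
        once = ms.smooth_labels(seg, 30.0)
        twice = ms.smooth_labels(once, 30.0)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            ms.smooth_labels(self._seg([0, 1]), -1.0)


# --- statistics --------------------------------------------------------------

class TestStatistics:
    def test_hand_enumerated_example(self):
        # [0,0,1,1,1,2] at 2 Hz: 3 s of data, three one-segment states
        stats = ms.microstate_statistics(np.array([0, 0, 1, 1, 1, 2]), 3, 2.0)
        np.testing.assert_allclose(stats.coverage, [1 / 3, 1 / 2, 1 / 6])
        np.testing.assert_allclose(stats.duration, [1000.0, 1500.0, 500.0])
        np.testing.assert_allclose(stats.occurrence, [1 / 3, 1 / 3, 1 / 3])
        expected_trans = np.zeros((3, 3))
        expected_trans[0, 1] = 1.0
        expected_trans[1, 2] = 1.0
        np.testing.assert_allclose(stats.transition, expected_trans)

    def test_constant_labels(self):
        stats = ms.microstate_statistics(np.zeros(50, dtype=int), 3, 250.0)
        np.testing.assert_allclose(stats.coverage, [1.0, 0.0, 0.0])
        np.testing.assert_allclose(stats.transition, 0.0)

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=200), st.sampled_from([100.0, 250.0]))
    @settings(max_examples=50, deadline=None)
    def test_identity_occurrence_duration_coverage(self, labels, fs):
        stats = ms.microstate_statistics(np.array(labels), 4, fs)
        assert np.isclose(stats.coverage.sum(), 1.0, atol=1e-9)
        for k in range(4):
            if stats.coverage[k] > 0:
                assert np.isclose(
                    stats.occurrence[k] * stats.duration[k],
                    1000.0 * stats.coverage[k],
                    atol=1e-6,
                )
        rowsum = stats.transition.sum(axis=1)
        assert np.all((np.isclose(rowsum, 1.0, atol=1e-9)) | (rowsum == 0.0))


def test_gev_monotone_in_prototype_count(rng):
    # best-assignment GEV never decreases when a prototype is added
    data = rng.standard_normal((16, 80))
    protos = ms.normalize_maps(rng.standard_normal((4, 16)))
    gevs = []
    for k in (2, 3, 4):
        sub = protos[:k]
        seg = ms.backfit(data, sub, 250.0)
        gevs.append(ms.compute_gev(data, sub, seg.labels))
    assert gevs[0] <= gevs[1] + 1e-12 <= gevs[2] + 2e-12
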