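import functools
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ivtk import profiling as prof
from ivtk.synthetic import ARCHETYPES, gen_cohort
from ivtk.tracks_io import resample_track

from conftest import make_track


def dtw_bruteforce(a, b):
    """Independent oracle: memoized recursion over all monotone alignments."""

    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        c = float(np.linalg.norm(a[i] - b[j]))
        if i == 0 and j == 0:
            return c
        opts = []
        if i > 0:
            opts.append(rec(i - 1, j))
        if j > 0:
            opts.append(rec(i, j - 1))
        if i > 0 and j > 0:
            opts.append(rec(i - 1, j - 1))
        return c + min(opts)

    return rec(len(a) - 1, len(b) - 1)


def shortest_path_bruteforce(adj, src, dst, n):
    """Min-cost simple path by exhaustive enumeration (small n only)."""
    best = np.inf
    nodes = [v for v in range(n) if v not in (src, dst)]
    for r in range(len(nodes) + 1):
        for mid in itertools.permutations(nodes, r):
            path = (src, *mid, dst)
            cost = 0.0
            for u, v in zip(path, path[1:]):
                w = adj[u, v]
                if w == 0:
                    cost = np.inf
                    break
                cost += w
            best = min(best, cost)
    return best


class TestWindowFeatures:
    @staticmethod
    def _uniform_track(n, dt=10.0, speed_um_min=6.0, track_id="w"):
        step = speed_um_min * dt / 60.0
        x = step * np.arange(n)
        return make_track(np.arange(n) * dt, x, np.zeros(n), track_id=track_id)

    def test_window_count_500s_track(self):
        feats = prof.window_features(self._uniform_track(51))
        assert feats.values.shape == (47, 4)

    def test_straight_track_directionality_one(self):
        feats = prof.window_features(self._uniform_track(20))
        np.testing.assert_allclose(feats.values[:, 0], 1.0)

    def test_arrested_track_hits_epsilon_cap(self):
        n = 10
        tr = make_track(np.arange(n) * 10.0, np.zeros(n), np.zeros(n))
        feats = prof.window_features(tr, epsilon_um2=1e-3)
        np.testing.assert_allclose(feats.values[:, 3], 1e3)
        np.testing.assert_allclose(feats.values[:, 0], 0.0)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            prof.window_features(self._uniform_track(4))

    def test_requires_matching_dt(self):
        tr = self._uniform_track(20, dt=20.0)
        with pytest.raises(ValueError):
            prof.window_features(tr, dt_s=10.0)

    @given(n=st.integers(min_value=5, max_value=200))
    def test_window_count_property(self, n):
        """A track with S uniform samples yields S - 4 five-sample windows."""
        feats = prof.window_features(self._uniform_track(n))
        assert feats.values.shape[0] == n - 4


class TestNormalizeFeatures:
    def _series(self, seed=0, n_tracks=5):
        rng = np.random.default_rng(seed)
        return [
            prof.WindowedFeatureSeries(
                track_id=f"s{i}",
                values=rng.normal(loc=rng.uniform(-3, 3, 4), size=(int(rng.integers(3, 12)), 4)),
                window_start_times=np.arange(3),
            )
            for i in range(n_tracks)
        ]

    def test_pooled_zero_mean_unit_sd(self):
        normed, _ = prof.normalize_features(self._series())
        pooled = np.vstack([s.values for s in normed])
        np.testing.assert_allclose(pooled.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(pooled.std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_maps_to_zero(self):
        series = self._series()
        for s in series:
            s.values[:, 2] = 7.0
        normed, _ = prof.normalize_features(series)
        assert all((s.values[:, 2] == 0).all() for s in normed)

    def test_stored_stats_apply_to_held_out(self):
        series = self._series()
        _, (mean, sd) = prof.normalize_features(series)
        held = self._series(seed=99, n_tracks=2)
        normed, _ = prof.normalize_features(held, stats=(mean, sd))
        np.testing.assert_allclose(normed[0].values, (held[0].values - mean) / sd)


class TestDtw:
    def test_self_distance_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=(rng.integers(1, 10), 4))
            assert prof.dtw_distance(x, x) == pytest.approx(0.0)

    def test_symmetry_fuzz(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=(rng.integers(1, 12), 4))
            b = rng.normal(size=(rng.integers(1, 12), 4))
            assert prof.dtw_distance(a, b) == pytest.approx(prof.dtw_distance(b, a))

    def test_matches_bruteforce_recursion(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=(int(rng.integers(1, 7)), 4))
            b = rng.normal(size=(int(rng.integers(1, 7)), 4))
            assert prof.dtw_distance(a, b) == pytest.approx(dtw_bruteforce(a, b), abs=1e-10)

    def test_bounded_by_lockstep_distance(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(2, 10))
            a, b = rng.normal(size=(2, n, 4))
            lockstep = np.linalg.norm(a - b, axis=1).sum()
            assert prof.dtw_distance(a, b) <= lockstep + 1e-12

    def test_matrix_invariants(self):
        rng = np.random.default_rng(4)
        series = [rng.normal(size=(int(rng.integers(2, 8)), 4)) for _ in range(6)]
        D = prof.dtw_distance_matrix(series)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)
        assert (D >= 0).all() and np.isfinite(D).all()

    def test_empty_series_errors(self):
        with pytest.raises(ValueError):
            prof.dtw_distance(np.empty((0, 4)), np.ones((3, 4)))


class TestEmbed:
    @staticmethod
    def _two_group_distances(n=20, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat([0, 1], n // 2)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                base = 1.0 if labels[i] == labels[j] else 10.0
                D[i, j] = D[j, i] = base + rng.uniform(0, 0.1)
        return D, labels

    def test_shape_and_finiteness(self):
        D, _ = self._two_group_distances()
        emb = prof.embed(D, seed=42)
        assert emb.shape == (20, 2) and np.isfinite(emb).all()

    def test_deterministic_for_seed(self):
        D, _ = self._two_group_distances()
        np.testing.assert_array_equal(prof.embed(D, seed=42), prof.embed(D, seed=42))

    def test_separated_groups_stay_separated(self):
        from sklearn.metrics import silhouette_score

        D, labels = self._two_group_distances(n=30, seed=42)
        emb = prof.embed(D, seed=42)
        assert silhouette_score(emb, labels) > 0.5

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            prof.embed(np.zeros((4, 4)), neighbors=5)


class TestDensityPeaks:
    def test_k1_single_cluster(self):
        pts = np.random.default_rng(0).uniform(size=(30, 2))
        res = prof.density_peak_cluster(pts, k=1)
        assert set(res.labels) == {1}

    def test_three_planted_blobs_exact(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(13)
        centers = np.array([[0.1, 0.1], [0.5, 0.6], [0.9, 0.2]])
        pts = np.vstack([c + rng.normal(0, 0.02, (50, 2)) for c in centers])
        truth = np.repeat([0, 1, 2], 50)
        res = prof.density_peak_cluster(pts, k=3)
        assert adjusted_rand_score(truth, res.labels) == 1.0
        # centers belong to their own clusters; they top the gamma ranking
        assert (res.labels[res.centers] == np.arange(3) + 1).all()
        assert res.gamma[res.centers].min() >= np.partition(res.gamma, -3)[-3] - 1e-12

    def test_small_n_matches_exhaustive_shortest_paths(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            pts = rng.uniform(size=(8, 2))
            res = prof.density_peak_cluster(pts, k=2, prune_threshold=0.45)
            norm = prof._minmax(pts)
            from scipy.spatial.distance import pdist, squareform

            dist = squareform(pdist(norm))
            adj = np.where(dist <= 0.45, dist, 0.0)
            np.fill_diagonal(adj, 0.0)
            for i in range(8):
                if i in res.centers:
                    continue
                costs = [shortest_path_bruteforce(adj, int(c), i, 8) for c in res.centers]
                if np.isfinite(min(costs)):
                    assert res.labels[i] == int(np.argmin(costs)) + 1

    def test_infinite_prune_matches_nearest_center(self):
        rng = np.random.default_rng(6)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        pts = np.vstack([c + rng.normal(0, 0.3, (40, 2)) for c in centers])
        res = prof.density_peak_cluster(pts, k=3, prune_threshold=np.inf)
        norm = prof._minmax(pts)
        nearest = np.argmin(
            np.linalg.norm(norm[:, None, :] - norm[res.centers][None], axis=2), axis=1
        )
        np.testing.assert_array_equal(res.labels, nearest + 1)

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            prof.density_peak_cluster(np.zeros((3, 2)), k=4)

    def test_unreachable_noise_mode(self):
        pts = np.array([[0, 0], [0.01, 0], [1.0, 1.0]])
        res = prof.density_peak_cluster(pts, k=1, prune_threshold=0.05, unreachable="noise")
        assert res.labels[2] == 0


class TestClusterProfile:
    def test_two_clusters_differing_in_speed(self):
        records = pd.DataFrame({
            "speed": [2.0, 2.0, 8.0, 8.0],
            "directionality": [0.5] * 4,
            "arrest_coefficient": [0.2] * 4,
            "displacement": [10.0] * 4,
            "path_length": [20.0] * 4,
        })
        profile = prof.cluster_profile(np.array([1, 1, 2, 2]), records)
        assert profile.loc[1, "speed"] == 0.0 and profile.loc[2, "speed"] == 1.0
        assert (profile["directionality"] == 0.5).all()  # degenerate metric -> 0.5

    def test_single_cluster_degenerate(self):
        records = pd.DataFrame({
            "speed": [1.0, 2.0], "directionality": [0.1, 0.9],
            "arrest_coefficient": [0.0, 1.0], "displacement": [1.0, 2.0],
            "path_length": [2.0, 4.0],
        })
        profile = prof.cluster_profile(np.array([1, 1]), records)
        assert (profile.values == 0.5).all()

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            prof.cluster_profile(np.array([1]), pd.DataFrame({"speed": [1.0, 2.0]}))


@pytest.fixture(scope="module")
def cohort_run():
    tracks, labels = gen_cohort({m: 30 for m in ARCHETYPES}, seed=21)
    res = prof.profile_pipeline(tracks, k=4, seed=42)
    return tracks, labels, res


class TestPipeline:
    def test_archetype_recovery(self, cohort_run):
        from sklearn.metrics import adjusted_rand_score

        _, labels, res = cohort_run
        truth = labels.set_index("track_id").loc[res.track_ids, "label"]
        assert adjusted_rand_score(truth, res.clusters.labels) >= 0.8

    def test_profile_poles_match_archetypes(self, cohort_run):
        _, labels, res = cohort_run
        truth = labels.set_index("track_id").loc[res.track_ids, "label"].to_numpy()
        majority = pd.DataFrame({"cl": res.clusters.labels, "true": truth}) \
            .groupby("cl")["true"].agg(lambda s: s.mode()[0])
        directed_cl = majority[majority == "directed"].index[0]
        arrested_cl = majority[majority == "arrested"].index[0]
        assert res.profile.loc[directed_cl, "directionality"] == 1.0
        assert res.profile.loc[arrested_cl, "arrest_coefficient"] == 1.0

    def test_distance_matrix_invariants(self, cohort_run):
        _, _, res = cohort_run
        D = res.distance_matrix
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)
        assert np.isfinite(D).all() and (D >= 0).all()

    def test_rerun_is_deterministic(self, cohort_run):
        tracks, _, res = cohort_run
        res2 = prof.profile_pipeline(tracks, k=4, seed=42)
        np.testing.assert_array_equal(res.clusters.labels, res2.clusters.labels)
        np.testing.assert_array_equal(res.embedding, res2.embedding)

    def test_too_few_tracks_errors(self):
        tracks, _ = gen_cohort({"directed": 2}, seed=0, duration_s=100.0)
        with pytest.raises(ValueError, match="duration"):
            prof.profile_pipeline(tracks, k=2)
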