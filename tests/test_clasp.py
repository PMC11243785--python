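import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from herdtrack.clasp import (
    SegmentationConfig,
    binary_auc,
    build_windows,
    find_split,
    knn_neighbors,
    score_profile,
    segment_batch,
    segment_trajectory,
    standardize,
)
from conftest import planted_movement_slice


# ---------------------------------------------------------------- oracles
def brute_knn(W, k, exclusion):
    """Exhaustive pairwise-distance neighbor search (independent oracle)."""
    m = len(W)
    out = np.empty((m, k), dtype=int)
    for q in range(m):
        dists = []
        for j in range(m):
            if abs(j - q) <= exclusion:
                continue
            dists.append((float(np.sqrt(((W[q] - W[j]) ** 2).sum())), j))
        dists.sort()  # ties fall back to the lower index
        out[q] = [j for _, j in dists[:k]]
    return out


def brute_profile(W, cfg):
    """Score profile recomputed split-by-split from the brute-force KNN."""
    m = len(W)
    ms = cfg.effective_min_seg
    neigh = brute_knn(W, cfg.knn, cfg.effective_exclusion)
    scores = np.full(m, np.nan)
    for i in range(ms, m - ms + 1):
        truth = np.arange(m) >= i
        pred = np.array(
            [np.sum(neigh[q] >= i) * 2 > cfg.knn for q in range(m)]
        )
        tp = np.sum(pred & truth)
        tn = np.sum(~pred & ~truth)
        scores[i] = 0.5 * (tp / truth.sum() + tn / (~truth).sum())
    return scores


# ------------------------------------------------------------ window prep
class TestWindows:
    @pytest.mark.parametrize("n,w,f,rows,width", [(5, 2, 1, 4, 2), (5, 2, 3, 4, 6), (10, 3, 2, 8, 6)])
    def test_window_counts(self, n, w, f, rows, width):
        X = np.arange(n * f, dtype=float).reshape(n, f)
        W = build_windows(X, w)
        assert W.shape == (rows, width)

    def test_feature_major_concatenation(self):
        X = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        W = build_windows(X, 2)
        assert np.array_equal(W[0], [1.0, 2.0, 10.0, 20.0])

    def test_constant_feature_gives_identical_rows(self):
        W = build_windows(np.full((6, 1), 3.14), 2)
        assert np.all(W == W[0])

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError, match="shorter than window"):
            build_windows(np.zeros((2, 1)), 3)


class TestStandardize:
    def test_closed_form(self):
        Z = standardize(np.array([2.0, 4.0, 6.0]))
        assert np.allclose(Z.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_column_maps_to_zeros(self):
        Z = standardize(np.column_stack([np.full(5, 7.0), np.arange(5.0)]))
        assert np.all(Z[:, 0] == 0.0)

    def test_output_moments(self):
        rng = np.random.default_rng(0)
        Z = standardize(rng.normal(3, 5, (50, 2)))
        assert np.allclose(Z.mean(0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(0), 1.0, atol=1e-12)


# ------------------------------------------------------------------- knn
class TestKnn:
    def test_exact_duplicate_is_nearest(self):
        W = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 10.0], [20.0, 20.0]])
        assert knn_neighbors(W, 1, 0)[0, 0] == 1

    def test_tie_breaks_to_lower_index(self):
        W = np.array([[0.0], [5.0], [5.0], [9.0]])
        # rows 1 and 2 are equidistant duplicates; row 3's nearest is the tie
        assert knn_neighbors(W, 1, 0)[3, 0] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.normal(0, 1, (40, 4)).round(2)  # rounding provokes real ties
        for k, excl in [(1, 0), (3, 2), (5, 1)]:
            assert np.array_equal(knn_neighbors(W, k, excl), brute_knn(W, k, excl))

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            knn_neighbors(np.zeros((5, 1)), 3, 2)


# ------------------------------------------------------------------- auc
class TestBinaryAuc:
    def test_perfect_and_inverted(self):
        truth = np.array([0, 0, 1, 1])
        assert binary_auc(truth, truth) == 1.0
        assert binary_auc(truth, 1 - truth) == 0.0

    def test_worked_example(self):
        assert binary_auc([0, 0, 1, 1], [0, 1, 1, 1]) == pytest.approx(0.75)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            binary_auc([1, 1, 1], [0, 1, 1])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=60))
    def test_closed_form_matches_rank_auc(self, pairs):
        truth = np.array([t for t, _ in pairs], dtype=int)
        pred = np.array([p for _, p in pairs], dtype=int)
        if truth.all() or not truth.any():
            return
        assert binary_auc(truth, pred) == pytest.approx(roc_auc_score(truth, pred))


# ----------------------------------------------------------- score profile
class TestScoreProfile:
    def test_two_regime_peak_at_boundary(self):
        cfg = SegmentationConfig(window=2, knn=3, features=("rate",))
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0, 1, 60), rng.normal(10, 1, 60)])
        prof = score_profile(build_windows(standardize(x), 2), cfg)
        assert abs(int(np.nanargmax(prof)) - 60) <= 2
        assert np.nanmax(prof) >= 0.95

    def test_iid_noise_stays_below_threshold(self):
        cfg = SegmentationConfig(window=2, knn=3, features=("rate",))
        fired = 0
        for seed in range(20):
            z = np.random.default_rng(seed).normal(0, 1, 120)
            prof = score_profile(build_windows(standardize(z), 2), cfg)
            fired += np.nanmax(prof) > cfg.score_threshold
        assert fired <= 2

    def test_scores_bounded_and_admissible_range(self):
        cfg = SegmentationConfig(window=2, knn=3, features=("rate",))
        rng = np.random.default_rng(5)
        prof = score_profile(build_windows(standardize(rng.normal(0, 1, 80)), 2), cfg)
        ms = cfg.effective_min_seg
        valid = prof[~np.isnan(prof)]
        assert np.all((valid >= 0.0) & (valid <= 1.0))
        assert np.isnan(prof[:ms]).all() and np.isnan(prof[len(prof) - ms + 1 :]).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_profile(self, seed):
        cfg = SegmentationConfig(window=2, knn=3, features=("rate",))
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(0, 1, 60).round(1).cumsum()
        prof = score_profile(build_windows(standardize(x), 2), cfg)
        oracle = brute_profile(build_windows(standardize(x), 2), cfg)
        assert np.allclose(prof, oracle, equal_nan=True)


class TestFindSplit:
    def test_flat_profile_returns_none(self):
        assert find_split(np.full(50, 0.5), 0.7) is None

    def test_single_spike(self):
        prof = np.full(50, np.nan)
        prof[20] = 0.9
        assert find_split(prof, 0.7) == 20

    def test_tie_goes_to_earlier_index(self):
        prof = np.full(50, 0.5)
        prof[[10, 30]] = 0.95
        assert find_split(prof, 0.7) == 10

    def test_threshold_is_strict(self):
        prof = np.full(30, 0.70)
        assert find_split(prof, 0.70) is None


# ------------------------------------------------------------ segmentation
class TestSegmentBatch:
    def test_constant_slice_single_segment(self):
        cfg = SegmentationConfig(features=("rate",))
        assert segment_batch(np.zeros((100, 1)), cfg) == [(0, 99)]

    def test_short_slice_single_segment(self):
        cfg = SegmentationConfig(features=("rate",))
        assert segment_batch(np.zeros((5, 1)), cfg) == [(0, 4)]

    def test_three_regime_movement_boundaries_recovered(self):
        cfg = SegmentationConfig(window=2, knn=3)
        found = 0
        for seed in range(10):
            feats = planted_movement_slice(seed)
            F = feats.loc[feats["rate"].notna(), list(cfg.features)].to_numpy(float)
            segs = segment_batch(standardize(F), cfg)
            bounds = {s for s, _ in segs}
            hit40 = any(abs(b - 40) <= cfg.window for b in bounds)
            hit80 = any(abs(b - 80) <= cfg.window for b in bounds)
            found += hit40 and hit80
        assert found >= 9

    def test_segments_tile_slice(self):
        cfg = SegmentationConfig(window=2, knn=3)
        feats = planted_movement_slice(3)
        F = feats.loc[feats["rate"].notna(), list(cfg.features)].to_numpy(float)
        segs = segment_batch(standardize(F), cfg)
        covered = [i for s, e in segs for i in range(s, e + 1)]
        assert covered == list(range(len(F)))

    def test_max_splits_caps_recursion(self):
        cfg = SegmentationConfig(window=2, knn=3, max_splits=1)
        feats = planted_movement_slice(0)
        F = feats.loc[feats["rate"].notna(), list(cfg.features)].to_numpy(float)
        assert len(segment_batch(standardize(F), cfg)) <= 2


class TestSegmentTrajectory:
    def test_batch_boundaries_always_segment_boundaries(self):
        feats = planted_movement_slice(1)
        feats = feats.iloc[:121]
        # triple the analyzed records to 360 by repeating the slice
        import pandas as pd

        parts = []
        for r in range(3):
            part = feats.copy()
            part["timestamp"] = part["timestamp"] + pd.Timedelta(minutes=242 * r)
            parts.append(part if r == 0 else part.iloc[1:])
        table = pd.concat(parts, ignore_index=True)
        segs = segment_trajectory(table, SegmentationConfig())
        starts = set(segs["start_index"])
        assert {1, 121, 241} <= starts  # analyzed range starts at fix 1

    def test_homogeneous_noise_one_segment_per_batch(self, water):
        from conftest import make_trajectory
        from herdtrack import compute_features

        rng = np.random.default_rng(12)
        xy = rng.normal(0, 1.0, (361, 2))  # stationary, noise only
        feats = compute_features(make_trajectory(xy), water)
        segs = segment_trajectory(feats, SegmentationConfig())
        assert len(segs) == 3
        assert list(segs["start_index"]) == [1, 121, 241]

    def test_determinism(self):
        feats = planted_movement_slice(9)
        a = segment_trajectory(feats, SegmentationConfig())
        b = segment_trajectory(feats, SegmentationConfig())
        assert a.equals(b)
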