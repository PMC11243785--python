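"""Classification-score-profile (ClaSP) change-point segmentation.

Step 1 of the pipeline partitions each animal's fix sequence into
contiguous segments of presumed-constant behavior. Every candidate split
position is scored by how well a self-supervised K-nearest-neighbor
classifier separates sliding windows before the split from windows after
it; the score is the ROC-AUC of the KNN majority-vote labels against the
hypothetical split labels. A split is accepted where the profile's maximum
exceeds a threshold, and the two halves are split recursively.

Two modifications adapt the method to multivariate GPS tracks:

* windows of each selected feature (rate, course, d2w) are concatenated
  into a single vector, so one Euclidean distance covers all features;
* the sequence is hard-partitioned into consecutive *mini-batches*
  (default 120 records = 4 h at 2-min fixes) segmented independently,
  which keeps KNN candidates local in time and the search tractable on
  multi-week tracks.

Distances are computed on per-batch z-scored feature columns, not on
z-normalized windows: with the very short windows used here (w = 2) every
non-constant window normalizes to the same two-point shape, which would
discard the level differences in rate that the behaviors differ by.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

FEATURE_NAMES = ("rate", "course", "d2w")


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation step.

    window
        Sliding-window length in records; w=2 covers 4 min of movement at
        the 2-min fix interval.
    knn
        Neighbor count K for the self-supervised classifier; odd values
        avoid majority-vote ties (even K ties go to the pre-split label).
    score_threshold
        Minimum AUC (strict) for a split to be accepted.
    batch_size
        Mini-batch length in records; batches are segmented independently.
    min_seg
        Minimum segment length in records; default max(2*window, knn+1) so
        both sides of an admissible split can out-vote the exclusion zone.
    features
        Subset of {"rate", "course", "d2w"} entering the window distance.
    exclusion
        Half-width of the trivial-match exclusion zone around each query
        window; default = window.
    max_splits
        Optional cap on the number of accepted splits per batch.
    """

    window: int = 2
    knn: int = 3
    score_threshold: float = 0.70
    batch_size: int = 120
    min_seg: int | None = None
    features: tuple[str, ...] = FEATURE_NAMES
    exclusion: int | None = None
    max_splits: int | None = None

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.knn < 1:
            raise ValueError("knn must be >= 1")
        if not 0.5 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0.5, 1]")
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature(s): {sorted(unknown)}")
        if self.batch_size <= 2 * self.effective_min_seg:
            raise ValueError("batch_size must exceed 2*min_seg")

    @property
    def effective_min_seg(self) -> int:
        if self.min_seg is not None:
            return self.min_seg
        return max(2 * self.window, self.knn + 1)

    @property
    def effective_exclusion(self) -> int:
        return self.window if self.exclusion is None else self.exclusion


def standardize(X: np.ndarray) -> np.ndarray:
    """Z-score each column; a zero-variance column maps to all zeros."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) < 2:
        raise ValueError("standardize needs at least 2 rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / safe
    Z[:, sd == 0] = 0.0
    return Z


def build_windows(X: np.ndarray, window: int) -> np.ndarray:
    """Sliding windows of each feature column, concatenated feature-major.

    Row j is ``[f1_j .. f1_{j+w-1}, f2_j .., ...]``; n rows of f features
    yield n-w+1 rows of length w*f.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if n < window:
        raise ValueError("sequence shorter than window")
    # (m, f, w) view -> concatenate the per-feature subsequences
    view = np.lib.stride_tricks.sliding_window_view(X, window, axis=0)
    return view.reshape(n - window + 1, -1)


def knn_neighbors(W: np.ndarray, k: int, exclusion: int) -> np.ndarray:
    """Indices of the k nearest rows to each row, Euclidean distance.

    Rows whose index is within ±``exclusion`` of the query are barred
    (trivial matches of overlapping windows). Distance ties break toward
    the lower index. Returns an (m, k) integer array.
    """
    W = np.asarray(W, dtype=float)
    m = len(W)
    if m < k + 2 * exclusion + 1:
        raise ValueError(
            f"need >= {k + 2 * exclusion + 1} windows for k={k}, exclusion={exclusion}"
        )
    D = cdist(W, W)
    idx = np.arange(m)
    band = np.abs(idx[:, None] - idx[None, :]) <= exclusion
    D[band] = np.inf
    order = np.argsort(D, axis=1, kind="stable")  # stable -> lower index on ties
    return order[:, :k]


def binary_auc(truth: np.ndarray, predicted: np.ndarray) -> float:
    """ROC-AUC of binary predictions against binary truth.

    For binary scores the ROC has a single interior point, so the AUC
    equals (sensitivity + specificity) / 2.
    """
    truth = np.asarray(truth, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    sens = predicted[truth].mean()
    spec = (~predicted[~truth]).mean()
    return float((sens + spec) / 2.0)


def score_profile(W: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """AUC splitting score at every admissible split index.

    For split index i, windows before i are hypothesis class 0 and windows
    at/after i class 1; each window's predicted class is the majority class
    of its K nearest neighbors (even-K ties go to class 0), and the score
    is the binary AUC of predictions against the hypothesis. Indices
    outside [min_seg, m - min_seg] are NaN (not evaluated). Neighbors are
    computed once; only the labels change with i.
    """
    W = np.asarray(W, dtype=float)
    m = len(W)
    ms = cfg.effective_min_seg
    scores = np.full(m, np.nan)
    if m < 2 * ms:
        return scores
    neigh = knn_neighbors(W, cfg.knn, cfg.effective_exclusion)
    for i in range(ms, m - ms + 1):
        votes_after = (neigh >= i).sum(axis=1)
        predicted = votes_after * 2 > cfg.knn
        truth = np.zeros(m, dtype=bool)
        truth[i:] = True
        scores[i] = binary_auc(truth, predicted)
    return scores


def find_split(scores: np.ndarray, threshold: float) -> int | None:
    """Argmax of the profile if it strictly exceeds the threshold.

    Ties break toward the earlier index; returns None when nothing clears
    the threshold or the profile is entirely unevaluated.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0 or np.all(np.isnan(scores)):
        return None
    i = int(np.nanargmax(scores))
    return i if scores[i] > threshold else None


def segment_batch(X: np.ndarray, cfg: SegmentationConfig) -> list[tuple[int, int]]:
    """Recursively split one standardized batch into segments.

    ``X`` is the (already standardized) feature matrix of a single batch.
    Returns inclusive (start, end) index pairs that tile [0, len(X)-1].
    A split at window index i places the boundary at record i (the first
    record of the right-hand window).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    ms = cfg.effective_min_seg
    w = cfg.window
    excl = cfg.effective_exclusion
    budget = [np.inf if cfg.max_splits is None else cfg.max_splits]

    def recurse(lo: int, hi: int) -> list[tuple[int, int]]:
        length = hi - lo
        if length < 2 * ms or budget[0] <= 0 or length < w:
            return [(lo, hi - 1)]
        windows = build_windows(X[lo:hi], w)
        if len(windows) < max(2 * ms, cfg.knn + 2 * excl + 1):
            return [(lo, hi - 1)]
        split = find_split(score_profile(windows, cfg), cfg.score_threshold)
        if split is None:
            return [(lo, hi - 1)]
        budget[0] -= 1
        return recurse(lo, lo + split) + recurse(lo + split, hi)

    if n == 0:
        return []
    return recurse(0, n)


def segment_trajectory(
    features: pd.DataFrame, cfg: SegmentationConfig | None = None
) -> pd.DataFrame:
    """Segment every animal's feature table in independent mini-batches.

    Rows with undefined rate (the first fix of each animal) are excluded
    from the analyzed range. The analyzed records are hard-partitioned
    into consecutive ``batch_size``-record batches (final remainder kept
    as its own batch), each standardized and recursively split on its own,
    so batch boundaries are always segment boundaries.

    Returns a DataFrame with one row per segment: ``animal_id,
    segment_id, start_index, end_index, start_time, end_time, n_fixes``,
    indices being 0-based inclusive fix positions within the animal.
    """
    cfg = cfg or SegmentationConfig()
    if features.empty:
        raise ValueError("empty feature table")
    cols = list(cfg.features)
    rows = []
    seg_id = 0
    for animal_id, group in features.groupby("animal_id", sort=False):
        group = group.reset_index(drop=True)
        analyzed = group.index[group["rate"].notna()].to_numpy()
        F = group.loc[analyzed, cols].to_numpy(float)
        n = len(analyzed)
        for lo in range(0, n, cfg.batch_size):
            hi = min(lo + cfg.batch_size, n)
            chunk = F[lo:hi]
            if len(chunk) < 2:
                local = [(0, len(chunk) - 1)] if len(chunk) else []
            else:
                local = segment_batch(standardize(chunk), cfg)
            for s, e in local:
                fs = int(analyzed[lo + s])
                fe = int(analyzed[lo + e])
                rows.append(
                    {
                        "animal_id": animal_id,
                        "segment_id": seg_id,
                        "start_index": fs,
                        "end_index": fe,
                        "start_time": group.loc[fs, "timestamp"],
                        "end_time": group.loc[fe, "timestamp"],
                        "n_fixes": fe - fs + 1,
                    }
                )
                seg_id += 1
    return pd.DataFrame(rows)
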