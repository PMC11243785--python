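"""Step 2: group variable-length segments by hierarchical clustering.

Segments from step 1 have different lengths, so each is summarized by
fixed-length statistics — the mean and standard deviation of its fix-level
rates (rate alone gives the most consistent clusters; course and d2w
statistics can be switched on). Segments are then clustered with
agglomerative (Ward) linkage on z-scored statistics and the dendrogram is
cut to exactly k clusters (default k = 6: three behaviors crossed with
near/far-from-water). Clustering is per animal by default, since
per-animal models generalize better than pooled ones for cattle behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass
class ClusterAssignment:
    """Segment-to-cluster map plus the linkage tree behind it.

    ``labels`` holds cluster indices in {0..k-1}, relabeled in order of
    first appearance so the assignment is stable under input order;
    ``linkage_matrix`` is the scipy merge table for dendrogram export.
    """

    segment_ids: np.ndarray
    labels: np.ndarray
    linkage_matrix: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"segment_id": self.segment_ids, "cluster": self.labels})


def _segment_rates(segments: pd.DataFrame, features: pd.DataFrame):
    """Yield (segment row, fix-level rates with NaN dropped) pairs."""
    by_animal = {
        aid: group.reset_index(drop=True)["rate"].to_numpy(float)
        for aid, group in features.groupby("animal_id", sort=False)
    }
    for _, seg in segments.iterrows():
        rates = by_animal[seg["animal_id"]][seg["start_index"] : seg["end_index"] + 1]
        yield seg, rates[~np.isnan(rates)]


def extract_segment_features(
    segments: pd.DataFrame,
    features: pd.DataFrame,
    include: tuple[str, ...] = ("rate",),
    ddof: int = 0,
) -> pd.DataFrame:
    """Mean and standard deviation of each segment's fix-level features.

    ``ddof=0`` (population sd) by default; a single-fix segment has sd 0.
    Columns are ``mean_<f>``/``sd_<f>`` per included feature.
    """
    by_animal = {
        aid: group.reset_index(drop=True)
        for aid, group in features.groupby("animal_id", sort=False)
    }
    rows = []
    for _, seg in segments.iterrows():
        group = by_animal[seg["animal_id"]]
        window = group.iloc[seg["start_index"] : seg["end_index"] + 1]
        row = {"segment_id": seg["segment_id"], "animal_id": seg["animal_id"]}
        for feat in include:
            vals = window[feat].to_numpy(float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                raise ValueError(
                    f"segment {seg['segment_id']} has no defined {feat} values"
                )
            row[f"mean_{feat}"] = float(vals.mean())
            row[f"sd_{feat}"] = float(vals.std(ddof=ddof)) if vals.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def hierarchical_cluster(
    segment_features: pd.DataFrame,
    k: int,
    method: str = "ward",
    columns: tuple[str, ...] | None = None,
) -> ClusterAssignment:
    """Ward-linkage agglomerative clustering of segment statistics.

    Feature columns are z-scored across segments (so the partition is
    invariant to rescaling all rates); the tree is cut to exactly ``k``
    clusters and labels are renumbered in order of first appearance.
    """
    if columns is None:
        columns = tuple(
            c for c in segment_features.columns if c.startswith(("mean_", "sd_"))
        )
    X = segment_features[list(columns)].to_numpy(float)
    n = len(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} segments")
    if n == 1:
        return ClusterAssignment(
            segment_ids=segment_features["segment_id"].to_numpy(),
            labels=np.zeros(1, dtype=int),
            linkage_matrix=np.empty((0, 4)),
        )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    Z[:, sd == 0] = 0.0
    tree = linkage(Z, method=method)
    raw = fcluster(tree, t=k, criterion="maxclust")
    # stable relabel: cluster of the earliest segment becomes 0, etc.
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    return ClusterAssignment(
        segment_ids=segment_features["segment_id"].to_numpy(),
        labels=labels,
        linkage_matrix=tree,
    )


def summarize_clusters(
    assignment: ClusterAssignment,
    segments: pd.DataFrame,
    features: pd.DataFrame,
    ddof: int = 0,
) -> pd.DataFrame:
    """Fix-level rate statistics per cluster (the Sr table).

    Statistics pool the fix-level rates of all member segments — many
    2-min steps of a resting cow have rate ~0, which is why low-velocity
    clusters show medians of 0 — not the per-segment means.
    """
    cluster_of = dict(zip(assignment.segment_ids, assignment.labels))
    pooled: dict[int, list[np.ndarray]] = {}
    seg_count: dict[int, int] = {}
    for seg, rates in _segment_rates(segments, features):
        c = cluster_of[seg["segment_id"]]
        pooled.setdefault(c, []).append(rates)
        seg_count[c] = seg_count.get(c, 0) + 1
    rows = []
    for c in sorted(pooled):
        rates = np.concatenate(pooled[c])
        if rates.size == 0:
            raise ValueError(f"cluster {c} has no fixes with defined rate")
        rows.append(
            {
                "cluster": c,
                "rate_mean": float(rates.mean()),
                "rate_sd": float(rates.std(ddof=ddof)) if rates.size > 1 else 0.0,
                "rate_median": float(np.median(rates)),
                "n_segments": seg_count[c],
                "n_fixes": int(rates.size),
            }
        )
    return pd.DataFrame(rows)
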