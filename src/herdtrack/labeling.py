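"""Map clusters to behaviors via velocity thresholds; diurnal summaries.

A cluster's mean fix-level rate Sr decides its behavior: Sr below
``rest_max`` (default 4.5 m/min) is resting, Sr above ``walk_min``
(default 25 m/min) is walking, anything between — boundaries included —
is grazing. Each fix then inherits the behavior of its segment's cluster,
and per-behavior rate tables and hourly activity distributions summarize
the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment

BEHAVIORS = ("resting", "grazing", "walking")


@dataclass(frozen=True)
class LabelRule:
    """Velocity thresholds (m/min) separating the three behaviors."""

    rest_max: float = 4.5
    walk_min: float = 25.0

    def __post_init__(self) -> None:
        if not 0 < self.rest_max < self.walk_min:
            raise ValueError("need 0 < rest_max < walk_min")

    def label(self, mean_rate: float) -> str:
        if not np.isfinite(mean_rate):
            raise ValueError("cluster mean rate must be finite")
        if mean_rate < self.rest_max:
            return "resting"
        if mean_rate > self.walk_min:
            return "walking"
        return "grazing"


def label_clusters(
    summary: pd.DataFrame, rule: LabelRule | None = None
) -> dict[int, str]:
    """Behavior per cluster from its mean rate Sr."""
    rule = rule or LabelRule()
    return {
        int(row["cluster"]): rule.label(float(row["rate_mean"]))
        for _, row in summary.iterrows()
    }


def assign_fix_labels(
    assignment: ClusterAssignment,
    cluster_labels: dict[int, str],
    segments: pd.DataFrame,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Per-fix behavior series: each fix inherits its segment's label.

    Returns one row per fix inside a segment with columns ``animal_id,
    timestamp, hour, segment_id, cluster, behavior, rate``.
    """
    cluster_of = dict(zip(assignment.segment_ids, assignment.labels))
    missing = [c for c in set(cluster_of.values()) if c not in cluster_labels]
    if missing:
        raise ValueError(f"unlabeled cluster(s): {sorted(missing)}")
    by_animal = {
        aid: group.reset_index(drop=True)
        for aid, group in features.groupby("animal_id", sort=False)
    }
    frames = []
    for _, seg in segments.iterrows():
        group = by_animal[seg["animal_id"]]
        window = group.iloc[seg["start_index"] : seg["end_index"] + 1]
        cluster = int(cluster_of[seg["segment_id"]])
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": seg["animal_id"],
                    "timestamp": window["timestamp"].to_numpy(),
                    "hour": window["hour"].to_numpy(),
                    "segment_id": seg["segment_id"],
                    "cluster": cluster,
                    "behavior": cluster_labels[cluster],
                    "rate": window["rate"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def overall_average(per_animal_values) -> float:
    """Unweighted mean of per-animal values, nulls excluded."""
    vals = np.asarray(per_animal_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no non-null per-animal values")
    return float(vals.mean())


def behavior_rate_table(series: pd.DataFrame) -> pd.DataFrame:
    """Mean fix-level rate per animal per behavior, plus the overall mean.

    Rows are behaviors, columns animals plus ``overall``; the overall
    column is the unweighted mean of the per-animal values, with absent
    behavior/animal cells left null and excluded.
    """
    table = (
        series.dropna(subset=["rate"])
        .pivot_table(index="behavior", columns="animal_id", values="rate", aggfunc="mean")
        .reindex([b for b in BEHAVIORS if b in series["behavior"].unique()])
    )
    table["overall"] = table.apply(lambda row: overall_average(row.to_numpy()), axis=1)
    table.columns.name = None
    return table


def diurnal_distribution(series: pd.DataFrame) -> pd.DataFrame:
    """Fraction of fixes in each behavior, per animal per hour of day.

    Fractions sum to 1 within each (animal, hour); behaviors never seen in
    an hour get 0. Columns: ``animal_id, hour, frac_resting, frac_grazing,
    frac_walking``.
    """
    counts = (
        series.groupby(["animal_id", "hour", "behavior"], sort=True)
        .size()
        .unstack("behavior", fill_value=0)
    )
    for b in BEHAVIORS:
        if b not in counts.columns:
            counts[b] = 0
    fracs = counts[list(BEHAVIORS)].div(counts[list(BEHAVIORS)].sum(axis=1), axis=0)
    fracs.columns = [f"frac_{b}" for b in BEHAVIORS]
    return fracs.reset_index()


def diurnal_mean(diurnal: pd.DataFrame) -> pd.DataFrame:
    """Across-animal mean of the per-animal hourly behavior fractions."""
    return (
        diurnal.groupby("hour", sort=True)[
            [f"frac_{b}" for b in BEHAVIORS]
        ]
        .mean()
        .reset_index()
    )
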