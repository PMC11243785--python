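"""End-to-end orchestration: read -> QC -> features -> segment -> cluster
-> label -> summaries."""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import pandas as pd

from . import clasp, clustering, labeling
from .clasp import SegmentationConfig
from .io import Trajectory, WaterPoint, compute_feature_table, qc_filter_animals
from .labeling import LabelRule


@dataclass
class PipelineResult:
    """All intermediate and final products of one run."""

    features: pd.DataFrame
    segments: pd.DataFrame
    segment_features: pd.DataFrame
    assignments: dict  # animal_id -> ClusterAssignment (or {"__pooled__": ...})
    cluster_summary: pd.DataFrame  # per animal per cluster
    cluster_labels: pd.DataFrame  # {animal_id, cluster, behavior}
    series: pd.DataFrame
    rate_table: pd.DataFrame
    diurnal: pd.DataFrame
    report: dict = field(default_factory=dict)


def run_pipeline(
    trajs: list[Trajectory],
    water: WaterPoint,
    seg_cfg: SegmentationConfig | None = None,
    k: int = 6,
    rule: LabelRule | None = None,
    utc_offset: int = 0,
    per_animal: bool = True,
    max_gap: float = 180.0,
    max_missing_frac: float = 0.1,
) -> PipelineResult:
    """Run the full two-step analysis on a list of trajectories.

    Clustering is per animal by default (``per_animal=False`` pools the
    segments of all animals into one clustering). The run report records
    the effective configuration and per-stage counts.
    """
    t0 = time.perf_counter()
    seg_cfg = seg_cfg or SegmentationConfig()
    rule = rule or LabelRule()

    kept, dropped = qc_filter_animals(trajs, max_gap, max_missing_frac)
    if not kept:
        raise ValueError("no animals pass quality control")
    features = compute_feature_table(kept, water, utc_offset)
    segments = clasp.segment_trajectory(features, seg_cfg)
    seg_feats = clustering.extract_segment_features(segments, features)

    assignments: dict = {}
    label_rows = []
    summaries = []
    series_parts = []
    groups = (
        [(aid, seg_feats[seg_feats["animal_id"] == aid]) for aid in seg_feats["animal_id"].unique()]
        if per_animal
        else [("__pooled__", seg_feats)]
    )
    for key, feats in groups:
        assign = clustering.hierarchical_cluster(feats, k=k)
        seg_subset = segments[segments["segment_id"].isin(assign.segment_ids)]
        summary = clustering.summarize_clusters(assign, seg_subset, features)
        labels = labeling.label_clusters(summary, rule)
        assignments[key] = assign
        summary = summary.assign(
            animal_id=key, behavior=summary["cluster"].map(labels)
        )
        summaries.append(summary)
        for c, b in labels.items():
            label_rows.append({"animal_id": key, "cluster": c, "behavior": b})
        series_parts.append(
            labeling.assign_fix_labels(assign, labels, seg_subset, features)
        )

    series = pd.concat(series_parts, ignore_index=True)
    rate_table = labeling.behavior_rate_table(series)
    diurnal = labeling.diurnal_distribution(series)

    report = {
        "config": {
            "window": seg_cfg.window,
            "knn": seg_cfg.knn,
            "score_threshold": seg_cfg.score_threshold,
            "batch_size": seg_cfg.batch_size,
            "min_seg": seg_cfg.effective_min_seg,
            "features": list(seg_cfg.features),
            "k": k,
            "rest_max": rule.rest_max,
            "walk_min": rule.walk_min,
            "utc_offset": utc_offset,
            "per_animal": per_animal,
            "max_gap": max_gap,
            "max_missing_frac": max_missing_frac,
            "water": {"x": water.x, "y": water.y},
        },
        "animals_kept": len(kept),
        "animals_dropped": [{"animal_id": a, "reason": r} for a, r in dropped],
        "n_fixes": int(len(features)),
        "n_segments": int(len(segments)),
        "n_clusters": int(k),
        "fixes_per_behavior": series["behavior"].value_counts().to_dict(),
        "wall_time_s": round(time.perf_counter() - t0, 3),
    }
    return PipelineResult(
        features=features,
        segments=segments,
        segment_features=seg_feats,
        assignments=assignments,
        cluster_summary=pd.concat(summaries, ignore_index=True),
        cluster_labels=pd.DataFrame(label_rows),
        series=series,
        rate_table=rate_table,
        diurnal=diurnal,
        report=report,
    )
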