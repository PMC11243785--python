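# herdtrack

Unsupervised classification of livestock behavior — resting, grazing,
walking — from GPS collar tracking data, with no human observations
needed for training.

Collars on free-ranging cattle record a position every few minutes for
weeks. Supervised behavior classifiers need labeled observations that are
expensive to collect on extensive rangeland. `herdtrack` instead uses a
two-step unsupervised pipeline:

1. **Segmentation.** Each animal's sequence of per-fix movement features
   — rate *f*ᵣ (m/min), course *f*꜀ (degrees from north), and distance to
   the water source *f*_d2w (m) — is partitioned into contiguous segments
   of presumed-constant behavior with a classification-score-profile
   (ClaSP) change-point detector: every candidate split *i* is scored by
   the ROC-AUC σᵢ of a self-supervised K-nearest-neighbor classifier
   separating sliding windows before *i* from windows after it, and the
   argmax is split recursively while σ_max > 0.70. Two modifications make
   this work on multivariate, multi-week tracks: per-feature windows are
   concatenated into one vector, and the sequence is processed in
   independent 120-record (4-hour) mini-batches.
2. **Clustering and labeling.** Variable-length segments are reduced to
   (mean, sd) of their fix-level rates, grouped by Ward-linkage
   hierarchical clustering with the dendrogram cut at k = 6, and each
   cluster is labeled from its mean fix-level rate Sᵣ:
   resting if Sᵣ < 4.5 m/min, walking if Sᵣ > 25 m/min, grazing between.

Because real multi-week cattle datasets are rarely public, the package
ships a ground-truth simulator: a semi-Markov bout process with a diurnal
schedule (nocturnal resting, morning and evening grazing bouts, midday
walking to water) drives a correlated random walk with state-specific
speeds and tortuosity plus GPS position noise, so the whole pipeline can
be validated end to end against known per-fix states.

## Worked example

```python
import herdtrack as ht

cfg = ht.SimulatorConfig(n_animals=2, days=1.0, seed=1)
fixes, truth = ht.simulate_herd(cfg)
result = ht.run_pipeline(ht.herd_trajectories(fixes), water=ht.WaterPoint(0.0, 0.0))

print(result.report["n_segments"], "segments")
print(result.rate_table.round(2))
merged = result.series.merge(truth, on=["animal_id", "timestamp"])
print("agreement:", round((merged.behavior == merged.true_state).mean(), 3))
```

prints

```
34 segments
          cow000  cow001  overall
behavior
resting     1.81    2.37     2.09
grazing    13.32   11.52    12.42
walking    40.98   42.82    41.90
agreement: 0.951
```

The two one-day tracks were cut into 34 segments; clustering and
threshold labeling recover per-behavior mean rates close to the
simulator's state means (2 / 13 / 44 m/min for resting / grazing /
walking), and 95% of fixes receive their true generating state.

The same pipeline is available from the shell:

```bash
herdtrack simulate --n-animals 5 --days 7 --seed 1 --out-dir sim/
herdtrack run sim/fixes.csv --water-x 0 --water-y 0 --out-dir out/
```

which writes per-stage CSVs (features, segments, cluster summaries,
per-fix behaviors, diurnal distributions) plus a `report.json` recording
the effective configuration and per-stage counts. `features`, `segment`,
`cluster` and `label` subcommands run the stages individually on
intermediate CSVs.

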