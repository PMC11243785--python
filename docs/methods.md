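# Methods

## Movement features

Each GPS fix contributes three features. The **rate** is the Euclidean
step length between consecutive fixes divided by the elapsed minutes
(m/min); at 2-minute fixes it is the standard velocity proxy for
distinguishing resting (~2 m/min, essentially GPS jitter), grazing
(~5–20 m/min, tortuous) and walking (>25 m/min, directed). The
**course** is the step bearing in degrees clockwise from north, recomputed
from positions so the pipeline needs nothing but fixes; a zero-length
step has no heading, so its course carries the previous defined value
forward (a stationary animal keeps its last heading; a track that never
moves gets 0). The **distance to water** is the Euclidean distance to the
pasture's single water point. The first fix of every animal has no
predecessor: it keeps only d2w, is excluded from windowed analysis, and
therefore belongs to no segment.

Longitude/latitude input is projected to local meters with an
equirectangular approximation about a reference point
(x = R·cos φ₀·Δλ, y = R·Δφ, R = 6 371 008.8 m). Over a ≤10 km pasture the
distortion is below 0.1%, far below collar noise, so no projection
library or datum grid is required. Timestamps are stored as given; an
integer UTC-offset converts them to local time for hour-of-day summaries,
since diurnal behavior (grazing at 5–8 am / 5–8 pm) is a local-solar-time
phenomenon.

Quality control drops whole animals, not fixes: any inter-fix gap longer
than `max_gap` (default 180 min) or an overall missing-fix fraction above
`max_missing_frac` (default 0.1, against span/interval expected fixes)
marks a collar as failed. The defaults are configurable judgment calls —
collar-failure studies rarely publish exact cleaning thresholds — and
loosening either threshold can only keep more animals (monotone filter).

## Segmentation (step 1)

The change-point detector scores every candidate split of a window
sequence by self-supervision: hypothesize a split at *i*, label windows
before *i* class 0 and the rest class 1, predict each window's class as
the majority class of its K nearest windows (Euclidean distance), and
take the ROC-AUC of predictions against the hypothesis as σᵢ. For binary
predictions the AUC reduces to (sensitivity + specificity)/2, which is
what the implementation computes; equality with rank-based ROC-AUC is
property-tested. The split with the largest σ is accepted if it strictly
exceeds the score threshold (default 0.70) and both halves are processed
recursively; otherwise the slice is one segment.

Numerical and design choices, in the order they matter:

- **Window length w = 2** records (4 min of movement at 2-min fixes);
  K = 3 neighbors. K is odd so the majority vote cannot tie; with an even
  K, ties go to the pre-split class.
- **Multivariate windows.** The length-w subsequences of each selected
  feature are concatenated into one row vector (row length w × features),
  so one Euclidean distance covers rate, course and d2w.
- **Feature standardization, not window normalization.** Features are
  z-scored per mini-batch (zero-variance columns to zeros) and windows
  are compared raw. z-normalizing each window — the usual shape-based
  convention — would be destructive here: at w = 2 every non-constant
  window normalizes to the same two-point shape, erasing exactly the
  rate-level differences that separate behaviors.
- **Mini-batches.** The analyzed records are hard-partitioned into
  consecutive 120-record (4-h) batches, each segmented independently, so
  batch boundaries are always segment boundaries and KNN candidates stay
  temporally local; the final remainder is its own batch. Batches are
  defined by record count, not clock time. Batch-level z-scores are
  reused down the recursion rather than re-standardizing each half, so a
  window's coordinates do not depend on the recursion path.
- **Exclusion zone ±w** records around each query window (standard
  matrix-profile practice) prevents trivial self-matches; distance ties
  break toward the lower index, making the whole step deterministic.
- **Admissible splits** lie in [min_seg, m − min_seg] windows,
  min_seg = max(2w, K + 1), so both hypothetical classes always hold
  enough members to out-vote noise; a split at window index *i* places
  the fix boundary at the first record of the right-hand window.
- **Raw degrees for course.** The 0°/360° discontinuity is kept as-is; a
  northward-moving animal's course jitters across the wrap and inflates
  course distances. This is a known artifact accepted for simplicity and
  because rate dominates the segmentation in practice.

A structural limitation worth knowing: when two regimes with *identical*
feature distributions flank a distinct middle regime (stationary →
directed → stationary at the same location and approach), the AUC at
either boundary is capped well below 1 — windows of the recurring regime
scatter their neighbors evenly across both hypothetical classes — and at
the 0.70 threshold such splits often do not fire on a rate-only
analysis. In real tracks the d2w feature breaks the symmetry (the animal
ends up somewhere else), which is one concrete reason the multivariate
default outperforms rate-only segmentation; the planted three-regime
tests exercise exactly this configuration.

## Clustering and labeling (step 2)

Each segment is summarized by the mean and standard deviation of its
fix-level rates (population sd; a single-fix segment has sd 0). Course
and d2w statistics can be included but are off by default — rate-only
statistics give the most behavior-consistent clusters. Statistics are
z-scored across segments, clustered by Ward-linkage agglomerative
clustering on Euclidean distance (average/complete available), and the
tree is cut to exactly k clusters, default k = 6 (three behaviors crossed
with near/far-from-water reasoning). Cluster indices are renumbered in
order of first appearance, so the partition — not the arbitrary scipy
numbering — is the stable object. Clustering is per animal by default:
per-animal behavior models generalize better for cattle than pooled
ones; `per_animal=False` pools all segments.

Cluster summaries (mean, population sd, median of rate; fix and segment
counts) pool the **fix-level** rates of member segments, not segment
means — a resting cluster's median of 0.00 m/min is only possible at fix
level, where many 2-min steps are pure noise.

Labeling applies velocity thresholds to a cluster's mean fix-level rate
Sᵣ: resting below 4.5 m/min, walking above 25 m/min, grazing between.
The published inequalities are open on both sides, leaving the exact
boundary values undefined; both are assigned to grazing (the middle
class) and tested explicitly. The rule is deliberately the reproducible
core: the original analysis additionally used cluster medians and
diurnal context to override one borderline cluster (mean 24.84 m/min,
called walking), which no stated rule reproduces — the package surfaces
the diurnal distribution for the same human review instead of encoding
that override.

Per-behavior rate tables give each animal's mean fix-level rate per
behavior and an overall column that is the unweighted mean of per-animal
values (absent behaviors are null and excluded). Diurnal distributions
report, per animal and hour of day, the fraction of fixes in each
behavior (summing to 1), plus an across-animal hourly mean.

## Synthetic herd

The simulator generates what the pipeline needs to be falsifiable:
2-min-interval tracks with known per-fix states. A semi-Markov bout
process draws (state, duration) pairs: at each bout end the next state is
sampled proportionally to hour-of-day preference weights; durations are
uniform per state (resting 60–240 min, grazing 30–120, walking 6–30);
consecutive same-state draws merge. The default schedule encodes the
canonical cattle day — resting-dominated nights with no walking
(22:00–06:00), grazing bouts at 5–8 and 17–20, and a midday block
(9:00–13:00) where walking peaks and walking bouts steer half-weight
toward the water point.

Movement is a correlated random walk: per step, speed is gamma-distributed
(grazing mean 13, sd 10 m/min; walking 44/15) and the heading turns by a
wrapped-Cauchy angle with state concentration ρ (grazing 0.3 tortuous,
walking 0.9 directed). A resting cow is stationary (nominal speed 0):
the ~2 m/min rate observed for resting cattle at 2-min fixes is GPS
jitter, and modeling it as nominal movement *plus* jitter would
double-count. Isotropic Gaussian noise (default sd 2 m) is added to every
fix, making the observed resting rate the difference of two 2-D errors —
Rayleigh with mean sd·√(π/2)·√2/interval ≈ 1.8 m/min — which the tests
verify against that closed form. At sd 5 m the same formula gives
≈ 4.4 m/min, above the resting/grazing threshold region, which is why 2 m
is the default and 5 m a documented option for noisier collars.

What the simulator does *not* emulate: pasture boundaries (no
reflection), herd interaction, forage-driven patch selection, GPS
dropouts and multipath outliers, and fix-interval jitter. Passing
recovery tests therefore show the pipeline correctly inverts this
generative model at realistic signal-to-noise — not that it handles
collar failure modes, which the QC stage addresses separately.

## Problem sizes and tolerances

The end-to-end validation simulates 5 animals × 7 days (25 200 fixes,
~42 batches/animal), enough for hundreds of segments per animal and
stable diurnal curves while keeping the whole suite fast; the simulator
default remains 26 days, the span of the motivating field deployment.
Recovery checks use fix-level agreement against ground truth (≥ 0.75
required; ~0.95 typical), per-behavior mean rates within ±20% of the
state means (2/13/44 m/min), and grazing-bout excess measured as the mean
hourly grazing fraction over each bout window (5–7 h and 17–19 h pooled)
against the 24-h mean — pooled because long nocturnal resting bouts spill
into hour 5 and make the morning rise gradual, exactly as in observed
herds. Brute-force O(m²) oracles re-derive the KNN and score-profile
results exactly on sequences up to 200 windows; change-point detection is
required in ≥ 95/100 planted two-regime replicates with ≤ 10/100 false
alarms on i.i.d. noise.
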