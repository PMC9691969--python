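# Methods

## Model and assumptions

The composite severity score relates a test animal's multivariate
deviation from its own baseline to the maximal deviations observed in a
reference cohort with a known qualitative severity context. The model
assumes:

- each outcome measure has a meaningful pre-intervention baseline, and
  severity manifests monotonically in one known direction per variable
  (decrease for body weight change, burrowing, activity, HRV and
  temperature; increase for heart rate);
- expressing values as a percentage of the per-animal baseline removes
  units and between-animal level differences, so deviations are
  comparable across sensors and animals (the score is invariant to any
  positive rescaling of a raw variable);
- the reference cohort's worst observed deviation per variable is a
  meaningful anchor: a weight of 1 means "as bad as the reference ever
  got" for that variable. Weights are not clipped above 1 — test animals
  may exceed the reference, and those excursions are the signal in
  severe models;
- the root mean square is the right pooling rule: larger weights
  dominate, the result lives on the same scale as the weights, and a
  vector of equal weights pools to exactly that weight.

Missing-data semantics are central for real telemetry/behaviour studies
with heterogeneous sampling: at each time `N` counts the variables with
an observation. A missing variable is excluded from numerator and
denominator alike; a measured variable at or beyond baseline in the
benign direction contributes zero *and* counts toward `N`. Time points
with no observation at all carry a missing score and are ignored by the
per-animal maximum. No imputation or resampling is performed; scoring
happens on the union of observed times.

## Reference set construction

Baselines are aggregated as the mean over a configurable baseline window
(default: all negative times; the intervention sits at time 0 by
convention). A window mean is more robust to single-day noise than a
single pre-intervention day and reduces to that choice when the window
has one entry. Per-variable reference maxima are pooled over *all*
reference animals and *all* post-baseline times. A variable whose pooled
maximum deviation is zero makes the build fail loudly rather than being
dropped, because a silent drop would change `N` for every downstream
score. Self-referencing is legitimate: each reference animal then has
per-variable weights ≤ 1, and each variable attains 1 for at least one
animal/time.

## Severity levels

Per-animal maxima are clustered by univariate k-means. Two solvers are
provided: Lloyd's algorithm with 25 random restarts (scikit-learn), and
an exact O(k·n²) dynamic program over the sorted values (optimal 1-D
clusters are contiguous intervals). The DP is the recommended mode for
reported thresholds and serves as the oracle for the heuristic in the
tests.

The number of levels is chosen from the within-cluster sum-of-squares
(WSS) curve, computed at the DP optimum for each candidate k (default
range 1–8) so the curve is deterministic. The elbow is the k maximising
the second difference of **log** WSS, i.e. the largest
`wss[k−1]·wss[k+1]/wss[k]²`. The log scale is essential and was a
deliberate design choice: the absolute k=1→2 drop in WSS dominates a raw
second difference for essentially any clustered data, always returning
k=2, whereas a visual scree elbow marks where the *proportional* decay
stalls. A floor of `1e−12·max(WSS)` keeps the log finite when some k
separates the data perfectly (the smallest such k then wins). The
selected k is always user-overridable.

Thresholds are the within-cluster maxima (upper level bounds), so every
fitted value obeys "≤ its level's bound, > the bound below"; a
midpoint-between-clusters mode is offered as an alternative since the
printed form of published thresholds cannot distinguish the two.
Grading maps a value to the smallest level whose bound is ≥ the value;
ties grade into the lower level; values beyond the top bound grade into
the top level and are flagged as beyond the reference range.

## Bootstrap

Group means of per-animal maxima and cluster centroids get 95%
bias-corrected and accelerated (BCa) intervals, default B = 10,000
replicates from one seeded generator per call. z0 comes from the
proportion of replicates below the point estimate, the acceleration from
jackknife skewness. When every replicate ties with the estimate or the
jackknife is flat, the percentile interval is returned with a warning
and the fallback recorded in the result metadata. Centroid intervals
hold cluster memberships fixed at the fitted assignment and resample
member values within each cluster; re-running the clustering inside each
replicate is a defensible alternative we did not adopt, because with
small clusters it makes the statistic's identity (which cluster is
"L2"?) unstable across replicates. Singleton clusters are skipped (no
jackknife exists).

## Synthetic cohorts

The generator emulates the statistical structure the model assumes: a
baseline plateau, an abrupt intervention-time deflection per variable
(direction-aware), exponential recovery with a per-variable half-life,
additive Gaussian noise on the percent scale (direct control of weight
perturbations), per-variable sampling periods (daily weighing vs.
sub-daily telemetry), optional i.i.d. post-baseline missingness, and an
optional humane-endpoint rule that truncates a record when a monitored
variable drops past a cut-off (e.g. 20 % body-weight loss). Between-
animal heterogeneity is a per-animal multiplicative factor on the
deflections (CV 0.1 by default); decrease-type deflections are clamped
at 100 % of baseline. Default parameters mimic a transmitter-
implantation cohort qualitatively: 13 animals, ~11 % body-weight drop
recovering over ~10 days, burrowing collapsing by ~74 % with fast
recovery, a transient ~11 % heart-rate rise, deep slow-recovering HRV
and activity drops, and a small (~0.7 %) temperature dip over 14 study
days with a 2-day baseline phase.

What the generator does **not** emulate: temporal autocorrelation of the
noise, circadian structure, variable-specific non-exponential recovery
shapes, informative (severity-dependent) missingness, and mortality.
Tests passing on these cohorts therefore demonstrate correctness of the
scoring algebra, clustering and uncertainty machinery under the model's
own assumptions — not that the default parameters reproduce any
particular real cohort's statistics.

`engineer_known_severity` inverts the score analytically (equal weights
across a chosen variable subset; RMS of equal weights equals the
weight), giving noise-free animals with exactly prescribed score
profiles for end-to-end recovery tests; a target of 1 at one time point
reconstructs the reference ceiling.

## Numerical choices

- All score arithmetic in double precision; test comparisons at 1e−12
  absolute for pure algebra, 1e−9 for values that pass through baseline
  division.
- The radar "contribution" area divides the polygon area (equal angular
  spacing, radius = weight, missing → 0) by the all-ones polygon; the
  sine factor cancels, leaving `Σ r_j·r_{j+1} / n` (cyclic). The value
  depends on the variable order and needs ≥ 3 variables; it is exposed
  as advisory output only.
- Delimiter auto-detection is limited to comma/tab; decimals use points.
- Pipeline outputs carry no wall-clock timestamps so equal-seed reruns
  are byte-identical.

## Problem sizes used in the checks

The suite runs desk-scale: randomized formula-agreement checks use 100
cohorts of ≤ 5 animals × ≤ 6 variables × ≤ 10 times; clustering-oracle
fixtures stay ≤ 50 points; bootstrap calibration uses 500 simulated
Normal(1,1) datasets of n = 30 with B = 2,000 replicates (the default
B = 10,000 is used for single intervals); recovery tests use cohorts of
6–200 animals. These sizes were chosen so the entire suite completes in
well under a minute while keeping Monte-Carlo error far below the
asserted tolerances.

## Known limitations

- The severity scale is only as good as its reference cohort: maxima are
  extreme statistics, sensitive to the reference sample size and noise
  level, and inherit its qualitative severity label.
- The radar area fraction is order-dependent; reporting should fix and
  state the variable order.
- The scree elbow is a heuristic surrogate for expert judgement; k
  should be inspected (the full WSS curve is returned) and can be fixed
  explicitly.
- Variables with tiny reference deviations (e.g. temperature, ~1 % of
  baseline) give noise a large leverage on their weights; consider
  excluding near-flat variables or widening the reference cohort.
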