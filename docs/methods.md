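# Methods

This note records the model, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## The SOM variant implemented

`airsom` implements the classical **sequential (online) Kohonen SOM**
with a **bubble (indicator) neighborhood**:

- One observation is presented per iteration, drawn uniformly with
  replacement from the training matrix. No epoch structure is imposed.
- The update moves every codebook whose *planar grid distance* to the BMU
  is **strictly less** than the current radius by `α(t)·(z − w)`, i.e.
  toward the presented observation. Some textbook presentations write
  the update toward a neighborhood *mean* of provisionally assigned
  observations; that describes the batch SOM hybrid, and it is
  incompatible with one-day-at-a-time presentation. We implement the
  standard online rule, which is also what the widely used R `kohonen`
  implementation does in its sequential mode.
- The strict inequality in the neighborhood makes the held final radius
  of 1.0 equal BMU-only fine tuning on a unit-spaced grid — the late
  phase of training is an online k-means polish.
- BMU ties break to the lowest node id (deterministic).

Grids are rectangular (default) or hexagonal (even rows offset +0.5,
row spacing √3/2), nodes ordered row-major from the bottom-left. A 1-D
grid is just `Y = 1`.

### Schedules and their defaults

| parameter | default | meaning |
|---|---|---|
| `t_total` | 500·k | iterations; the standard ≥500-per-node recommendation |
| `alpha_start → alpha_end` | 0.05 → 0.01, linear over T | learning rate for classification-oriented maps |
| `radius_start` | 2/3-quantile of distinct node-to-node distances | initial bubble covers most of the map |
| `radius_end` | 1.0 | BMU-only fine tuning on a unit grid |
| `radius_fraction` | 1/3 | radius reaches its floor after T/3, then holds |
| restarts | 10 | independent initializations |

α(t) = alpha_start + (alpha_end − alpha_start)·t/T, so for a 4×4 map
(T = 8000) the midpoint rate is exactly 0.03.

The **restart rule** follows the "most frequent QE" convention: the QE of
each restart is rounded to 3 decimals (on the standardized scale, where
QE is O(1), so 3 decimals is a meaningful bin width), the modal bin wins,
and ties break to the lowest unrounded QE. When all rounded QEs are
distinct this degenerates to QE minimization. Restart seeds derive from
the top-level seed via `numpy.random.SeedSequence(seed, spawn_key=(r,))`;
every stochastic component in the package uses the same scheme, so a
single integer seed reproduces any artifact bit-exactly.

### Missing data

Training is complete-case. Projection of new days
(`assign`) tolerates missingness through a masked Euclidean distance
rescaled by √(p/p_obs), which is unbiased for the full squared distance
under exchangeable coordinates and keeps complete and incomplete days on
one scale. Days with no observed entries are returned unlabeled (−1).
Standardization parameters are fitted once on the training set and reused
for all projections and all map sizes.

## Map-size selection

- **CH index**: `(SS_B/(k−1))/(SS_W/(n−k))` on the standardized training
  data. Zero within-class scatter is reported as infinite CH (perfect
  separation), not an error.
- **Adjusted R²**: each *raw* pollutant regressed on class indicators
  (equivalently, predicted by class means); `adj R² = 1 − (1−R²)(n−1)/(n−k)`
  with k the realized (non-empty) class count. Raw values are used
  because the question is how well classes approximate the original
  concentrations; standardization would not change R² but would change
  its reading. Pooled summaries are the mean/min/max over pollutants.
- **Grid shapes** for non-square k use the most-square factor pair
  (X ≥ Y, minimizing X−Y); primes get a 1-D map. This is a convention —
  nothing in the method forces it.
- `size_scan` flags the CH-maximal k and the k values with above-median
  pooled-R² gains but sets no `chosen_k`: on data without sharp cluster
  boundaries (the typical multipollutant situation) the statistics point
  in different directions — CH toward very coarse partitions, R² toward
  fine ones — and the analyst must weigh variance explained against
  per-class sample size (at a 2,724-day record, k=16 leaves 170 expected
  days per class; k=28 drops below 100).

Classical MDS is Torgerson double centering with an eigendecomposition
(deterministic up to sign; output dimensions ordered by variance). It is
O(n²) in memory, so for display on multi-thousand-day records a seeded
subsample is the intended use.

## Comparators

- **k-means**: Lloyd iterations to an assignment fixpoint, initialized
  from k sampled data rows — deliberately the same initialization policy
  as the SOM so comparisons are like-for-like rather than flattering
  either method. Empty clusters are reseeded from the farthest point.
  Best of n restarts by within-SS.
- **Ward**: delegated to `scipy.cluster.hierarchy.linkage(method="ward")`,
  i.e. the Ward.D2 convention with merge heights on the distance scale.
  (R's `hclust` historically also offers "ward.D", which skips squaring
  and yields different heights; results are not interchangeable.) The
  test suite validates the full merge sequence against an independent
  Lance–Williams recurrence.
- **Sammon mapping**: gradient descent on the Sammon stress with
  backtracking step halving, initialized from classical MDS; accepted
  iterations strictly decrease the stress, so the result is never worse
  than the MDS start. Duplicate points make the stress undefined (zero
  denominators); a jitter option perturbs the offending distances.
- **Agreement** between two partitions is the percent of days matched
  after an optimal one-to-one matching of class identities (Hungarian
  algorithm on the padded confusion matrix). "Direct agreement" has no
  single standard definition; optimal matching is the most favorable and
  fully reproducible convention, and a greedy variant is available to
  gauge sensitivity to the matching rule.

## Evaluation conventions

- **Within-class dissimilarity** is member-to-assigned-codebook distance
  (the same quantity QE averages), not mean pairwise distance.
- **Reliability CV** = 100·SE/mean of those distances. The default SE
  convention (`as_printed`) is sd/n, matching how the statistic is
  printed in applied reports of this design; the conventional sd/√n is
  available, the two differ exactly by √n_c, and the convention used is
  recorded in the output's metadata. Classes with <2 members are flagged,
  not scored.
- **Persistence** uses run-length encoding over consecutive calendar
  days; a gap of ≥2 days between observations breaks a run even within
  one type, because persistence across unobserved days is unknowable.
  Run lengths per class always sum to the class's day count.
- **Seasons** default to meteorological DJF/MAM/JJA/SON and are
  configurable; period tables take arbitrary disjoint covering ranges.

## The synthetic generator

`generate` draws a latent day-type sequence from a first-order Markov
chain (stay-probability = `persistence`; on a switch the new type is
sampled from season-weighted probabilities **excluding the current
type**, so mean run length is exactly 1/(1−persistence)), then emits
`exp(MVN(log_mean_type, Σ_log))` — lognormal marginals, since real
pollutant metrics are positive and right-skewed. Each column is then
affinely transformed in log space so that the *mixture* marginal hits the
configured target mean and sd exactly in expectation (the scale solves a
one-dimensional coefficient-of-variation equation by root finding; the
location then fixes the mean).

`table1_profile` encodes the study conditions the package is exercised
under: ~2,922 days (8 calendar years), 10 metrics in two correlated
blocks (primary combustion: CO, NO₂, NOx, SO₂, EC, OC; secondary
photochemical: O₃, SO₄, NH₄, NO₃; within-block log correlation 0.55,
cross-block 0.15, within-type log-sd 0.45), four overlapping latent
regimes (clean / primary-dominated / secondary-dominated / all-high) with
log-scale half-separation 0.55, winter-peaking primary and summer-peaking
secondary seasonality, persistence 0.45 (mean duration ≈ 1.8 days), and
0.7% cell-wise missingness leaving ≈2,700 complete days. Marginal targets
are typical urban central-monitor summary statistics (CO 1.0/0.8 ppm,
NO₂ 40.3/15.5 ppb, NOx 115.9/107.2 ppb, O₃ 41.8/20.4 ppb, SO₂ 14.2/14.5
ppb, EC 1.4/0.9, OC 4.0/2.3, NH₄ 2.0/1.2, NO₃ 0.9/0.8, SO₄ 4.5/3.1
μg/m³). The overlap is intentional: real multipollutant data show no
sharp cluster boundaries, and the generator reproduces the resulting
behavior (CH maximal at very small k, adjusted R² rising smoothly,
heterogeneous class frequencies of roughly 1–14%, sub-2-day durations).

`separated_profile` is the opposite regime for recovery experiments:
type *t* elevates log-dimension *t* by 4 within-type sds (log-sd 0.25,
spherical), making every pair of type means √2·4 pooled sds apart. On
this data a 2×2 SOM recovers the latent labels at ≈99% agreement, the CH
maximum lands at the true k, and BMU-only training agrees with Lloyd's
k-means ≥95% — the degenerate-equivalence check.

What the generator does **not** emulate: real meteorology–pollution
dependence (covariates are simple type-conditioned normals), measurement
error structure, long-term emission trends, instrument-specific
missingness patterns (cells go missing independently), and any spatial
structure. Passing tests therefore demonstrate that the algorithms are
implemented correctly and behave as expected on data with the assumed
statistical shape — not that 16 classes, or any particular map, is right
for a given real monitoring record.

## Problem sizes used in tests and the acceptance script

Experiments are sized for quick, repeated runs: recovery and equivalence
checks use 200–400-day series over 10–20 seeds with 2–5 restarts; size
scans cover k = 2–8 with shortened schedules (T = 1000); the full-scale
organization check trains a 4×4 map with 10 restarts and the default
T = 8000 on a complete ~2,700-day record. These sizes give stable
statistics while keeping the whole suite in the tens of seconds.

## Known limitations

- The sequential SOM is order-sensitive by construction; determinism
  comes from seeding, and the restart policy (modal QE) addresses
  initialization variance, not presentation-order variance.
- The bubble neighborhood with a final radius of 1.0 never updates
  non-BMU nodes late in training; maps can retain mild twists that a
  Gaussian-kernel or batch SOM would smooth. Those variants are out of
  scope.
- Empty nodes are legal and reported with frequency 0; on very
  overlapping data with large maps they do occur.
- CH and adjusted R² are decision aids; neither identifies a "true" k on
  data without separation, and the package deliberately refuses to pick
  one automatically.
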