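# airsom

Self-organizing-map (SOM) day typing for multipollutant ambient air
quality time series.

## The problem

Health studies of air pollution mixtures need exposure metrics that
describe the *combination* of pollutants present on a day, not each
pollutant in isolation. One practical strategy is to classify calendar
days into a discrete set of **day types** — groups of days with similar
multipollutant profiles — and compare health outcomes across types. This
package implements that classification with a Kohonen self-organizing
map: a hybrid of vector quantization (like k-means) and low-dimensional
projection (like MDS) that places the day-type profiles on a small planar
grid so that **similar day types are map neighbors**. The organized
layout is the point: with 16 or more classes, an unordered cluster list
is hard to reason about, while a map reads at a glance.

## The method

Days are rows `Z_i` of an `n × p` matrix (one column per pollutant
metric). After complete-case filtering and standardization (each column
to mean 0, sd 1), the map `M` of `k = X·Y` nodes carries one codebook
vector `w_m = (μ_m1, …, μ_mp)` per node. Sequential training repeats, for
`t = 1..T`:

1. draw a day `Z_i(t)` at random;
2. find its best matching unit (BMU) `m*` by Euclidean distance
   `D(Z_i, w_m) = (Σ_j (Z_ij − μ_mj)²)^{1/2}`;
3. update every node within a planar radius of the BMU (bubble
   neighborhood) toward the day:
   `w_m ← w_m + α(t) · (Z_i − w_m)`.

The learning rate `α(t)` decays linearly 0.05 → 0.01 over the run; the
neighborhood radius starts at the 2/3-quantile of node-to-node distances
and shrinks to 1.0 over the first third of iterations (then holds, which
is BMU-only fine tuning on a unit grid); `T` defaults to 500·k. Training
runs with 10 random restarts and keeps a run with the modal (most
frequent) quantization error, QE = mean day-to-assigned-codebook
distance.

Map-size selection is supported by the Calinski–Harabasz index
`CH = (SS_B/(k−1)) / (SS_W/(n−k))`, a per-pollutant adjusted-R² scan
(one-way ANOVA on class indicators), and classical MDS displays.
Evaluation covers class frequencies, run-length persistence, seasonal and
period contingency tables, per-class covariate summaries, within-class
CV reliability, a Ward dendrogram and a Sammon projection of the class
profiles, and label-matched agreement against k-means and Ward
partitions. A seeded synthetic generator produces multipollutant series
with known latent day types so the whole pipeline is testable without any
data download.

## Worked example

```python
from airsom import (SOMGrid, TrainingSchedule, complete_case_filter,
                    frequency_table, generate, standardize, table1_profile,
                    train_with_restarts)

Z, truth = generate(table1_profile(seed=1))   # 2922 days x 10 pollutants
Zc = complete_case_filter(Z)                  # 2729 complete days
Zs, params = standardize(Zc)
model = train_with_restarts(Zs.values, SOMGrid(4, 4),
                            TrainingSchedule(seed=1), n_restarts=10,
                            standardization=params, columns=Zc.columns)
print(round(model.qe, 3))                     # 1.407
freq = frequency_table(model.assignments, classes=range(16))
print(round(freq["percent"].min(), 1),        # 2.2
      round(freq["percent"].max(), 1))        # 11.8
```

The quantization error (1.407 on the standardized scale) is the mean
distance between a day and its day-type profile; the frequency range
(2.2%–11.8% across the 16 nodes) shows the map resolving both common and
rare multipollutant combinations. The scripts in `examples/` walk through
each capability (training, size selection, evaluation, method comparison,
projection of incomplete new days) and print annotated output; the
numbers above are what `examples/01_simulate_and_train.py` prints.

There is also a thin CLI mirroring the workflow:

```sh
airsom simulate --n-days 2922 --seed 1 --out days.csv
airsom select-size --input days.csv --kmin 2 --kmax 30 --seed 1 --out scan.csv
airsom train --input days.csv --x 4 --y 4 --seed 1 --out model.som
airsom evaluate --input days.csv --model model.som --out evaldir/
airsom compare --input days.csv --model model.som --out agreement.csv
```

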