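# cgmentropy

Entropy-based classification of continuous glucose monitoring (CGM) time
series, with characterization of how acquisition artifacts degrade the
classification.

CGM sensors sample interstitial glucose every 5 minutes (288 samples/day)
for a few days at most, and the records are routinely affected by missing
samples, sensor saturation at the device scale limits, and unstable early
segments. `cgmentropy` is for researchers who want to use time-series
*irregularity* as a discriminative feature on such data — for example to
separate glucose dynamics recorded at two stages of a metabolic
intervention — and need to know how robust that feature is to each
artifact before trusting it.

## The statistics

For a series `x = x_1 … x_N`, templates of length `m` are compared by the
Chebyshev distance `d_ij = max_k |x_{i+k} − x_{j+k}|` with tolerance
`r·SD(x)`:

* **SampEn(m, r)** = `−ln(A/B)`, where `B` counts template pairs (`j ≠ i`)
  within tolerance at length `m` and `A` the same pairs still within
  tolerance at length `m+1`. It is the negative log conditional
  probability that sequences similar for `m` points remain similar for
  `m+1` — higher values mean more irregular dynamics.
* **FuzzyEn(m, r, n)** replaces the hard threshold by the continuous
  membership `exp(−(d/(r·SD))^n)` and subtracts each window's own mean
  before comparison; `FuzzyEn = ln φ_m − ln φ_{m+1}`.
* **FuzzyEn\*** is FuzzyEn without the window-mean subtraction, isolating
  the contribution of the fuzzy dissimilarity.

Per-record entropy scores feed a two-class ROC analysis: the empirical
AUC is the normalized Mann–Whitney statistic over all cross-class score
pairs, the parametric counterpart is the binormal model
`AUC = Φ(Δμ/√(σ_A² + σ_B²))`, and an accuracy-optimal threshold yields
sensitivity/specificity/accuracy. Leave-one-out validation holds out one
record per class, re-fits the threshold, and classifies the held-out
pair. Artifact experiments inject isolated missing samples (zero
spikes), single saturation pulses at 22.2 mmol/L, center truncation and
day-shifted windows, and report AUC per condition.

Because no public CGM dataset accompanies the analysis, the package ships
a synthetic cohort generator (circadian + meal structure plus a MIX-style
blend of AR(1) and white noise whose mixing weight controls the "true"
irregularity of each class) and the published per-record SampEn scores of
the 23 six-day records (14 in class A1, 9 in class B1) together with the
25 published leave-one-out rows, as replay fixtures.

## Worked example

```python
from cgmentropy import EntropyClassifier, load_fixtures

fx = load_fixtures()                       # published per-record SampEn scores
results = EntropyClassifier.from_scores(fx.scoreset()).fit()
print(results.summary())
```

```
Entropy two-class classifier (A1 vs B1)
==============================================
Metric:            SampEn(m=1, r=0.17), six-day records
Records:           14 A1 / 9 B1
AUC (empirical):   0.9048  [0.780, 1.000]
AUC (binormal):    0.8226
AUC SE (H-M):      0.0637
Threshold (midpoint): 0.2611
Sensitivity:       0.857
Specificity:       1.000
Accuracy:          0.913
Mann-Whitney p:    0.001467
```

The empirical AUC of 0.90 means 114 of the 126 cross-class score pairs
rank the A1 record above the B1 record; at the fitted threshold 12 of 14
A1 and all 9 B1 records classify correctly (accuracy 91.3%). The
leave-one-out replay follows directly:

```python
loo = results.loo(fixed_pairs=fx.loo_pairs())
print(loo.mean_auc, loo.mean_accuracy_pct)   # 0.905 80.0
```

Fitting on raw records instead runs the entropy stage and the (m, r)
grid search:

```python
from cgmentropy import CohortSpec, EntropyClassifier, generate_cohort

cohort = generate_cohort(CohortSpec(seed=1))     # 14 + 9 six-day records
results = EntropyClassifier(records=cohort).fit()
print(results.params.tag(), round(results.auc, 3))
# SampEn(m=2, r=0.15) 0.944
```

The same operations are scriptable from a shell via the `cgmentropy`
CLI (`simulate`, `entropy`, `grid`, `inject`, `sweep-*`, `loo`,
`reproduce-reference`).

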