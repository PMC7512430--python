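# Methods

## Entropy estimators

Both estimators operate on a series `x` of length `N` and compare
templates (subsequences) of length `m` against all other templates,
excluding self-matches (`j ≠ i`); overlapping templates are allowed.
`N − m` templates are used at both lengths `m` and `m + 1` (the
Richman–Moorman convention), so the numerator and denominator counts are
taken over the same template set and their per-template normalisation
constants (`1/(N−m−1)` within template, `1/(N−m)` across templates)
cancel in the final ratio. All logarithms are natural.

**SampEn(m, r)`= −ln(A/B)`** with hard threshold `r·SD(x)` on the
Chebyshev distance. When no template pair matches at either length the
statistic is undefined; the package signals this with a dedicated
exception rather than returning 0 or infinity, and grid searches drop
the offending configuration with a warning.

**FuzzyEn(m, r, n)** subtracts each window's own mean before distances
are taken and replaces the hard threshold with the membership
`exp(−(d/(r·SD))^n)`; the statistic `ln φ_m − ln φ_{m+1}` is always
finite because memberships are strictly positive. **FuzzyEn\*** skips
the mean subtraction only. No additional z-scoring is applied before
the per-window centering: only the transformation the estimator itself
defines.

Conventions worth stating explicitly because published descriptions of
these estimators frequently leave them open:

* **Tolerance is SD-relative.** `r` is a fraction of the standard
  deviation (ddof = 0) of the exact series handed to the estimator —
  after any interpolation, truncation or artifact injection, before
  nothing else. This is the universal convention for `r ∈ [0.15, 0.30]`
  and makes both entropies invariant under positive rescaling of the
  input (tested to 1e−10). A consequence adopted deliberately: injected
  artifacts (zero spikes, saturation pulses) inflate the SD and hence
  the tolerance; the artifacted series is taken as given.
* **Parameter ranges.** `m ∈ {1, 2, 3}` and `r ∈ {0.15 … 0.30, step
  0.01}` form the conventional grid (48 SampEn configurations); values
  outside it are accepted but raise a `ParameterRangeWarning`. The fuzzy
  exponent grid is `n ∈ {0.25 … 3.0, step 0.125}` (23 values), which
  contains the reference optimum 0.625 and the Gaussian point `n = 2`.
* **Implementation.** Pairwise template distances are computed as full
  `(N−L+1)²` Chebyshev matrices and cached per (length, centering), so a
  grid search touches each matrix once per record. Equivalence with a
  naive double-loop oracle is maintained to 1e−12 for `N ≤ 300` in the
  test suite.

A six-day record at 5-minute sampling has `N = 1728`; records need
`N ≥ m + 2` and nonzero variance.

## ROC surface

The empirical AUC is the normalised Mann–Whitney statistic (ties count
one half). The binormal AUC is `Φ(Δμ/√(σ_A²+σ_B²))` with per-class
sample means and SDs (ddof = 1). The AUC standard error uses the
Hanley–McNeil estimator with `Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`;
confidence intervals are `AUC ± z·SE` clipped to [0, 1].

The decision rule is "A1 iff score > threshold". The threshold scan
maximises pooled accuracy over all cuts between adjacent distinct pooled
scores; ties break toward higher specificity, then the higher cut. Two
conventions for reporting the selected cut coexist because both appear
in published per-record tables computed from the same data: `midpoint`
(the midpoint of the two scores straddling the best cut — the canonical
one, used by leave-one-out validation) and `data_value` (the smallest
score classified as A1, to be used with the `≥` rule). On the packaged
score table the conventions give 0.2611 and 0.2625 respectively, with
identical confusion matrices.

Rank-sum p-values use the tie-corrected normal approximation with
continuity correction; an exact-enumeration option (via scipy) is
available for small samples. The degenerate all-tied case returns p = 1.

Leave-one-out validation draws one record per class uniformly *with
replacement across iterations* (25 by default), re-fits the threshold on
the remaining records, and scores the held-out pair all-or-nothing: a
row counts 100% only if both records classify correctly. Per-record
scores are cached, so holding records out never changes the scores of
the rest. A replay mode runs an explicit list of held-out pairs
deterministically.

## Artifact model

* **Missing samples** — `round(f·N)` positions (ties up), drawn
  uniformly among all pairwise non-adjacent position sets (the
  single-missing-sample regime), are set to 0 and masked. The uniform
  draw uses the combinatorial bijection between non-adjacent `k`-subsets
  of `{0…N−1}` and arbitrary `k`-subsets of `{0…N−k}`, which is exact
  and O(N); fractions above `(N+1)/2N` are infeasible and rejected.
  Sweeps score the spiked series directly ("spikes down to zero"); a
  recovery mode interpolates first.
* **Saturation** — exactly one contiguous pulse of 6–60 samples at the
  device ceiling 22.2 mmol/L, start uniform over placements that keep
  the pulse inside the record. The low limit 2.2 mmol/L is available via
  the amplitude field.
* **Truncation** — center slices (start `⌊(N−L)/2⌋`) avoid border
  effects; day-aligned windows implement the time-offset analysis
  (3-day windows at shifts 0–3 days share two days of data between
  adjacent shifts).
* **Interpolation** — linear between nearest observed neighbours;
  leading/trailing gaps copy the nearest observed value. Observed
  samples are never modified.

The experiment composition order is fixed: interpolate real gaps →
truncate/window → inject synthetic artifact → entropy.

Stochastic sweeps default to 10 repetitions per condition and report
mean ± SD; repetition `rep` of condition `c` under master seed `s` uses
`default_rng([s, c, rep])`, making every sweep bit-for-bit reproducible.
Deterministic sweeps (length, offset) report SD exactly 0.

## Synthetic cohort generator

Each record is `baseline + circadian sinusoid + meals + s(t)`, clamped
to the device range [2.2, 22.2] mmol/L:

| parameter | default | meaning |
|---|---|---|
| `baseline` | 7.5 mmol/L | mean glucose level |
| `circadian_amplitude` | 1.0 mmol/L | 24-h sinusoid amplitude |
| `meal_amplitude` | 3.0 mmol/L | Gaussian meal bumps at 07:30/12:30/18:30, σ = 45 min, timing jitter ±1 h, amplitude jitter ±20% |
| `noise_sd` | 0.5 mmol/L | stationary SD of the stochastic term |
| `ar_coefficient` | 0.9 | lag-1 coefficient of the correlated component |
| `irregularity_a1` / `irregularity_b1` | 0.55 / 0.35 | MIX weight `p` per class |
| `irregularity_jitter` | 0.10 | SD of per-record jitter on `p`, clipped to [0, 1] |
| `days`, `n_a1`, `n_b1` | 6, 14, 9 | cohort layout of the target study |

The stochastic term is the MIX-style blend
`s = (1−p)·AR(1)(φ, σ) + p·white(σ)` with both components at equal
stationary variance; entropy estimators are monotone in the white-noise
weight `p`, which is exactly the family these estimators are known to
resolve well, so `p` is the class-contrast dial. The per-record jitter
on `p` emulates inter-patient heterogeneity — without it any useful
class contrast separates perfectly (AUC 1.0), unlike real cohorts whose
score distributions overlap.

Defaults were fixed once by a calibration run: with the values above a
default cohort's SampEn AUC is ≈ 0.9 (high but imperfect), equal class
irregularities give chance-level AUC, and separability grows
monotonically with the contrast. The generator reproduces the *layout*
of the target data (sampling, duration, range, class orientation, score
overlap), not its physiology: no glucose–insulin dynamics, no sensor
calibration drift, no treatment effect. Passing tests on synthetic
cohorts therefore demonstrate correctness and qualitative robustness of
the pipeline, not clinical performance on real CGM records.

## Problem sizes used in tests and the acceptance script

All published-score computations run on the packaged 23-record table and
are instantaneous. Synthetic experiments in the acceptance script use
the full six-day 14 + 9 cohort (grid search over 48 configurations;
missing-sample and saturation sweeps at 10 repetitions per condition;
length and offset sweeps deterministic). Unit and property tests use
one-day cohorts and short series so the whole suite stays fast; the
oracle-equivalence checks cap `N` at 300 where the O(N²·m) brute force
is cheap.

## Known limitations

* The standard-error estimator and confidence-interval procedure behind
  some published AUC uncertainty figures are not identifiable from their
  description; the package reports Hanley–McNeil SEs and
  normal-approximation CIs and documents them as such (they do not
  reproduce the published SE 0.0708 for AUC 0.90 at 14 + 9).
* One published leave-one-out row is internally inconsistent (its
  printed threshold presupposes a score the same row lists as held out);
  the replay reproduces the other 24 rows exactly and all summary
  statistics.
* FuzzyEn ≥ 0 is guaranteed analytically only for the non-centered
  variant (distances grow with template length pointwise); with
  per-window centering the inequality is checked empirically and holds
  on all tested inputs.
* Missing epochs longer than one sample (record splitting) and artifact
  *detection* are out of scope; the injectors characterize, they do not
  flag.
* Artifact sweeps on the synthetic cohort validate the machinery
  (reproducibility, repetition semantics, recovery by interpolation), not
  the *direction* of the clinical effect: because the injected artifacts
  are identically distributed in both classes and the tolerance is
  SD-relative, the MIX-driven class ordering is largely insensitive to
  them, and mean AUC under missing-sample or saturation injection stays
  near the clean baseline instead of degrading the way real cohorts do.
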