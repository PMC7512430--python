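"""Characterization experiments: grid search, artifact sweeps, LOO validation.

Orchestrates the analyses that turn a labeled cohort of CGM records into
classification summaries:

* (variant, m, r, n) grid search maximising empirical AUC;
* record-length, missing-sample, sensor-saturation and time-offset sweeps;
* leave-one-out validation (one held-out record per class per iteration);
* per-record entropy-versus-length stability profiles.

All stochastic sweeps are reproducible bit-for-bit from (records, seed,
config): repetition ``rep`` of condition ``c`` uses the child generator
``default_rng([seed, c, rep])``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .artifacts import (
    ArtifactSpec,
    extract_window,
    inject_missing,
    inject_saturation,
    interpolate_missing,
    truncate_center,
)
from .entropy import EntropyEngine, EntropyParams, UndefinedEntropyError
from .records import GlucoseRecord
from .roc import (
    ROCResult,
    ScoreSet,
    empirical_auc,
    evaluate_scoreset,
    mann_whitney_test,
    optimal_threshold,
)

logger = logging.getLogger(__name__)

#: Conventional parameter grids.
DEFAULT_M_GRID = (1, 2, 3)
DEFAULT_R_GRID = tuple(np.round(np.arange(0.15, 0.301, 0.01), 2))
DEFAULT_N_GRID = tuple(np.round(np.arange(0.25, 3.001, 0.125), 3))
DEFAULT_FRACTIONS = (0.025, 0.05, 0.075, 0.10)
DEFAULT_PULSE_LENGTHS = tuple(range(6, 61, 6))
DEFAULT_SHIFTS = (0, 1, 2, 3)


def split_cohort(records: list[GlucoseRecord]) -> tuple[list[GlucoseRecord], list[GlucoseRecord]]:
    a = [r for r in records if r.label == "A1"]
    b = [r for r in records if r.label == "B1"]
    if len(a) < 1 or len(b) < 1:
        raise ValueError("cohort must contain records of both classes A1 and B1")
    return a, b


def score_records(
    records: list[GlucoseRecord], params: EntropyParams
) -> ScoreSet:
    """Entropy score of every record; returns a ScoreSet keyed by record id."""
    a, b = split_cohort(records)
    return ScoreSet(
        scores_a1=[EntropyEngine(r.values).score(params) for r in a],
        scores_b1=[EntropyEngine(r.values).score(params) for r in b],
        metric_tag=params.tag(),
        ids_a1=[r.record_id or i + 1 for i, r in enumerate(a)],
        ids_b1=[r.record_id or i + 1 for i, r in enumerate(b)],
    )


def cohort_auc(records: list[GlucoseRecord], params: EntropyParams) -> float:
    return empirical_auc(score_records(records, params))


@dataclass
class GridSearchResult:
    """Full (configuration -> ROC summary) table plus the AUC argmax."""

    table: pd.DataFrame  # columns: variant, m, r, n, auc, sensitivity, ...
    results: dict[EntropyParams, ROCResult]
    best: EntropyParams

    @property
    def best_result(self) -> ROCResult:
        return self.results[self.best]

    @property
    def best_auc(self) -> float:
        return self.best_result.auc_empirical


def grid_search(
    records: list[GlucoseRecord],
    variant: str = "sample",
    m_grid=DEFAULT_M_GRID,
    r_grid=DEFAULT_R_GRID,
    n_grid=(0.625,),
) -> GridSearchResult:
    """Exhaustive (m, r[, n]) search maximising empirical AUC.

    Every record is scored under every configuration (pairwise-distance
    matrices are cached per record).  Configurations yielding undefined
    SampEn on any record are excluded with a warning.  Deterministic given
    the records; AUC ties resolve to the first configuration in grid order.
    """
    a, b = split_cohort(records)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("grid search needs at least 2 records per class")
    engines_a = [EntropyEngine(r.values) for r in a]
    engines_b = [EntropyEngine(r.values) for r in b]
    n_values = (None,) if variant == "sample" else tuple(n_grid)
    configs = [
        EntropyParams(variant=variant, m=int(m), r=float(r), n=n)
        for m in m_grid
        for r in r_grid
        for n in n_values
    ]
    results: dict[EntropyParams, ROCResult] = {}
    rows = []
    for params in configs:
        try:
            sa = [e.score(params) for e in engines_a]
            sb = [e.score(params) for e in engines_b]
        except UndefinedEntropyError as err:
            logger.warning("skipping %s: %s", params.tag(), err)
            continue
        res = evaluate_scoreset(
            ScoreSet(sa, sb, metric_tag=params.tag())
        )
        results[params] = res
        rows.append(
            {
                "variant": params.variant,
                "m": params.m,
                "r": params.r,
                "n": params.n,
                "auc": res.auc_empirical,
                "threshold": res.threshold,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "accuracy": res.accuracy,
                "p_value": res.p_value,
            }
        )
    if not results:
        raise UndefinedEntropyError("every grid configuration was undefined")
    table = pd.DataFrame(rows)
    best = max(results, key=lambda p: (results[p].auc_empirical, -configs.index(p)))
    return GridSearchResult(table=table, results=results, best=best)


def optimize_fuzzy_n(
    records: list[GlucoseRecord],
    m: int = 3,
    r: float = 0.24,
    n_grid=DEFAULT_N_GRID,
    variant: str = "fuzzy",
    optimize_mr: bool = False,
    m_grid=DEFAULT_M_GRID,
    r_grid=DEFAULT_R_GRID,
) -> tuple[float, pd.DataFrame]:
    """AUC as a function of the fuzzy exponent n; returns (argmax, curve).

    With ``optimize_mr`` the (m, r) pair is re-optimised per n; otherwise
    it is held fixed at the given values.
    """
    rows = []
    for n in n_grid:
        if optimize_mr:
            gs = grid_search(records, variant=variant, m_grid=m_grid, r_grid=r_grid, n_grid=(n,))
            auc, best = gs.best_auc, gs.best
            rows.append({"n": float(n), "auc": auc, "m": best.m, "r": best.r})
        else:
            params = EntropyParams(variant=variant, m=m, r=r, n=float(n))
            rows.append({"n": float(n), "auc": cohort_auc(records, params), "m": m, "r": r})
    curve = pd.DataFrame(rows)
    best_n = float(curve.loc[curve["auc"].idxmax(), "n"])
    return best_n, curve


@dataclass
class SweepResult:
    """AUC summary over one artifact-condition axis.

    ``auc_sd`` is exactly 0 for deterministic conditions (length, offset)
    and the across-repetition SD for stochastic ones.
    """

    condition_name: str
    conditions: list
    auc_mean: np.ndarray
    auc_sd: np.ndarray
    n_reps: int
    seed: int | None = None
    table: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.auc_mean = np.asarray(self.auc_mean, dtype=float)
        self.auc_sd = np.asarray(self.auc_sd, dtype=float)
        if self.table is None:
            self.table = pd.DataFrame(
                {
                    self.condition_name: self.conditions,
                    "auc_mean": self.auc_mean,
                    "auc_sd": self.auc_sd,
                }
            )


def length_sweep(
    records: list[GlucoseRecord],
    params: EntropyParams,
    day_grid=(1, 2, 3, 4, 5, 6),
    sample_lengths=(),
    reoptimize: bool = False,
    fixed_cohort: bool = True,
    variant: str = "sample",
) -> SweepResult:
    """AUC versus record length, center-truncated.

    Lengths are ``day_grid`` days (one day = samples_per_day) plus any
    explicit sub-day ``sample_lengths``.  ``fixed_cohort`` requires every
    record to cover the longest length (the constant-dataset design);
    otherwise short records are dropped per condition.  ``reoptimize``
    re-runs the (m, r) grid search at every length instead of holding
    ``params`` fixed.
    """
    spd = records[0].samples_per_day
    lengths = sorted(set(sample_lengths) | {d * spd for d in day_grid})
    max_len = max(lengths)
    if fixed_cohort:
        short = [r.record_id for r in records if r.n < max_len]
        if short:
            raise ValueError(f"records shorter than {max_len} samples: {short}")
    aucs = []
    kept = []
    for length in lengths:
        usable = [r for r in records if r.n >= length]
        if not (
            any(r.label == "A1" for r in usable) and any(r.label == "B1" for r in usable)
        ):
            logger.warning("length %d drops every record of one class; skipped", length)
            continue
        truncated = [truncate_center(r, length) for r in usable]
        kept.append(length)
        if reoptimize:
            aucs.append(grid_search(truncated, variant=variant).best_auc)
        else:
            aucs.append(cohort_auc(truncated, params))
    lengths = kept
    return SweepResult(
        condition_name="length_samples",
        conditions=lengths,
        auc_mean=aucs,
        auc_sd=np.zeros(len(lengths)),
        n_reps=1,
    )


def _artifact_sweep(
    records, params, conditions, make_spec, inject, reps, seed, post=None, name="condition"
) -> SweepResult:
    aucs = np.empty((len(conditions), reps))
    for ci, cond in enumerate(conditions):
        spec = make_spec(cond)
        for rep in range(reps):
            rng = np.random.default_rng([seed, ci, rep])
            perturbed = [inject(r, spec, rng) for r in records]
            if post is not None:
                perturbed = [post(r) for r in perturbed]
            aucs[ci, rep] = cohort_auc(perturbed, params)
    return SweepResult(
        condition_name=name,
        conditions=list(conditions),
        auc_mean=aucs.mean(axis=1),
        auc_sd=aucs.std(axis=1, ddof=1) if reps > 1 else np.zeros(len(conditions)),
        n_reps=reps,
        seed=seed,
    )


def missing_sweep(
    records: list[GlucoseRecord],
    params: EntropyParams,
    fractions=DEFAULT_FRACTIONS,
    reps: int = 10,
    seed: int = 0,
    interpolate: bool = False,
) -> SweepResult:
    """AUC under injected isolated missing samples (zero spikes).

    ``interpolate`` enables the recovery experiment: gaps are linearly
    interpolated before scoring instead of entering the entropy as zeros.
    """
    for r in records:
        if r.missing_mask.any():
            raise ValueError("records must be pre-interpolated before injection")
    return _artifact_sweep(
        records,
        params,
        fractions,
        lambda f: ArtifactSpec(kind="missing", fraction=float(f)),
        inject_missing,
        reps,
        seed,
        post=interpolate_missing if interpolate else None,
        name="missing_fraction",
    )


def saturation_sweep(
    records: list[GlucoseRecord],
    params: EntropyParams,
    pulse_lengths=DEFAULT_PULSE_LENGTHS,
    reps: int = 10,
    seed: int = 0,
    amplitude: float = 22.2,
) -> SweepResult:
    """AUC under one random saturation pulse per record per repetition."""
    return _artifact_sweep(
        records,
        params,
        pulse_lengths,
        lambda L: ArtifactSpec(kind="saturation", pulse_length=int(L), amplitude=amplitude),
        inject_saturation,
        reps,
        seed,
        name="pulse_length",
    )


def offset_sweep(
    records: list[GlucoseRecord],
    params: EntropyParams,
    shifts=DEFAULT_SHIFTS,
    window_days: int = 3,
) -> pd.DataFrame:
    """AUC and Mann-Whitney p per day-shifted window.  Deterministic."""
    rows = []
    for shift in shifts:
        windows = [extract_window(r, shift, window_days) for r in records]
        s = score_records(windows, params)
        mw = mann_whitney_test(s.scores_a1, s.scores_b1)
        rows.append({"shift_days": shift, "auc": empirical_auc(s), "p_value": mw.p_value})
    return pd.DataFrame(rows)


@dataclass
class LOOResult:
    """Leave-one-out validation summary.

    Each row holds one iteration: the held-out pair, the training AUC and
    threshold, the held-out scores and the all-or-nothing row accuracy
    (100% iff both held-out records classify correctly).
    """

    rows: pd.DataFrame
    mean_auc: float
    sd_auc: float
    mean_accuracy_pct: float


def loo_validation(
    scores: ScoreSet,
    n_iter: int = 25,
    seed: int | None = None,
    convention: str = "midpoint",
    fixed_pairs=None,
) -> LOOResult:
    """Leave-one-out validation on a per-record score set.

    Per iteration one A1 and one B1 record are held out (drawn uniformly
    with replacement across iterations, or replayed from ``fixed_pairs``);
    the empirical AUC and the accuracy-optimal threshold are computed on
    the remaining records, and the held-out pair is classified with the
    rule ``A1 iff score > threshold``.  Scores are cached per record —
    removing a record never changes the scores of the others.
    """
    if scores.n_a < 2 or scores.n_b < 2:
        raise ValueError("LOO validation needs at least 2 records per class")
    score_a = dict(zip(scores.ids_a1, scores.scores_a1))
    score_b = dict(zip(scores.ids_b1, scores.scores_b1))
    if fixed_pairs is not None:
        pairs = list(fixed_pairs)
    else:
        rng = np.random.default_rng(seed)
        pairs = [
            (
                scores.ids_a1[rng.integers(scores.n_a)],
                scores.ids_b1[rng.integers(scores.n_b)],
            )
            for _ in range(n_iter)
        ]
    rows = []
    for a_id, b_id in pairs:
        train = scores.without(a1_id=a_id, b1_id=b_id)
        auc = empirical_auc(train)
        thr = optimal_threshold(train, convention=convention)
        ok_a = score_a[a_id] > thr
        ok_b = not (score_b[b_id] > thr)
        rows.append(
            {
                "a1_id": a_id,
                "b1_id": b_id,
                "auc": auc,
                "threshold": thr,
                "score_a1": score_a[a_id],
                "score_b1": score_b[b_id],
                "accuracy_pct": 100.0 if (ok_a and ok_b) else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    return LOOResult(
        rows=df,
        mean_auc=float(df["auc"].mean()),
        sd_auc=float(df["auc"].std(ddof=1)) if len(df) > 1 else 0.0,
        mean_accuracy_pct=float(df["accuracy_pct"].mean()),
    )


def entropy_length_profile(
    records: list[GlucoseRecord], params: EntropyParams, length_grid
) -> pd.DataFrame:
    """Entropy versus center-prefix length, per record.

    Returns a tidy frame (record_id, label, length, entropy); the
    across-record SD per length quantifies estimator stability — it
    shrinks with length, and faster for FuzzyEn than SampEn.
    """
    rows = []
    for rec in records:
        for length in length_grid:
            if length > rec.n:
                raise ValueError(f"length {length} exceeds record {rec.record_id}")
            sub = truncate_center(rec, int(length))
            rows.append(
                {
                    "record_id": rec.record_id,
                    "label": rec.label,
                    "length": int(length),
                    "entropy": EntropyEngine(sub.values).score(params),
                }
            )
    return pd.DataFrame(rows)
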