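"""Grid search, artifact sweeps, LOO validation and stability profiles."""

import numpy as np
import pytest

from cgmentropy import (
    CohortSpec,
    EntropyEngine,
    EntropyParams,
    ScoreSet,
    entropy_length_profile,
    generate_cohort,
    grid_search,
    length_sweep,
    loo_validation,
    missing_sweep,
    offset_sweep,
    optimize_fuzzy_n,
    saturation_sweep,
    score_records,
    truncate_center,
)
from cgmentropy.entropy import UndefinedEntropyError
from cgmentropy.experiments import DEFAULT_N_GRID, DEFAULT_R_GRID, cohort_auc

PARAMS = EntropyParams("sample", 1, 0.2)


@pytest.fixture(scope="module")
def tiny_cohort():
    """Very small, short cohort for exhaustive grid checks."""
    spec = CohortSpec(n_a1=3, n_b1=3, days=1, seed=3)
    return [truncate_center(r, 150) for r in generate_cohort(spec)]


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


def test_grid_search_single_configuration(tiny_cohort):
    res = grid_search(tiny_cohort, m_grid=(2,), r_grid=(0.2,))
    assert res.best == EntropyParams("sample", 2, 0.2)
    assert len(res.table) == 1


def test_grid_search_shape_and_argmax(tiny_cohort):
    res = grid_search(tiny_cohort)  # 3 m-values x 16 r-values
    assert len(res.table) == 48
    # best beats every corner configuration under independent re-evaluation
    for m in (1, 3):
        for r in (0.15, 0.30):
            corner = cohort_auc(tiny_cohort, EntropyParams("sample", m, r))
            assert res.best_auc >= corner - 1e-12
    assert res.best_auc == pytest.approx(res.table["auc"].max())


def test_grid_search_skips_undefined_configurations(tiny_cohort, monkeypatch):
    original = EntropyEngine.score

    def flaky(self, params):
        if params.m == 3:
            raise UndefinedEntropyError("no matches")
        return original(self, params)

    monkeypatch.setattr(EntropyEngine, "score", flaky)
    res = grid_search(tiny_cohort)
    assert set(res.table["m"]) == {1, 2}
    assert len(res.table) == 32


def test_grid_search_requires_two_per_class(tiny_cohort):
    with pytest.raises(ValueError):
        grid_search(tiny_cohort[:4])  # 3 A1 + 1 B1


def test_optimize_fuzzy_n_curve(tiny_cohort):
    best_n, curve = optimize_fuzzy_n(tiny_cohort, m=2, r=0.2, n_grid=(0.25, 0.625, 2.0))
    assert len(curve) == 3
    assert best_n in (0.25, 0.625, 2.0)
    assert curve.loc[curve["n"] == best_n, "auc"].iloc[0] == curve["auc"].max()
    single, _ = optimize_fuzzy_n(tiny_cohort, m=2, r=0.2, n_grid=(0.625,))
    assert single == 0.625


def test_default_n_grid_contains_reference_points():
    assert len(DEFAULT_N_GRID) == 23
    assert 0.625 in DEFAULT_N_GRID and 2.0 in DEFAULT_N_GRID
    assert len(DEFAULT_R_GRID) == 16


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


def test_length_sweep_deterministic(small_cohort):
    res = length_sweep(
        small_cohort, PARAMS, day_grid=(1,), sample_lengths=(72, 144)
    )
    assert res.conditions == [72, 144, 288]
    assert np.all(res.auc_sd == 0.0)
    res2 = length_sweep(small_cohort, PARAMS, day_grid=(1,), sample_lengths=(72, 144))
    assert np.array_equal(res.auc_mean, res2.auc_mean)
    # full-length condition equals the plain cohort AUC
    assert res.auc_mean[-1] == pytest.approx(cohort_auc(small_cohort, PARAMS))


def test_length_sweep_fixed_cohort_flag(small_cohort):
    with pytest.raises(ValueError, match="shorter"):
        length_sweep(small_cohort, PARAMS, day_grid=(2,))
    res = length_sweep(small_cohort, PARAMS, day_grid=(1, 2), fixed_cohort=False)
    assert res.conditions == [288]  # the 2-day condition drops every record


def test_missing_sweep_reproducible_and_single_rep_sd(small_cohort):
    res = missing_sweep(small_cohort, PARAMS, fractions=(0.05,), reps=1, seed=9)
    assert res.auc_sd[0] == 0.0
    res2 = missing_sweep(small_cohort, PARAMS, fractions=(0.05,), reps=1, seed=9)
    assert np.array_equal(res.auc_mean, res2.auc_mean)


def test_interpolation_recovers_entropy_better_than_zero_spikes(small_cohort):
    """Per-record SampEn distortion: zero spikes >> interpolated gaps."""
    from cgmentropy import ArtifactSpec, inject_missing, interpolate_missing

    spec = ArtifactSpec(kind="missing", fraction=0.1)
    raw_err, rec_err = [], []
    for i, rec in enumerate(small_cohort):
        base = EntropyEngine(rec.values).score(PARAMS)
        spiked = inject_missing(rec, spec, np.random.default_rng(i))
        raw_err.append(abs(EntropyEngine(spiked.values).score(PARAMS) - base))
        filled = interpolate_missing(spiked)
        rec_err.append(abs(EntropyEngine(filled.values).score(PARAMS) - base))
    assert np.mean(rec_err) < np.mean(raw_err)


def test_missing_sweep_rejects_gappy_records(small_cohort):
    gappy = [r.replace() for r in small_cohort]
    gappy[0].missing_mask[10] = True
    with pytest.raises(ValueError, match="pre-interpolated"):
        missing_sweep(gappy, PARAMS, fractions=(0.05,), reps=1)


def test_saturation_sweep_shape(small_cohort):
    res = saturation_sweep(small_cohort, PARAMS, pulse_lengths=(6, 60), reps=2, seed=4)
    assert res.conditions == [6, 60]
    assert res.auc_mean.shape == (2,) and np.all(res.auc_sd >= 0.0)


def test_offset_sweep_deterministic(small_cohort):
    spec = CohortSpec(n_a1=4, n_b1=4, days=4, seed=21)
    cohort = generate_cohort(spec)
    df = offset_sweep(cohort, PARAMS, shifts=(0, 1), window_days=3)
    df2 = offset_sweep(cohort, PARAMS, shifts=(0, 1), window_days=3)
    assert df.equals(df2)
    assert list(df["shift_days"]) == [0, 1]
    assert np.all((df["p_value"] > 0) & (df["p_value"] <= 1))


# ---------------------------------------------------------------------------
# Leave-one-out
# ---------------------------------------------------------------------------


def test_loo_perfect_separation_gives_full_accuracy():
    s = ScoreSet([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
    res = loo_validation(s, n_iter=10, seed=0)
    assert np.all(res.rows["accuracy_pct"] == 100.0)
    assert res.mean_accuracy_pct == 100.0


def test_loo_fixed_pairs_replay_is_deterministic(fixture_scores, fixture_tables):
    pairs = fixture_tables.loo_pairs()
    a = loo_validation(fixture_scores, fixed_pairs=pairs)
    b = loo_validation(fixture_scores, fixed_pairs=pairs)
    assert a.rows.equals(b.rows)
    assert len(a.rows) == 25
    # cached per-record scores: held-out scores equal the published entries
    assert np.allclose(a.rows["score_a1"], fixture_tables.loo_table["sampen_a1"])
    assert np.allclose(a.rows["score_b1"], fixture_tables.loo_table["sampen_b1"])


def test_loo_random_mode_samples_with_replacement(fixture_scores):
    res = loo_validation(fixture_scores, n_iter=50, seed=123)
    assert len(res.rows) == 50
    # with replacement, 50 draws from 14x9 pairs almost surely repeat
    assert res.rows.duplicated(["a1_id", "b1_id"]).any()
    assert set(res.rows["accuracy_pct"]) <= {0.0, 100.0}


def test_loo_requires_two_per_class():
    with pytest.raises(ValueError):
        loo_validation(ScoreSet([1.0], [2.0, 3.0]))


# ---------------------------------------------------------------------------
# Entropy-versus-length stability
# ---------------------------------------------------------------------------


def test_length_profile_full_length_matches_whole_record(small_cohort):
    rec = small_cohort[0]
    df = entropy_length_profile([rec], PARAMS, length_grid=(100, rec.n))
    assert len(df) == 2
    full = df.loc[df["length"] == rec.n, "entropy"].iloc[0]
    assert full == pytest.approx(EntropyEngine(rec.values).score(PARAMS))


def test_sampen_dispersion_shrinks_with_length():
    """Across-record SD of SampEn at 200 samples exceeds the SD at 1500.

    Records share one irregularity level (no per-record jitter), so the
    across-record spread isolates estimator variance at each length.
    """
    spec = CohortSpec(
        n_a1=3,
        n_b1=3,
        days=6,
        irregularity_a1=0.5,
        irregularity_b1=0.5,
        irregularity_jitter=0.0,
        seed=17,
    )
    records = generate_cohort(spec)
    df = entropy_length_profile(records, PARAMS, length_grid=(200, 1500))
    sd = df.groupby("length")["entropy"].std()
    assert sd[200] > sd[1500]
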