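"""Synthetic two-class CGM cohort generator.

Emulates the statistical structure the classification analysis assumes:
5-minute sampling (288 samples/day), multi-day duration, a physiological
glucose range clamped to the device scale [2.2, 22.2] mmol/L, circadian
and meal structure, optional isolated missing samples, and a between-class
contrast in irregularity such that class A1 scores higher entropy than
class B1.

Each record is

    g(t) = baseline + circadian sinusoid (24 h period)
         + three daily meal excursions (Gaussian bumps, timing jittered
           +-1 h, amplitude jittered +-20%)
         + s(t)

where the stochastic term is a MIX-style blend

    s(t) = (1 - p) * AR(1)(phi, sigma) + p * white noise(sigma)

of a correlated AR(1) process (stationary SD sigma) and white noise of
matched variance.  The mixing weight p in [0, 1] is the per-class
irregularity control: entropy estimators read higher values as p grows,
so ``irregularity_a1 > irregularity_b1`` orients the classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .artifacts import ArtifactSpec, inject_missing
from .records import SATURATION_HIGH, SATURATION_LOW, GlucoseRecord

#: Daily meal times in hours (breakfast, lunch, dinner) and bump width (h).
MEAL_HOURS = (7.5, 12.5, 18.5)
MEAL_WIDTH_H = 0.75


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of one synthetic cohort.

    Defaults mirror the target study's layout: 14 A1 + 9 B1 six-day
    records.  The irregularity contrast (0.55 vs 0.35) and the per-record
    irregularity jitter (SD 0.10, emulating inter-patient heterogeneity)
    were fixed once by a calibration run so that the cohort's SampEn AUC
    is high but imperfect (~0.9), as in real data; see the package
    methods note.
    """

    n_a1: int = 14
    n_b1: int = 9
    days: int = 6
    irregularity_a1: float = 0.55
    irregularity_b1: float = 0.35
    irregularity_jitter: float = 0.10
    meal_amplitude: float = 3.0
    ar_coefficient: float = 0.9
    noise_sd: float = 0.5
    baseline: float = 7.5
    circadian_amplitude: float = 1.0
    missing_fraction: float = 0.0
    sampling_period_s: int = 300
    randomize_meals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a1 < 1 or self.n_b1 < 1:
            raise ValueError("each class needs at least one record")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        for name in ("irregularity_a1", "irregularity_b1"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.irregularity_jitter < 0:
            raise ValueError("irregularity_jitter must be nonnegative")
        if not 0.0 <= self.missing_fraction <= 0.2:
            raise ValueError("missing_fraction must lie in [0, 0.2]")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _mix_noise(spec: CohortSpec, p: float, n: int, rng: np.random.Generator) -> np.ndarray:
    sigma = spec.noise_sd
    if sigma == 0.0:
        return np.zeros(n)
    phi = spec.ar_coefficient
    eps = rng.normal(0.0, sigma * np.sqrt(1.0 - phi**2), size=n)
    ar = np.empty(n)
    # stationary start so variance is sigma^2 from the first sample
    ar[0] = rng.normal(0.0, sigma)
    for k in range(1, n):
        ar[k] = phi * ar[k - 1] + eps[k]
    white = rng.normal(0.0, sigma, size=n)
    return (1.0 - p) * ar + p * white


def generate_record(
    spec: CohortSpec, class_label: str, rng: np.random.Generator, record_id: str = ""
) -> GlucoseRecord:
    """One synthetic CGM record of ``spec.days`` days for the given class."""
    if class_label not in ("A1", "B1"):
        raise ValueError("class_label must be 'A1' or 'B1'")
    spd = 86400 // spec.sampling_period_s
    n = spec.days * spd
    t_h = np.arange(n) * spec.sampling_period_s / 3600.0
    values = spec.baseline + spec.circadian_amplitude * np.sin(
        2.0 * np.pi * (t_h - 14.0) / 24.0
    )
    for day in range(spec.days):
        for meal_h in MEAL_HOURS:
            if spec.randomize_meals:
                center = day * 24.0 + meal_h + rng.uniform(-1.0, 1.0)
                amp = spec.meal_amplitude * (1.0 + rng.uniform(-0.2, 0.2))
            else:
                center = day * 24.0 + meal_h
                amp = spec.meal_amplitude
            values += amp * np.exp(-0.5 * ((t_h - center) / MEAL_WIDTH_H) ** 2)
    p = spec.irregularity_a1 if class_label == "A1" else spec.irregularity_b1
    if spec.irregularity_jitter > 0.0:
        p = float(np.clip(rng.normal(p, spec.irregularity_jitter), 0.0, 1.0))
    values += _mix_noise(spec, p, n, rng)
    np.clip(values, SATURATION_LOW, SATURATION_HIGH, out=values)
    rec = GlucoseRecord(
        values=values,
        sampling_period_s=spec.sampling_period_s,
        label=class_label,
        record_id=record_id or class_label,
    )
    if spec.missing_fraction > 0.0:
        rec = inject_missing(
            rec, ArtifactSpec(kind="missing", fraction=spec.missing_fraction), rng
        )
    return rec


def generate_cohort(spec: CohortSpec) -> list[GlucoseRecord]:
    """Labeled cohort of ``n_a1`` + ``n_b1`` independent records.

    Reproducible from ``spec.seed``; record ids follow the pattern
    ``A1-01 ... B1-09``.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for label, count in (("A1", spec.n_a1), ("B1", spec.n_b1)):
        for i in range(count):
            records.append(
                generate_record(spec, label, rng, record_id=f"{label}-{i + 1:02d}")
            )
    return records
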