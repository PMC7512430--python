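"""Artifact injection and record transformations for robustness experiments.

Four disturbances/transformations are modelled, each mirroring a failure
mode of ambulatory CGM acquisition:

* isolated missing samples ("spikes down to zero") at a controlled rate;
* a single sensor-saturation pulse at the device scale limit (22.2 mmol/L);
* center truncation to a target length (border effects avoided);
* day-aligned window extraction (time-offset analysis).

Plus the linear-interpolation pre-filter used to remove gaps before any
entropy computation.  The experiment composition order is fixed:
interpolate real gaps -> truncate/window -> inject synthetic artifact ->
entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import SATURATION_HIGH, GlucoseRecord


class InjectionInfeasibleError(ValueError):
    """Requested missing fraction cannot be placed without adjacency."""


@dataclass(frozen=True)
class ArtifactSpec:
    """Parameters of one synthetic disturbance.

    ``kind='missing'`` uses ``fraction``; ``kind='saturation'`` uses
    ``pulse_length`` (samples) and ``amplitude`` (mmol/L, default the
    device ceiling 22.2).
    """

    kind: str
    fraction: float | None = None
    pulse_length: int | None = None
    amplitude: float = SATURATION_HIGH

    def __post_init__(self) -> None:
        if self.kind == "missing":
            if self.fraction is None or not (0 < self.fraction <= 0.2):
                raise ValueError("missing artifact requires fraction in (0, 0.2]")
            if self.pulse_length is not None:
                raise ValueError("pulse_length is not a missing-artifact field")
        elif self.kind == "saturation":
            if self.pulse_length is None or self.pulse_length < 1:
                raise ValueError("saturation artifact requires a positive pulse_length")
            if self.fraction is not None:
                raise ValueError("fraction is not a saturation-artifact field")
        else:
            raise ValueError("kind must be 'missing' or 'saturation'")


def _sample_nonadjacent(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of k pairwise non-adjacent positions from range(n).

    Classic bijection: non-adjacent k-subsets of {0..n-1} correspond to
    arbitrary k-subsets of {0..n-k}; draw the latter, sort, and add the
    offset i to the i-th smallest element.  Uniform over all valid sets.
    """
    if k == 0:
        return np.empty(0, dtype=int)
    if k > (n + 1) // 2:
        raise InjectionInfeasibleError(
            f"cannot place {k} non-adjacent missing samples in {n} positions"
        )
    base = rng.choice(n - k + 1, size=k, replace=False)
    base.sort()
    return base + np.arange(k)


def inject_missing(
    rec: GlucoseRecord, spec: ArtifactSpec, rng: np.random.Generator
) -> GlucoseRecord:
    """Zero out ``round(fraction * N)`` isolated samples and mask them.

    The record must be gap-free on entry (pre-filtered).  Injected
    positions are pairwise non-adjacent — the single-missing-sample regime
    — and are set to 0 with ``missing_mask`` True, emulating sensor
    dropouts recorded as zero spikes.
    """
    if spec.kind != "missing":
        raise ValueError("spec.kind must be 'missing'")
    if rec.missing_mask.any():
        raise ValueError("record has pre-existing gaps; interpolate before injection")
    n = rec.n
    k = int(np.floor(spec.fraction * n + 0.5))  # ties round up
    out = rec.replace()
    if k == 0:
        return out
    pos = _sample_nonadjacent(n, k, rng)
    out.values[pos] = 0.0
    out.missing_mask[pos] = True
    return out


def inject_saturation(
    rec: GlucoseRecord, spec: ArtifactSpec, rng: np.random.Generator
) -> GlucoseRecord:
    """Overwrite one contiguous run of samples with the saturation amplitude.

    The pulse start is uniform over all placements that keep the pulse
    fully inside the record; exactly one pulse per record.
    """
    if spec.kind != "saturation":
        raise ValueError("spec.kind must be 'saturation'")
    length = int(spec.pulse_length)
    if length > rec.n:
        raise ValueError(f"pulse_length {length} exceeds record length {rec.n}")
    start = int(rng.integers(0, rec.n - length + 1))
    out = rec.replace()
    out.values[start : start + length] = spec.amplitude
    out.missing_mask[start : start + length] = False
    return out


def truncate_center(rec: GlucoseRecord, target_len: int) -> GlucoseRecord:
    """Contiguous center slice of ``target_len`` samples (border effects avoided)."""
    if not (1 <= target_len <= rec.n):
        raise ValueError(f"target_len must be in [1, {rec.n}], got {target_len}")
    start = (rec.n - target_len) // 2
    return rec.slice(start, start + target_len)


def extract_window(
    rec: GlucoseRecord, shift_days: int, window_days: int
) -> GlucoseRecord:
    """Day-aligned window: samples ``[shift*spd, (shift+window)*spd)``."""
    if shift_days < 0 or window_days < 1:
        raise ValueError("shift_days must be >= 0 and window_days >= 1")
    spd = rec.samples_per_day
    start = shift_days * spd
    stop = (shift_days + window_days) * spd
    if stop > rec.n:
        raise ValueError(
            f"window [{start}, {stop}) exceeds record length {rec.n}"
        )
    return rec.slice(start, stop)


def interpolate_missing(rec: GlucoseRecord) -> GlucoseRecord:
    """Fill every gap by linear interpolation between observed neighbours.

    Leading/trailing gaps, where interpolation is undefined, are filled by
    extending the nearest observed value.  The returned record has an
    all-False mask; observed samples are untouched.
    """
    if not rec.missing_mask.any():
        return rec.replace()
    observed = ~rec.missing_mask
    if not observed.any():
        raise ValueError("cannot interpolate a record with no observed samples")
    idx = np.arange(rec.n)
    filled = np.interp(idx, idx[observed], rec.values[observed])
    out = rec.replace()
    out.values = filled
    out.missing_mask = np.zeros(rec.n, dtype=bool)
    return out
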