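"""Container for a single continuous glucose monitoring (CGM) record.

A record is an evenly sampled glucose trace (mmol/L) with a per-sample
missing-data mask.  The default sampling period of 5 minutes gives
288 samples per day.  Class labels follow the two-arm study design the
package targets: ``A1`` (early post-implantation, expected-higher entropy)
and ``B1`` (late post-implantation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Glucose values a CGM sensor can plausibly report, in mmol/L.
GLUCOSE_RANGE = (0.0, 30.0)

#: Device scale limits at which readings saturate, in mmol/L.
SATURATION_LOW = 2.2
SATURATION_HIGH = 22.2

VALID_LABELS = ("A1", "B1", "unlabeled")


@dataclass
class GlucoseRecord:
    """One CGM time series with its missing-sample mask.

    Parameters
    ----------
    values : array-like of float
        Glucose samples in mmol/L.  Positions flagged in ``missing_mask``
        carry a placeholder (conventionally 0.0) and are ignored by any
        consumer that respects the mask.
    missing_mask : array-like of bool, optional
        True where the sample is missing.  Defaults to all-False.
    sampling_period_s : int
        Sampling period in seconds (default 300, i.e. 5 minutes).
    label : str
        Class label, one of ``A1``, ``B1`` or ``unlabeled``.
    record_id : str
        Opaque identifier used in manifests and result tables.
    """

    values: np.ndarray
    missing_mask: np.ndarray | None = None
    sampling_period_s: int = 300
    label: str = "unlabeled"
    record_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("record values must be one-dimensional")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.size, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("values and missing_mask must have equal length")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-missing samples must be finite")
        if observed.size and (observed.min() <= GLUCOSE_RANGE[0] or observed.max() > GLUCOSE_RANGE[1]):
            raise ValueError(
                "non-missing glucose values must lie in "
                f"({GLUCOSE_RANGE[0]}, {GLUCOSE_RANGE[1]}] mmol/L"
            )
        if self.sampling_period_s <= 0:
            raise ValueError("sampling_period_s must be positive")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n

    @property
    def samples_per_day(self) -> int:
        return 86400 // self.sampling_period_s

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def replace(self, **changes) -> "GlucoseRecord":
        """Return a copy with the given fields replaced (arrays are copied)."""
        out = replace(self, **changes)
        out.values = out.values.copy()
        out.missing_mask = out.missing_mask.copy()
        return out

    def slice(self, start: int, stop: int) -> "GlucoseRecord":
        """Return the contiguous sub-record ``[start, stop)``."""
        if not (0 <= start <= stop <= self.n):
            raise ValueError(f"invalid slice [{start}, {stop}) for record of length {self.n}")
        return GlucoseRecord(
            values=self.values[start:stop].copy(),
            missing_mask=self.missing_mask[start:stop].copy(),
            sampling_period_s=self.sampling_period_s,
            label=self.label,
            record_id=self.record_id,
        )
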