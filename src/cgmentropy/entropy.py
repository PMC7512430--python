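"""Sample entropy and fuzzy entropy estimators.

Both statistics quantify the irregularity of a time series ``x`` of length
``N`` by comparing subsequences (templates) of length ``m`` against all
other templates of the series:

* **SampEn(m, r)** counts template pairs whose Chebyshev distance is within
  a hard tolerance ``r·SD(x)`` at lengths ``m`` and ``m+1`` (self-matches
  excluded) and returns ``-ln(A/B)``, the negative log conditional
  probability that templates matching for ``m`` points keep matching for
  ``m+1``.
* **FuzzyEn(m, r, n)** replaces the hard threshold by the continuous
  membership ``exp(-(d / (r·SD))^n)`` and subtracts each window's own mean
  before distances are taken; it returns ``ln(phi_m) - ln(phi_{m+1})``.
* **FuzzyEn\\*** is FuzzyEn with the per-window mean subtraction skipped,
  isolating the effect of the fuzzy dissimilarity alone.

Conventions (the Richman–Moorman ones, standard in the field): ``N - m``
templates are used at both lengths; the tolerance is relative to the
standard deviation (ddof=0) of the exact series passed in; logarithms are
natural.  Per-template normalisation constants cancel in the ratios, so
only the undefined-SampEn contract depends on raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

VARIANTS = ("sample", "fuzzy", "fuzzy_star")

#: Conventional grid bounds; values outside are allowed but flagged.
RECOMMENDED_M = (1, 3)
RECOMMENDED_R = (0.15, 0.30)


class EntropyError(ValueError):
    """Base class for entropy computation errors."""


class InputTooShortError(EntropyError):
    """Series shorter than the minimum ``m + 2`` samples."""


class ConstantInputError(EntropyError):
    """Zero-variance series under the SD-relative tolerance convention."""


class UndefinedEntropyError(EntropyError):
    """SampEn undefined: no template matches at length m or m+1."""


class ParameterRangeWarning(UserWarning):
    """Parameters outside the conventional (m, r) grid."""


@dataclass(frozen=True)
class EntropyParams:
    """Configuration of one entropy computation.

    Parameters
    ----------
    variant : {"sample", "fuzzy", "fuzzy_star"}
    m : int
        Embedding dimension (template length), ``m >= 1``.
    r : float
        Tolerance as a fraction of the standard deviation of the input
        series.
    n : float, optional
        Fuzzy exponent; required for the fuzzy variants, ignored for
        ``sample``.  ``n = 2`` makes the membership function Gaussian.
    """

    variant: str
    m: int
    r: float
    n: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError("m must be a positive integer")
        if not self.r > 0:
            raise ValueError("r must be positive")
        if self.variant == "sample":
            if self.n is not None:
                raise ValueError("n is only meaningful for fuzzy variants")
        else:
            if self.n is None or not self.n > 0:
                raise ValueError("fuzzy variants require a positive exponent n")
        if not (RECOMMENDED_M[0] <= self.m <= RECOMMENDED_M[1]) or not (
            RECOMMENDED_R[0] <= self.r <= RECOMMENDED_R[1]
        ):
            warnings.warn(
                f"(m={self.m}, r={self.r}) lies outside the conventional grid "
                f"m in {RECOMMENDED_M}, r in {RECOMMENDED_R}",
                ParameterRangeWarning,
                stacklevel=2,
            )

    @property
    def is_fuzzy(self) -> bool:
        return self.variant in ("fuzzy", "fuzzy_star")

    def tag(self) -> str:
        if self.variant == "sample":
            return f"SampEn(m={self.m}, r={self.r})"
        name = "FuzzyEn*" if self.variant == "fuzzy_star" else "FuzzyEn"
        return f"{name}(m={self.m}, r={self.r}, n={self.n})"


@dataclass(frozen=True)
class MatchCounts:
    """Average template-match densities at lengths m and m+1.

    For SampEn these are hard-threshold match densities (``a_m <= b_m``
    since matching is harder for longer templates); for the fuzzy variants
    they are the averaged memberships ``phi_m`` and ``phi_m1``.
    """

    b_m: float
    a_m: float

    @property
    def phi_m(self) -> float:
        return self.b_m

    @property
    def phi_m1(self) -> float:
        return self.a_m


def chebyshev_distance(u, v) -> float:
    """Maximum absolute coordinate difference between two equal-length windows."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 1:
        raise ValueError("windows must be one-dimensional and of equal positive length")
    return float(np.max(np.abs(u - v)))


class EntropyEngine:
    """Caches pairwise template distances of one series across configurations.

    Grid searches evaluate many (variant, m, r, n) configurations on the
    same record; the expensive part — the pairwise Chebyshev distance
    matrix per template length — depends only on (length, centered), so it
    is computed once and reused.
    """

    def __init__(self, x) -> None:
        x = np.asarray(x, dtype=float).ravel()
        if not np.all(np.isfinite(x)):
            raise ValueError(
                "series contains non-finite samples; resolve missing data first"
            )
        self.x = x
        self.n = x.size
        self.sd = float(x.std())  # ddof=0, the SampEn convention
        self._dist: dict[tuple[int, bool], np.ndarray] = {}

    def _maxdist(self, length: int, centered: bool) -> np.ndarray:
        """Pairwise Chebyshev distances between all windows of ``length``."""
        key = (length, centered)
        if key not in self._dist:
            windows = sliding_window_view(self.x, length)
            if centered:
                windows = windows - windows.mean(axis=1, keepdims=True)
            d = np.abs(windows[:, 0][:, None] - windows[:, 0][None, :])
            for k in range(1, length):
                np.maximum(d, np.abs(windows[:, k][:, None] - windows[:, k][None, :]), out=d)
            self._dist[key] = d
        return self._dist[key]

    def _check(self, params: EntropyParams) -> float:
        if self.n < params.m + 2:
            raise InputTooShortError(
                f"need at least m+2 = {params.m + 2} samples, got {self.n}"
            )
        if self.sd == 0.0:
            raise ConstantInputError(
                "constant series: SD-relative tolerance is undefined"
            )
        return params.r * self.sd

    def match_counts(self, params: EntropyParams) -> MatchCounts:
        """Match densities (SampEn) or averaged memberships (FuzzyEn)."""
        tol = self._check(params)
        m = params.m
        n_t = self.n - m  # templates at both lengths
        centered = params.variant == "fuzzy"
        out = []
        for length in (m, m + 1):
            d = self._maxdist(length, centered)[:n_t, :n_t]
            if params.variant == "sample":
                total = int((d <= tol).sum()) - n_t  # drop diagonal self-matches
            else:
                memb = np.exp(-((d / tol) ** params.n))
                total = float(memb.sum()) - float(np.trace(memb))
            out.append(total / (n_t * (n_t - 1)))
        return MatchCounts(b_m=out[0], a_m=out[1])

    def score(self, params: EntropyParams) -> float:
        """Entropy of the series under ``params``."""
        counts = self.match_counts(params)
        if params.variant == "sample":
            if counts.a_m == 0 or counts.b_m == 0:
                raise UndefinedEntropyError(
                    f"SampEn undefined: no matches at length "
                    f"{'m+1' if counts.b_m else 'm'} for {params.tag()}"
                )
            return float(-np.log(counts.a_m / counts.b_m))
        return float(np.log(counts.phi_m) - np.log(counts.phi_m1))


def sample_entropy(x, params: EntropyParams) -> float:
    """SampEn of ``x``; raises :class:`UndefinedEntropyError` when no pairs match."""
    if params.variant != "sample":
        raise ValueError("sample_entropy requires variant='sample'")
    return EntropyEngine(x).score(params)


def fuzzy_entropy(x, params: EntropyParams) -> float:
    """FuzzyEn (or FuzzyEn*) of ``x``; always finite for finite input."""
    if not params.is_fuzzy:
        raise ValueError("fuzzy_entropy requires a fuzzy variant")
    return EntropyEngine(x).score(params)


def entropy_score(x, params: EntropyParams) -> float:
    """Dispatch to the estimator selected by ``params.variant``."""
    return EntropyEngine(x).score(params)
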