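"""Two-class separability statistics: ROC/AUC, thresholds, Mann-Whitney.

The positive class (``A1``) is expected to score higher.  The empirical
AUC is the normalised Mann-Whitney U statistic

    AUC = (#{a > b} + 0.5 * #{a = b}) / (n_A * n_B)

over all cross-class score pairs; the parametric counterpart assumes
Gaussian score distributions per class (binormal model),
``AUC = Phi(dmu / sqrt(sd_a^2 + sd_b^2))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats


@dataclass
class ScoreSet:
    """Per-record entropy scores paired with class labels.

    ``scores_a1`` is the positive (expected-higher) class.  Optional
    record identifiers default to 1-based integers, matching the row
    numbering of published per-record score tables.
    """

    scores_a1: np.ndarray
    scores_b1: np.ndarray
    metric_tag: str = ""
    ids_a1: Sequence = field(default=None)
    ids_b1: Sequence = field(default=None)

    def __post_init__(self) -> None:
        self.scores_a1 = np.asarray(self.scores_a1, dtype=float)
        self.scores_b1 = np.asarray(self.scores_b1, dtype=float)
        if self.scores_a1.size == 0 or self.scores_b1.size == 0:
            raise ValueError("both classes must be non-empty")
        if not (np.all(np.isfinite(self.scores_a1)) and np.all(np.isfinite(self.scores_b1))):
            raise ValueError("scores must be finite")
        if self.ids_a1 is None:
            self.ids_a1 = list(range(1, self.scores_a1.size + 1))
        if self.ids_b1 is None:
            self.ids_b1 = list(range(1, self.scores_b1.size + 1))
        if len(self.ids_a1) != self.scores_a1.size or len(self.ids_b1) != self.scores_b1.size:
            raise ValueError("ids must match score lengths")

    @property
    def n_a(self) -> int:
        return self.scores_a1.size

    @property
    def n_b(self) -> int:
        return self.scores_b1.size

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.scores_a1, self.scores_b1])

    def without(self, a1_id=None, b1_id=None) -> "ScoreSet":
        """Copy with at most one record per class removed (by id)."""
        keep_a = [i for i, rid in enumerate(self.ids_a1) if rid != a1_id]
        keep_b = [i for i, rid in enumerate(self.ids_b1) if rid != b1_id]
        return ScoreSet(
            scores_a1=self.scores_a1[keep_a],
            scores_b1=self.scores_b1[keep_b],
            metric_tag=self.metric_tag,
            ids_a1=[self.ids_a1[i] for i in keep_a],
            ids_b1=[self.ids_b1[i] for i in keep_b],
        )


@dataclass(frozen=True)
class ROCResult:
    """Classification summary of one score set at its optimal threshold."""

    auc_empirical: float
    auc_binormal: float
    se: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    p_value: float
    n_a: int
    n_b: int

    def auc_conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-approximation CI ``auc +- z * SE``, clipped to [0, 1]."""
        z = stats.norm.ppf(1 - alpha / 2)
        return (
            float(np.clip(self.auc_empirical - z * self.se, 0, 1)),
            float(np.clip(self.auc_empirical + z * self.se, 0, 1)),
        )


class MannWhitneyResult(NamedTuple):
    u: float
    z: float
    p_value: float


def empirical_auc(s: ScoreSet) -> float:
    """Normalised Mann-Whitney statistic over all cross-class pairs."""
    a = s.scores_a1[:, None]
    b = s.scores_b1[None, :]
    wins = (a > b).sum() + 0.5 * (a == b).sum()
    return float(wins / (s.n_a * s.n_b))


def binormal_auc(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """AUC under the binormal model, ``Phi(dmu / sqrt(sd_a^2 + sd_b^2))``."""
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    return float(stats.norm.cdf((mean_a - mean_b) / np.hypot(sd_a, sd_b)))


def _candidate_cuts(pooled: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct pooled scores, plus outer cuts."""
    u = np.unique(pooled)
    mids = (u[:-1] + u[1:]) / 2.0
    span = max(u[-1] - u[0], 1.0)
    return np.concatenate([[u[0] - 0.5 * span], mids, [u[-1] + 0.5 * span]])


def confusion_at_threshold(
    s: ScoreSet, threshold: float, rule: str = "gt"
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) for rule ``A1 iff score > t`` (or >=)."""
    if rule not in ("gt", "ge"):
        raise ValueError("rule must be 'gt' or 'ge'")
    if rule == "gt":
        pred_a = s.scores_a1 > threshold
        pred_b = s.scores_b1 > threshold
    else:
        pred_a = s.scores_a1 >= threshold
        pred_b = s.scores_b1 >= threshold
    sens = float(pred_a.mean())
    spec = float(1.0 - pred_b.mean())
    acc = (sens * s.n_a + spec * s.n_b) / (s.n_a + s.n_b)
    return sens, spec, float(acc)


def optimal_threshold(s: ScoreSet, convention: str = "midpoint") -> float:
    """Accuracy-maximising decision threshold for ``A1 iff score > t``.

    ``midpoint`` returns the midpoint of the two adjacent pooled scores
    straddling the best cut; ``data_value`` returns the smallest score
    classified as A1 (to be used with the ``>=`` rule).  Ties between
    equally accurate cuts are broken toward higher specificity, then
    toward the higher cut.
    """
    if convention not in ("midpoint", "data_value"):
        raise ValueError("convention must be 'midpoint' or 'data_value'")
    best = None
    for t in _candidate_cuts(s.pooled()):
        _, spec, acc = confusion_at_threshold(s, t, rule="gt")
        key = (acc, spec, t)
        if best is None or key > best:
            best = key
    cut = best[2]
    if convention == "midpoint":
        return float(cut)
    above = s.pooled()[s.pooled() > cut]
    return float(above.min()) if above.size else float(np.inf)


def mann_whitney_test(a, b, method: str = "asymptotic") -> MannWhitneyResult:
    """Two-sided Mann-Whitney rank-sum test.

    ``asymptotic`` (default) uses the tie-corrected normal approximation
    with continuity correction — the convention behind the reported
    p-values; ``exact`` enumerates the null distribution (small samples,
    no ties) via scipy.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if method == "exact":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return MannWhitneyResult(u=u, z=float("nan"), p_value=float(res.pvalue))
    if method != "asymptotic":
        raise ValueError("method must be 'asymptotic' or 'exact'")
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations tied
        return MannWhitneyResult(u=u, z=0.0, p_value=1.0)
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return MannWhitneyResult(u=u, z=float(z), p_value=p)


def auc_standard_error(auc: float, n_a: int, n_b: int) -> float:
    """Hanley-McNeil standard error of the empirical AUC."""
    if not (0 <= auc <= 1):
        raise ValueError("auc must lie in [0, 1]")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_a - 1) * (q1 - auc**2)
        + (n_b - 1) * (q2 - auc**2)
    ) / (n_a * n_b)
    return float(np.sqrt(max(var, 0.0)))


def roc_curve_points(s: ScoreSet) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve (FPR, TPR) via scikit-learn."""
    from sklearn.metrics import roc_curve

    labels = np.concatenate([np.ones(s.n_a), np.zeros(s.n_b)])
    fpr, tpr, _ = roc_curve(labels, s.pooled())
    return fpr, tpr


def export_roc_curve(s: ScoreSet, path) -> None:
    """Write the ROC curve as a two-column FPR/TPR plain-text table."""
    fpr, tpr = roc_curve_points(s)
    header = "fpr\ttpr"
    np.savetxt(path, np.column_stack([fpr, tpr]), fmt="%.6f", delimiter="\t", header=header)


def evaluate_scoreset(
    s: ScoreSet, convention: str = "midpoint", rule: str = "gt"
) -> ROCResult:
    """Full ROC summary of a score set at its optimal threshold."""
    auc = empirical_auc(s)
    thr = optimal_threshold(s, convention=convention)
    if convention == "data_value" and rule == "gt":
        rule = "ge"  # data-value thresholds classify their own score as A1
    sens, spec, acc = confusion_at_threshold(s, thr, rule=rule)
    mw = mann_whitney_test(s.scores_a1, s.scores_b1)
    return ROCResult(
        auc_empirical=auc,
        auc_binormal=binormal_auc(
            float(s.scores_a1.mean()),
            float(s.scores_a1.std(ddof=1)),
            float(s.scores_b1.mean()),
            float(s.scores_b1.std(ddof=1)),
        ),
        se=auc_standard_error(auc, s.n_a, s.n_b),
        threshold=thr,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        p_value=mw.p_value,
        n_a=s.n_a,
        n_b=s.n_b,
    )
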