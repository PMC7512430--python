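"""Model/Results facade for the entropy-based two-class classifier.

``EntropyClassifier`` is built from a labeled cohort of CGM records (or
directly from per-record scores); ``fit()`` grid-searches the entropy
parameters when a cohort is given, evaluates the ROC surface at the
selected configuration, and returns an :class:`EntropyClassifierResults`
carrying the estimates, their uncertainty and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .entropy import EntropyParams
from .experiments import (
    GridSearchResult,
    LOOResult,
    grid_search,
    loo_validation,
    score_records,
)
from .records import GlucoseRecord
from .roc import ROCResult, ScoreSet, evaluate_scoreset, export_roc_curve


class EntropyClassifier:
    """Two-class CGM classifier based on an entropy score and a threshold.

    Parameters
    ----------
    records : list of GlucoseRecord, optional
        Labeled cohort (labels ``A1``/``B1``).  Required unless ``scores``
        is given.
    scores : ScoreSet, optional
        Pre-computed per-record scores (skips the entropy stage).
    variant : {"sample", "fuzzy", "fuzzy_star"}
        Entropy family searched/used.
    params : EntropyParams, optional
        Fix the configuration instead of grid-searching.
    threshold_convention : {"midpoint", "data_value"}
    """

    def __init__(
        self,
        records: list[GlucoseRecord] | None = None,
        scores: ScoreSet | None = None,
        variant: str = "sample",
        params: EntropyParams | None = None,
        m_grid=(1, 2, 3),
        r_grid=None,
        n_grid=(0.625,),
        threshold_convention: str = "midpoint",
    ) -> None:
        if (records is None) == (scores is None):
            raise ValueError("provide exactly one of records or scores")
        self.records = records
        self.scores = scores
        self.variant = variant
        self.params = params
        self.m_grid = m_grid
        self.r_grid = r_grid
        self.n_grid = n_grid
        self.threshold_convention = threshold_convention

    @classmethod
    def from_scores(cls, scores: ScoreSet, **kwargs) -> "EntropyClassifier":
        return cls(scores=scores, **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, score_col: str = "sampen", **kwargs
    ) -> "EntropyClassifier":
        """Build from a tidy frame with columns ``record_id, label, <score>``."""
        a = df[df["label"] == "A1"]
        b = df[df["label"] == "B1"]
        scores = ScoreSet(
            scores_a1=a[score_col].to_numpy(),
            scores_b1=b[score_col].to_numpy(),
            ids_a1=a["record_id"].tolist(),
            ids_b1=b["record_id"].tolist(),
            metric_tag=score_col,
        )
        return cls(scores=scores, **kwargs)

    def fit(self) -> "EntropyClassifierResults":
        """Select the entropy configuration and evaluate the ROC surface."""
        grid: GridSearchResult | None = None
        if self.records is not None:
            if self.params is None:
                kwargs = {} if self.r_grid is None else {"r_grid": self.r_grid}
                grid = grid_search(
                    self.records,
                    variant=self.variant,
                    m_grid=self.m_grid,
                    n_grid=self.n_grid,
                    **kwargs,
                )
                params = grid.best
            else:
                params = self.params
            scores = score_records(self.records, params)
        else:
            params = self.params
            scores = self.scores
        roc = evaluate_scoreset(scores, convention=self.threshold_convention)
        return EntropyClassifierResults(self, params, scores, roc, grid)


class EntropyClassifierResults:
    """Fitted classifier: selected configuration, threshold and ROC summary."""

    def __init__(
        self,
        model: EntropyClassifier,
        params: EntropyParams | None,
        scores: ScoreSet,
        roc: ROCResult,
        grid: GridSearchResult | None = None,
    ) -> None:
        self.model = model
        self.params = params
        self.scores = scores
        self.roc = roc
        self.grid = grid

    # -- pass-through estimates ------------------------------------------
    @property
    def auc(self) -> float:
        return self.roc.auc_empirical

    @property
    def auc_binormal(self) -> float:
        return self.roc.auc_binormal

    @property
    def threshold(self) -> float:
        return self.roc.threshold

    @property
    def sensitivity(self) -> float:
        return self.roc.sensitivity

    @property
    def specificity(self) -> float:
        return self.roc.specificity

    @property
    def accuracy(self) -> float:
        return self.roc.accuracy

    @property
    def p_value(self) -> float:
        return self.roc.p_value

    def auc_conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        return self.roc.auc_conf_int(alpha)

    # -- downstream analyses ---------------------------------------------
    def loo(self, n_iter: int = 25, seed: int | None = None, fixed_pairs=None) -> LOOResult:
        """Leave-one-out validation on the fitted per-record scores."""
        return loo_validation(
            self.scores,
            n_iter=n_iter,
            seed=seed,
            convention=self.model.threshold_convention,
            fixed_pairs=fixed_pairs,
        )

    def predict(self, score) -> np.ndarray:
        """Class labels for new scores under the fitted threshold."""
        score = np.atleast_1d(np.asarray(score, dtype=float))
        return np.where(score > self.threshold, "A1", "B1")

    def export_roc(self, path) -> None:
        export_roc_curve(self.scores, path)

    def to_report(self) -> dict:
        """Flat key/value summary (serialisable)."""
        ci = self.auc_conf_int()
        return {
            "metric": self.params.tag() if self.params else self.scores.metric_tag,
            "n_a1": self.roc.n_a,
            "n_b1": self.roc.n_b,
            "auc_empirical": self.auc,
            "auc_binormal": self.auc_binormal,
            "auc_se_hanley_mcneil": self.roc.se,
            "auc_ci_low": ci[0],
            "auc_ci_high": ci[1],
            "threshold": self.threshold,
            "threshold_convention": self.model.threshold_convention,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mann_whitney_p": self.p_value,
        }

    def summary(self) -> str:
        """Human-readable summary table."""
        rep = self.to_report()
        lines = [
            "Entropy two-class classifier (A1 vs B1)",
            "=" * 46,
            f"Metric:            {rep['metric']}",
            f"Records:           {rep['n_a1']} A1 / {rep['n_b1']} B1",
            f"AUC (empirical):   {rep['auc_empirical']:.4f}  "
            f"[{rep['auc_ci_low']:.3f}, {rep['auc_ci_high']:.3f}]",
            f"AUC (binormal):    {rep['auc_binormal']:.4f}",
            f"AUC SE (H-M):      {rep['auc_se_hanley_mcneil']:.4f}",
            f"Threshold ({rep['threshold_convention']}): {rep['threshold']:.4f}",
            f"Sensitivity:       {rep['sensitivity']:.3f}",
            f"Specificity:       {rep['specificity']:.3f}",
            f"Accuracy:          {rep['accuracy']:.3f}",
            f"Mann-Whitney p:    {rep['mann_whitney_p']:.4g}",
        ]
        return "\n".join(lines)
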