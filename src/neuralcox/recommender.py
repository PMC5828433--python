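"""Personalized treatment recommendation from a fitted log-risk model.

Under a shared baseline hazard, the log hazard ratio between prescribing
treatment i versus j to the same patient is

    rec_ij(x) = h(x, tau=i) - h(x, tau=j),

computed by two forward passes with the treatment input overwritten
(the baseline hazard cancels).  A positive value means treatment i
carries the higher risk, so j is recommended; a negative value
recommends i.  Patients are then split into a Recommendation subset
(actual treatment equals the recommended one) and an
Anti-Recommendation subset, and the two subsets' survival is compared
by Kaplan-Meier curves, median survival and a log-rank test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .stats import (
    NOT_REACHED,
    KaplanMeierCurve,
    LogRankResult,
    kaplan_meier,
    logrank_test,
    median_survival,
)

__all__ = ["RecommendationReport", "recommender_function", "evaluate_recommendations",
           "recommend_multi"]


def _predict_with_treatment(model, X: np.ndarray, label: float,
                            treatment_col: int) -> np.ndarray:
    Xi = np.array(X, dtype=float)
    Xi[:, treatment_col] = label
    return model.predict_log_risk(Xi)


def recommender_function(model, X: np.ndarray, i: int, j: int,
                         treatment_col: int = -1) -> np.ndarray:
    """rec_ij(x): difference of predicted log-risks under treatments i and j.

    ``model`` is any object with ``predict_log_risk`` trained with the
    treatment label as an input column (``treatment_col``, default the
    last).  ``i == j`` returns zeros with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if i == j:
        warnings.warn("rec_ij with i == j is identically zero", stacklevel=2)
        return np.zeros(X.shape[0])
    h_i = _predict_with_treatment(model, X, float(i), treatment_col)
    h_j = _predict_with_treatment(model, X, float(j), treatment_col)
    return h_i - h_j


def recommend_multi(model, X: np.ndarray, labels, treatment_col: int = -1) -> np.ndarray:
    """Argmin of predicted log-risk over several treatment labels.

    Generalizes the two-treatment recommender: each record is assigned
    the label whose forward pass yields the lowest predicted log-risk.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = list(labels)
    risks = np.stack(
        [_predict_with_treatment(model, X, float(lab), treatment_col) for lab in labels]
    )
    return np.asarray(labels)[np.argmin(risks, axis=0)]


@dataclass
class RecommendationReport:
    """Per-record recommendations and the Rec / Anti-Rec survival contrast."""

    rec_values: np.ndarray
    recommended: np.ndarray
    concordant: np.ndarray
    km_rec: KaplanMeierCurve | None
    km_anti: KaplanMeierCurve | None
    median_rec: float | str | None
    median_anti: float | str | None
    logrank: LogRankResult | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rec_value": self.rec_values,
                "recommended": self.recommended,
                "concordant": self.concordant.astype(int),
            }
        )

    def summary(self) -> dict:
        """JSON-serializable summary (medians, subset sizes, log-rank)."""
        return {
            "n_rec": int(self.concordant.sum()),
            "n_anti": int((~self.concordant).sum()),
            "median_rec": self.median_rec,
            "median_anti": self.median_anti,
            "logrank_statistic": None if self.logrank is None else self.logrank.statistic,
            "logrank_p": None if self.logrank is None else self.logrank.p_value,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def evaluate_recommendations(
    model,
    ds: SurvivalDataset,
    i: int = 0,
    j: int = 1,
    alpha: float = 0.05,
    treatment_col: int = -1,
) -> RecommendationReport:
    """Recommend i or j per record and compare the concordant/discordant subsets.

    rec_ij > 0 recommends j (i carries the higher risk), rec_ij < 0
    recommends i, and an exact tie keeps the record's actual treatment
    (counted as concordant) so a constant model degenerates gracefully.
    The model's input is the dataset's covariates with the treatment
    label appended as the last column.
    """
    if ds.treatment is None:
        raise ValueError("dataset has no treatment column")
    X = ds.with_treatment_covariate().covariates
    rec = recommender_function(model, X, i, j, treatment_col=treatment_col)
    recommended = np.where(rec > 0, j, np.where(rec < 0, i, ds.treatment))
    concordant = recommended == ds.treatment

    km_rec = km_anti = None
    med_rec = med_anti = None
    lr = None
    sub_rec = ds.subset(concordant)
    sub_anti = ds.subset(~concordant)
    if sub_rec.n > 0:
        km_rec = kaplan_meier(sub_rec.time, sub_rec.event, alpha=alpha)
        med_rec = median_survival(km_rec)
    if sub_anti.n > 0:
        km_anti = kaplan_meier(sub_anti.time, sub_anti.event, alpha=alpha)
        med_anti = median_survival(km_anti)
    if sub_rec.n > 0 and sub_anti.n > 0:
        lr = logrank_test(sub_rec, sub_anti)
    else:
        warnings.warn("one recommendation subset is empty; log-rank skipped",
                      stacklevel=2)
    return RecommendationReport(
        rec_values=rec,
        recommended=recommended,
        concordant=concordant,
        km_rec=km_rec,
        km_anti=km_anti,
        median_rec=med_rec,
        median_anti=med_anti,
        logrank=lr,
    )
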