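"""Five-year ESKD risk from inferred eGFR slopes.

A subject's actual 5-year end-stage kidney disease (ESKD) label comes
from projecting their baseline eGFR forward with the slope estimated from
all their follow-up measurements (random-slope mixed model); projected
eGFR < 15 ml/min/1.73 m^2 means ESKD. A methylation-based risk score is
produced by inferring the eGFR slope with the multisite model under
cross-validation — the model is trained on 4/5 of subjects and scores the
left-out 1/5 — and applying the same projection. Scores are evaluated by
AUROC and AUPR over the pooled left-out predictions, overall and in the
baseline-eGFR >= 30 subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold

from .trajectories import (
    annual_pct_to_log_slope,
    fit_random_slope_model,
    project_cohort,
)

__all__ = ["RiskEvaluation", "score_metrics", "evaluate_eskd_prediction"]


@dataclass
class RiskEvaluation:
    """Risk scores, labels and ranking metrics for 5-year ESKD."""

    scores: pd.Series
    labels: pd.Series
    auroc: float
    aupr: float
    subgroup_mask: pd.Series | None = None
    subgroup_auroc: float = np.nan
    subgroup_aupr: float = np.nan
    extras: dict = field(default_factory=dict)


def score_metrics(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """AUROC and AUPR of a risk score; ties count half in the ROC area."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes present to compute AUROC/AUPR")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def eskd_labels_from_slopes(
    baselines: pd.Series, log_slopes: pd.Series, horizon_years: float = 5.0
) -> pd.Series:
    """ESKD labels by projecting baseline eGFR forward with given slopes."""
    proj = project_cohort(baselines, log_slopes, horizon_years)
    return proj["eskd_flag"].astype(int)


def evaluate_eskd_prediction(
    matrix_values: pd.DataFrame,
    baselines: pd.Series,
    longitudinal: pd.DataFrame,
    model_builder,
    covariates: pd.DataFrame | None = None,
    cv_folds: int = 5,
    horizon_years: float = 5.0,
    subgroup_min_baseline: float = 30.0,
    seed: int = 0,
) -> RiskEvaluation:
    """Cross-validated ESKD risk from methylation-inferred eGFR slopes.

    Parameters
    ----------
    model_builder
        Callable ``(train_values, train_trait, train_covariates) ->
        predict_fn`` where ``predict_fn(values, covariates)`` returns the
        inferred annual-percent eGFR slope for new samples. The multisite
        pipeline is the intended builder; anything with this signature
        works (e.g. clinical comparator equations).
    baselines
        Baseline eGFR per subject (sample IDs match the matrix rows).

    The trait the builder is trained on is the annual-percent slope
    estimated by the mixed model on the training subjects' longitudinal
    data; labels use the same estimates for all subjects ("actual"
    slopes). Subjects whose baseline eGFR is already below the ESKD
    threshold are labelled positive by the projection automatically
    (their projected eGFR stays below threshold for any plausible slope).

    Returns pooled AUROC/AUPR over left-out predictions and the same
    restricted to subjects with baseline eGFR >= ``subgroup_min_baseline``.
    """
    fit = fit_random_slope_model(longitudinal)
    slopes = fit.slopes()  # log_slope + annual_pct per subject
    subjects = matrix_values.index.intersection(slopes.index)
    if len(subjects) < cv_folds:
        raise ValueError("fewer subjects than folds")
    baselines = baselines.loc[subjects]
    actual_pct = slopes.loc[subjects, "annual_pct"]
    labels = eskd_labels_from_slopes(
        baselines, slopes.loc[subjects, "log_slope"], horizon_years
    )

    pred_pct = pd.Series(np.nan, index=subjects)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for tr, te in kf.split(np.arange(len(subjects))):
        tr_ids, te_ids = subjects[tr], subjects[te]
        predict_fn = model_builder(
            matrix_values.loc[tr_ids],
            actual_pct.loc[tr_ids],
            covariates.loc[tr_ids] if covariates is not None else None,
        )
        pred_pct.loc[te_ids] = np.asarray(
            predict_fn(
                matrix_values.loc[te_ids],
                covariates.loc[te_ids] if covariates is not None else None,
            ),
            dtype=float,
        )

    pred_pct = pred_pct.clip(lower=-99.9)  # projection domain
    pred_log = pd.Series(annual_pct_to_log_slope(pred_pct), index=subjects)
    proj = project_cohort(baselines, pred_log, horizon_years)
    scores = -proj["egfr_future"]  # lower projected eGFR = higher risk

    if labels.nunique() < 2:
        raise ValueError("pooled predictions contain a single class")
    auroc, aupr = score_metrics(labels.to_numpy(), scores.to_numpy())

    mask = baselines >= subgroup_min_baseline
    sub_auroc = sub_aupr = np.nan
    if mask.any() and labels[mask].nunique() == 2:
        sub_auroc, sub_aupr = score_metrics(
            labels[mask].to_numpy(), scores[mask].to_numpy()
        )
    return RiskEvaluation(
        scores=scores,
        labels=labels,
        auroc=auroc,
        aupr=aupr,
        subgroup_mask=mask,
        subgroup_auroc=sub_auroc,
        subgroup_aupr=sub_aupr,
        extras={"predicted_annual_pct": pred_pct, "actual_annual_pct": actual_pct},
    )
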