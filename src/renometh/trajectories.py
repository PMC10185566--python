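"""Per-subject eGFR decline from longitudinal data.

Kidney-function decline is modelled on the log scale with a linear mixed
model carrying a random intercept and a random slope per subject:

    log(eGFR_ij) = beta0 + beta1 * t_ij + b0i + b1i * t_ij + eps_ij

where ``t_ij`` is years from baseline. A subject's log-scale slope is
``c_i = beta1 + b1i`` and is reported clinically as the annual percent
change ``100 * (exp(c_i) - 1)``. Future eGFR is projected as
``eGFR(t) = eGFR(0) * exp(t * c_i)``; end-stage kidney disease (ESKD) at a
horizon is operationalised as projected eGFR < 15 ml/min/1.73 m^2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "RandomSlopeFit",
    "SlopeEstimate",
    "EgfrProjection",
    "validate_longitudinal",
    "fit_random_slope_model",
    "ols_subject_slopes",
    "slope_to_annual_pct",
    "annual_pct_to_log_slope",
    "project_future_egfr",
]

logger = logging.getLogger(__name__)

ESKD_EGFR_THRESHOLD = 15.0  # ml/min/1.73 m^2


@dataclass
class RandomSlopeFit:
    """Fitted random-slope model for log eGFR.

    ``beta0``/``beta1`` are the fixed intercept and yearly log-slope;
    ``subject_effects`` holds per-subject BLUPs (columns ``b0`` and ``b1``);
    ``cov_re`` is the estimated 2x2 random-effects covariance and
    ``resid_sd`` the residual SD of ``eps_ij``.
    """

    beta0: float
    beta1: float
    subject_effects: pd.DataFrame
    cov_re: np.ndarray
    resid_sd: float
    converged: bool
    method: str = "reml"

    def slopes(self) -> pd.DataFrame:
        """Per-subject log-slope ``c_i = beta1 + b1i`` and annual percent change."""
        c = self.beta1 + self.subject_effects["b1"]
        return pd.DataFrame(
            {"log_slope": c, "annual_pct": slope_to_annual_pct(c.to_numpy())},
            index=self.subject_effects.index,
        )


@dataclass
class SlopeEstimate:
    subject_id: str
    log_slope: float
    annual_pct: float


@dataclass
class EgfrProjection:
    subject_id: str
    egfr_baseline: float
    egfr_future: float
    eskd_flag: bool
    horizon_years: float = 5.0


def validate_longitudinal(series: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format (subject_id, time_years, egfr) table.

    Requires positive eGFR, finite times, a baseline (t=0) record and at
    least two visits per subject retained for fitting. Subjects with a
    single visit are dropped with a logged count rather than an error, as
    their slope is unidentifiable.
    """
    required = {"subject_id", "time_years", "egfr"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"longitudinal table missing columns: {sorted(missing)}")
    if (series["egfr"] <= 0).any():
        raise ValueError("eGFR values must be positive (log scale model)")
    if not np.isfinite(series["time_years"]).all():
        raise ValueError("non-finite measurement times")
    counts = series.groupby("subject_id")["time_years"].count()
    singletons = counts.index[counts < 2]
    if len(singletons) > 0:
        logger.info("dropping %d single-visit subjects", len(singletons))
        series = series[~series["subject_id"].isin(singletons)]
    has_baseline = series.groupby("subject_id")["time_years"].min()
    if (has_baseline > 1e-9).any():
        bad = has_baseline.index[has_baseline > 1e-9].tolist()
        raise ValueError(f"subjects without a baseline (t=0) record: {bad[:5]}")
    return series


def ols_subject_slopes(series: pd.DataFrame) -> pd.DataFrame:
    """Per-subject OLS of log eGFR on time; no pooling.

    Used for replication-style cohorts where each subject's raw slope is
    computed independently across all available measures.
    """
    series = validate_longitudinal(series)
    rows = {}
    for sid, grp in series.groupby("subject_id", sort=False):
        t = grp["time_years"].to_numpy(dtype=float)
        y = np.log(grp["egfr"].to_numpy(dtype=float))
        slope, _ = np.polyfit(t, y, 1)
        rows[sid] = slope
    c = pd.Series(rows, name="log_slope")
    return pd.DataFrame({"log_slope": c, "annual_pct": slope_to_annual_pct(c.to_numpy())})


def _per_subject_ols(series: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for sid, grp in series.groupby("subject_id", sort=False):
        t = grp["time_years"].to_numpy(dtype=float)
        y = np.log(grp["egfr"].to_numpy(dtype=float))
        slope, intercept = np.polyfit(t, y, 1)
        resid = y - (intercept + slope * t)
        rows[sid] = (intercept, slope, float(np.max(np.abs(resid))))
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["intercept", "slope", "max_abs_resid"]
    )
    out.index.name = "subject_id"
    return out


def fit_random_slope_model(series: pd.DataFrame, reml: bool = True) -> RandomSlopeFit:
    """Fit the random-intercept/random-slope model to log eGFR.

    The random-effects covariance is unstructured (intercept-slope
    correlation free). If the optimizer reports a singular covariance the
    model is refit with independent (diagonal) random effects and a
    warning is logged. Subject BLUPs come from the fitted model's
    empirical-Bayes estimates.
    """
    series = validate_longitudinal(series)
    n_subj = series["subject_id"].nunique()
    if n_subj < 2:
        raise ValueError("need >= 2 subjects to fit a mixed model")

    # degenerate noiseless case: every trajectory exactly linear. The
    # residual variance is zero, the mixed model is singular, and
    # per-subject OLS is the exact solution; fixed effects are the means
    # of the subject lines and the random effects their deviations.
    per_subj = _per_subject_ols(series)
    if per_subj["max_abs_resid"].max() < 1e-10:
        beta0 = float(per_subj["intercept"].mean())
        beta1 = float(per_subj["slope"].mean())
        effects = pd.DataFrame(
            {"b0": per_subj["intercept"] - beta0, "b1": per_subj["slope"] - beta1}
        )
        effects.index.name = "subject_id"
        cov = np.cov(np.column_stack([effects["b0"], effects["b1"]]).T, ddof=1)
        return RandomSlopeFit(
            beta0=beta0,
            beta1=beta1,
            subject_effects=effects,
            cov_re=np.atleast_2d(cov),
            resid_sd=0.0,
            converged=True,
            method="exact-noiseless",
        )

    data = pd.DataFrame(
        {
            "y": np.log(series["egfr"].to_numpy(dtype=float)),
            "t": series["time_years"].to_numpy(dtype=float),
            "subject": series["subject_id"].to_numpy(),
        }
    )

    def _fit(diagonal: bool):
        if diagonal:
            model = smf.mixedlm(
                "y ~ t",
                data,
                groups=data["subject"],
                re_formula="1",
                vc_formula={"t": "0 + t"},
            )
        else:
            model = smf.mixedlm("y ~ t", data, groups=data["subject"], re_formula="~t")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            return model.fit(reml=reml, method=["lbfgs", "powell"], maxiter=500)

    result = _fit(diagonal=False)
    cov = np.asarray(result.cov_re)
    singular = not np.all(np.isfinite(cov)) or np.linalg.cond(cov) > 1e12
    if singular:
        logger.warning("singular random-effects covariance; refitting with diagonal")
        diag_result = _fit(diagonal=True)
        if np.all(np.isfinite(np.asarray(diag_result.cov_re))):
            result = diag_result
            re_var = np.asarray(result.cov_re).ravel()[0]
            vc_var = float(result.vcomp[0]) if len(result.vcomp) else 0.0
            cov = np.diag([re_var, vc_var])

    effects = pd.DataFrame.from_dict(
        {
            g: {
                "b0": float(re.iloc[0]),
                "b1": float(re.iloc[1]) if len(re) > 1 else 0.0,
            }
            for g, re in result.random_effects.items()
        },
        orient="index",
    )
    effects.index.name = "subject_id"
    # keep input subject order
    order = pd.unique(series["subject_id"])
    effects = effects.loc[order]

    return RandomSlopeFit(
        beta0=float(result.params["Intercept"]),
        beta1=float(result.params["t"]),
        subject_effects=effects,
        cov_re=cov,
        resid_sd=float(np.sqrt(max(result.scale, 0.0))),
        converged=bool(getattr(result, "converged", True)),
    )


def slope_to_annual_pct(c):
    """Annual percent eGFR change from a log-scale yearly slope: ``100*(e^c - 1)``."""
    return 100.0 * np.expm1(np.asarray(c, dtype=float))


def annual_pct_to_log_slope(pct):
    """Inverse map ``c = log(pct/100 + 1)``; requires ``pct > -100``."""
    pct = np.asarray(pct, dtype=float)
    if np.any(pct <= -100.0):
        raise ValueError("annual percent change must be > -100")
    return np.log1p(pct / 100.0)


def project_future_egfr(
    egfr_baseline: float,
    log_slope: float,
    horizon_years: float = 5.0,
    subject_id: str = "",
) -> EgfrProjection:
    """Project eGFR forward and flag ESKD (projected eGFR < 15).

    ``egfr_future = egfr_baseline * exp(horizon_years * c)`` with ``c`` the
    log-scale yearly slope.
    """
    if egfr_baseline <= 0:
        raise ValueError("baseline eGFR must be positive")
    future = float(egfr_baseline) * float(np.exp(horizon_years * log_slope))
    return EgfrProjection(
        subject_id=subject_id,
        egfr_baseline=float(egfr_baseline),
        egfr_future=future,
        eskd_flag=bool(future < ESKD_EGFR_THRESHOLD),
        horizon_years=float(horizon_years),
    )


def project_cohort(
    baselines: pd.Series, log_slopes: pd.Series, horizon_years: float = 5.0
) -> pd.DataFrame:
    """Vectorised projection for a cohort; index-aligned on subject ID."""
    idx = baselines.index.intersection(log_slopes.index)
    base = baselines.loc[idx].to_numpy(dtype=float)
    if np.any(base <= 0):
        raise ValueError("baseline eGFR must be positive")
    future = base * np.exp(horizon_years * log_slopes.loc[idx].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "egfr_baseline": base,
            "egfr_future": future,
            "eskd_flag": future < ESKD_EGFR_THRESHOLD,
        },
        index=idx,
    )
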