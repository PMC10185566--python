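"""Single-site epigenome-wide association testing.

For every CpG, the trait (baseline eGFR or eGFR slope) is regressed on
that probe's methylation level plus clinical covariates by ordinary least
squares; the probe coefficient is tested with a two-sided t test. A
positive coefficient means higher methylation goes with higher baseline
eGFR (or slower decline). Multiplicity is handled by Bonferroni and by
Benjamini-Hochberg step-up FDR flags, and calibration is summarised by
the genomic inflation factor lambda.

The per-probe models are computed with Frisch-Waugh residualization —
trait and probe are both residualized on the covariate design once, then
each probe reduces to a simple regression — which is algebraically
identical to the full OLS fit but runs in one matrix pass over the array.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .preprocess import MethylationMatrix

__all__ = [
    "EwasResult",
    "build_design",
    "run_single_site_ewas",
    "bonferroni_adjust",
    "bh_fdr",
    "genomic_inflation",
    "pc_clinical_association",
]

logger = logging.getLogger(__name__)

CHI2_MEDIAN_DF1 = float(stats.chi2.ppf(0.5, 1))  # 0.454936...


@dataclass
class EwasResult:
    """Per-probe association statistics for one trait.

    ``table`` columns: ``coefficient``, ``stderr``, ``p``, ``p_bonferroni``,
    ``fdr_significant`` (BH step-up flags at ``fdr_q``).
    """

    table: pd.DataFrame
    trait: str
    covariates: list = field(default_factory=list)
    fdr_q: float = 0.05
    lambda_inflation: float = np.nan
    n_samples_used: int = 0

    def significant(self, bonferroni_alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["p_bonferroni"] < bonferroni_alpha]


class CollinearityError(ValueError):
    """Covariate design is rank deficient; carries the aliased columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear covariate columns: {self.columns}")


def build_design(covariates: pd.DataFrame | None, index=None) -> pd.DataFrame:
    """Numeric covariate design with intercept; categoricals dummy-coded.

    Object/categorical columns (e.g. smoking never/ex/current, batch) are
    expanded to k-1 dummies.
    """
    if covariates is None or covariates.shape[1] == 0:
        idx = covariates.index if covariates is not None else index
        return pd.DataFrame({"const": np.ones(len(idx))}, index=idx)
    cat_cols = [
        c
        for c in covariates.columns
        if covariates[c].dtype == object or str(covariates[c].dtype) == "category"
    ]
    design = pd.get_dummies(covariates, columns=cat_cols, drop_first=True, dtype=float)
    design = design.astype(float)
    design.insert(0, "const", 1.0)
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via the QR diagonal
        _, rmat = np.linalg.qr(X)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [design.columns[j] for j in range(X.shape[1]) if diag[j] <= tol]
        if not aliased:
            aliased = list(design.columns[rank:])
        raise CollinearityError(aliased)


def run_single_site_ewas(
    matrix: MethylationMatrix,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
    fdr_q: float = 0.05,
    trait_name: str = "trait",
) -> EwasResult:
    """OLS of trait on each probe + covariates; two-sided t test per probe.

    Samples with a missing trait or covariate value are dropped with a
    logged count. Probes with any missing methylation among retained
    samples get NaN statistics (the upstream filter normally removes
    them).
    """
    values = matrix.values
    trait = trait.reindex(values.index)
    if covariates is not None:
        covariates = covariates.reindex(values.index)
        complete = trait.notna() & covariates.notna().all(axis=1)
    else:
        complete = trait.notna()
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("dropping %d samples with missing trait/covariates", n_drop)
    values = values.loc[complete]
    trait = trait.loc[complete]
    design = build_design(
        covariates.loc[complete] if covariates is not None else None, index=values.index
    )
    _check_full_rank(design)

    X = design.to_numpy(dtype=float)
    n, p_cov = X.shape
    if n < p_cov + 2:
        raise ValueError(f"need at least {p_cov + 2} complete samples, have {n}")

    y = trait.to_numpy(dtype=float)
    Mv = values.to_numpy(dtype=float)

    # residualize trait and probes on the covariate design (incl. intercept)
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    M_r = Mv - Q @ (Q.T @ Mv)

    sxx = np.einsum("ij,ij->j", M_r, M_r)
    sxy = M_r.T @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
    syy = float(y_r @ y_r)
    rss = syy - beta * sxy
    df = n - p_cov - 1
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)

    table = pd.DataFrame(
        {
            "coefficient": beta,
            "stderr": se,
            "p": pvals,
            "p_bonferroni": bonferroni_adjust(pvals, allow_nan=True),
        },
        index=values.columns,
    )
    finite = np.isfinite(pvals)
    flags = np.zeros(len(pvals), dtype=bool)
    if finite.any():
        flags[finite] = bh_fdr(pvals[finite], q=fdr_q)
    table["fdr_significant"] = flags
    lam = genomic_inflation(pvals[finite]) if finite.any() else np.nan

    return EwasResult(
        table=table,
        trait=trait_name,
        covariates=list(covariates.columns) if covariates is not None else [],
        fdr_q=fdr_q,
        lambda_inflation=lam,
        n_samples_used=n,
    )


def _validate_p(p_values, allow_nan: bool = False) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if not allow_nan and not finite.all():
        raise ValueError("p-values must be finite")
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bonferroni_adjust(p_values, allow_nan: bool = False) -> np.ndarray:
    """Bonferroni family-wise adjustment: ``min(m * p, 1)``.

    ``m`` counts the finite entries when ``allow_nan`` is set.
    """
    p = _validate_p(p_values, allow_nan)
    m = int(np.isfinite(p).sum()) if allow_nan else p.size
    return np.minimum(p * m, 1.0)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up flags at FDR level ``q``.

    Flags the ``k`` smallest p-values where ``k`` is the largest rank with
    ``p_(k) <= q * k / m`` (boundary inclusive). Returns a boolean array
    aligned with the input.
    """
    p = _validate_p(p_values)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = q * np.arange(1, m + 1) / m
    passing = sorted_p <= thresholds
    flags = np.zeros(m, dtype=bool)
    if passing.any():
        k = int(np.max(np.nonzero(passing)[0]))
        flags[order[: k + 1]] = True
    return flags


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median observed chi^2_1 over null median.

    Exact zeros are mapped to the smallest positive float before the
    quantile transform (and logged), since chi2.isf(0) is infinite.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n_zero = int((p == 0).sum())
    if n_zero:
        logger.warning("%d zero p-values mapped to float tiny for lambda", n_zero)
        p = np.where(p == 0, np.finfo(float).tiny, p)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_MEDIAN_DF1)


def pc_clinical_association(
    matrix: MethylationMatrix,
    labels: pd.Series,
    n_pcs: int = 10,
    n_folds: int = 10,
    C: float = 1.0,
    seed: int = 0,
) -> dict:
    """How well methylation principal components classify a clinical label.

    PCA on the (beta or M) matrix, top ``n_pcs`` scores as features of an
    L2-regularized logistic regression, evaluated by k-fold
    cross-validated AUROC. Folds containing a single class are skipped
    with a warning and reported. Returns per-fold AUROCs and their mean.
    """
    labels = labels.reindex(matrix.sample_ids)
    keep = labels.notna()
    X = matrix.values.loc[keep].to_numpy(dtype=float)
    y = labels.loc[keep].astype(int).to_numpy()
    max_rank = min(X.shape[0], X.shape[1])
    if n_pcs > max_rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank bound {max_rank}")
    scores = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)

    aurocs, skipped = [], 0
    for train, test in KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(scores):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            skipped += 1
            logger.warning("skipping single-class fold")
            continue
        clf = LogisticRegression(C=C, max_iter=2000)
        clf.fit(scores[train], y[train])
        aurocs.append(float(roc_auc_score(y[test], clf.decision_function(scores[test]))))
    return {
        "fold_aurocs": aurocs,
        "mean_auroc": float(np.mean(aurocs)) if aurocs else np.nan,
        "skipped_folds": skipped,
    }
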