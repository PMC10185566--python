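"""Multisite CpG selection by repeated nested-CV LASSO.

The procedure builds a sparse linear predictor of a kidney-function trait
from many CpGs at once:

1. Hold out a test split (10%) untouched by everything below.
2. Repeat R times: partition the training samples into K outer folds.
   For each outer fold, choose the L1 penalty ``alpha`` on the outer-train
   portion by inner k-fold cross-validation with a one-SD-style rule —
   the *largest* alpha whose mean inner R^2 is within one SD (taken
   across the alpha grid) of the best — then fit a LASSO at that alpha
   and record the selected probe set and the Pearson correlation of the
   outer-test predictions. R=K=10 yields 100 fold models.
3. Weight every probe by the summed outer-test correlations of the
   fold models that selected it, and rank probes by weight.
4. Scan candidate model sizes n over the ranked list, refitting a LASSO
   on the top-n probes on the whole training set; choose the *largest* n
   whose BIC is within 0.1 SD (across scanned sizes) of the minimum.
5. Fit the final LASSO on the top-n* probes (zero coefficients are kept
   in the model record) and evaluate on the held-out split.

All randomness flows from a single seed; the same seed reproduces fold
assignments, selected sets and coefficients exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LogisticRegression, lasso_path
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .preprocess import Standardizer

__all__ = [
    "AlphaSelection",
    "FoldResult",
    "SiteWeights",
    "BicPath",
    "MultisiteModel",
    "default_alpha_grid",
    "select_alpha",
    "run_repeated_nested_cv",
    "aggregate_site_weights",
    "bic_select_n",
    "fit_final_model",
    "predict_and_evaluate",
    "classify_selected_sites",
    "apply_cross_cohort",
    "MultisitePipelineResult",
    "fit_multisite_pipeline",
]

LASSO_KW = dict(max_iter=20_000, tol=1e-4)


@dataclass
class AlphaSelection:
    """Inner-CV R^2 profile over the alpha grid and the chosen alpha.

    ``alpha_star`` is the largest grid value whose mean inner-CV R^2 is
    at least ``max(R^2) - SD(R^2)``, the SD taken across grid values.
    """

    grid: np.ndarray
    r2: np.ndarray
    sd_r2: float
    alpha_star: float


@dataclass
class FoldResult:
    """One outer-fold model: selected probes and outer-test correlation."""

    repeat: int
    fold: int
    selected: tuple
    rho: float
    alpha_star: float


@dataclass
class SiteWeights:
    """Per-probe summed fold correlations; ranked descending.

    Ties are broken by ascending probe ID so the ranking is deterministic.
    """

    weights: pd.Series

    def ranked(self, positive_only: bool = True) -> list:
        w = self.weights
        if positive_only:
            w = w[w > 0]
        order = sorted(w.index, key=lambda k: (-w[k], str(k)))
        return order


@dataclass
class BicPath:
    """BIC over candidate model sizes and the chosen size.

    ``n_star`` is the largest size whose BIC is within ``0.1 * SD(BIC)``
    (SD across scanned sizes) of the minimum.
    """

    sizes: np.ndarray
    bic: np.ndarray
    n_star: int
    alpha_by_size: dict = field(default_factory=dict)


@dataclass
class MultisiteModel:
    """Sparse linear predictor over a fixed candidate probe list.

    ``probes`` is the ordered candidate list of length n*; some entries
    may carry exactly-zero coefficients (candidates the final LASSO
    declined), and they stay in the record. Standardization parameters
    are stored so the model can be applied to new samples, including
    external cohorts where absent probes are zero-filled on the
    standardized scale.
    """

    probes: list
    coefficients: np.ndarray
    covariate_names: list
    covariate_coefficients: np.ndarray
    intercept: float
    alpha: float
    feature_means: pd.Series
    feature_sds: pd.Series
    with_covariates: bool

    def predict(
        self,
        matrix_values: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        zero_fill_missing: bool = False,
    ) -> pd.Series:
        cols = []
        for pid in self.probes:
            if pid in matrix_values.columns:
                z = (matrix_values[pid] - self.feature_means[pid]) / self.feature_sds[pid]
            elif zero_fill_missing:
                z = pd.Series(0.0, index=matrix_values.index)
            else:
                missing = [p for p in self.probes if p not in matrix_values.columns]
                raise ValueError(f"probes absent from matrix: {missing}")
            cols.append(z.to_numpy(dtype=float))
        pred = np.zeros(len(matrix_values))
        if cols:
            pred = np.column_stack(cols) @ self.coefficients
        if self.with_covariates:
            if covariates is None:
                raise ValueError("model was fit with covariates; none supplied")
            for name, coef in zip(self.covariate_names, self.covariate_coefficients):
                z = (covariates[name] - self.feature_means[name]) / self.feature_sds[name]
                pred = pred + coef * z.to_numpy(dtype=float)
        return pd.Series(pred + self.intercept, index=matrix_values.index)

    def to_json(self) -> str:
        payload = {
            "probes": list(self.probes),
            "coefficients": list(map(float, self.coefficients)),
            "covariate_names": list(self.covariate_names),
            "covariate_coefficients": list(map(float, self.covariate_coefficients)),
            "intercept": float(self.intercept),
            "alpha": float(self.alpha),
            "feature_means": {str(k): float(v) for k, v in self.feature_means.items()},
            "feature_sds": {str(k): float(v) for k, v in self.feature_sds.items()},
            "with_covariates": bool(self.with_covariates),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MultisiteModel":
        d = json.loads(text)
        return cls(
            probes=d["probes"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            covariate_names=d["covariate_names"],
            covariate_coefficients=np.asarray(d["covariate_coefficients"], dtype=float),
            intercept=d["intercept"],
            alpha=d["alpha"],
            feature_means=pd.Series(d["feature_means"]),
            feature_sds=pd.Series(d["feature_sds"]),
            with_covariates=d["with_covariates"],
        )


def default_alpha_grid(X: np.ndarray, y: np.ndarray, n_alphas: int = 50) -> np.ndarray:
    """Log-spaced grid from ``alpha_max`` down to ``1e-4 * alpha_max``.

    ``alpha_max = max |X^T (y - ybar)| / n`` is the smallest penalty that
    zeroes every coefficient in a standardized LASSO.
    """
    yc = y - y.mean()
    alpha_max = float(np.max(np.abs(X.T @ yc)) / len(y))
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.geomspace(alpha_max, 1e-4 * alpha_max, num=n_alphas)


def _inner_r2(X, y, grid, inner_folds, seed) -> np.ndarray:
    """Mean out-of-fold R^2 per alpha via one LASSO path per inner fold."""
    # lasso_path requires decreasing alphas
    order = np.argsort(grid)[::-1]
    alphas_desc = np.asarray(grid, dtype=float)[order]
    r2 = np.zeros((inner_folds, len(grid)))
    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    for f, (tr, te) in enumerate(kf.split(X)):
        ytr = y[tr]
        ybar = ytr.mean()
        _, coefs, _ = lasso_path(
            X[tr], ytr - ybar, alphas=alphas_desc, max_iter=LASSO_KW["max_iter"], tol=LASSO_KW["tol"]
        )
        preds = X[te] @ coefs + ybar  # (n_te, n_alphas)
        resid = preds - y[te][:, None]
        ss_res = np.einsum("ij,ij->j", resid, resid)
        ss_tot = float(np.sum((y[te] - y[te].mean()) ** 2))
        r2[f, order] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    mean_r2 = r2.mean(axis=0)
    if not np.all(np.isfinite(mean_r2)):
        raise ValueError("inner-CV R^2 undefined (constant test outcomes)")
    return mean_r2


def apply_one_sd_rule(grid, r2) -> tuple[float, float]:
    """The alpha-selection rule: largest alpha with R^2 >= max - SD.

    SD is taken across the grid's R^2 values (ddof=1 when the grid has
    more than one point).
    """
    grid = np.asarray(grid, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    sd = float(np.std(r2, ddof=1)) if len(r2) > 1 else 0.0
    threshold = float(np.max(r2)) - sd
    eligible = grid[r2 >= threshold]
    return float(np.max(eligible)), sd


def select_alpha(
    X: np.ndarray,
    y: np.ndarray,
    grid=None,
    inner_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 50,
) -> AlphaSelection:
    """Choose the LASSO penalty by inner CV and the largest-within-one-SD rule.

    A large alpha is preferred so only a small set of the most important
    CpGs survives in each fold model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = default_alpha_grid(X, y, n_alphas=n_alphas)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty alpha grid")
    if grid.size == 1:
        return AlphaSelection(grid=grid, r2=np.array([np.nan]), sd_r2=0.0, alpha_star=float(grid[0]))
    r2 = _inner_r2(X, y, grid, inner_folds, seed)
    alpha_star, sd = apply_one_sd_rule(grid, r2)
    return AlphaSelection(grid=grid, r2=r2, sd_r2=sd, alpha_star=alpha_star)


def _assemble_features(
    features: pd.DataFrame, covariates: pd.DataFrame | None
) -> tuple[pd.DataFrame, list]:
    if covariates is None:
        return features, []
    overlap = set(features.columns) & set(covariates.columns)
    if overlap:
        raise ValueError(f"covariate names collide with probe IDs: {sorted(overlap)}")
    return pd.concat([features, covariates], axis=1), list(covariates.columns)


def run_repeated_nested_cv(
    features: pd.DataFrame,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
    outer_folds: int = 10,
    repeats: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 50,
) -> list[FoldResult]:
    """Repeats x outer-folds LASSO models with per-fold alpha selection.

    ``features`` must already be standardized training-set probes (the
    held-out test split is excised before calling this and never seen
    here). Covariates, if given, are standardized columns appended to the
    design and penalized alongside the probes; they are excluded from the
    recorded selected sets, which contain probes only.
    """
    full, cov_names = _assemble_features(features, covariates)
    X_all = full.to_numpy(dtype=float)
    y_all = trait.to_numpy(dtype=float)
    n = len(y_all)
    if n // outer_folds < 5:
        raise ValueError(
            f"outer folds of ~{n // outer_folds} samples are too small; use fewer folds"
        )
    probe_cols = np.asarray(full.columns[: features.shape[1]])
    is_probe = np.zeros(full.shape[1], dtype=bool)
    is_probe[: features.shape[1]] = True

    results = []
    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(repeats)]
    for j in range(repeats):
        kf = KFold(n_splits=outer_folds, shuffle=True, random_state=repeat_seeds[j])
        for i, (tr, te) in enumerate(kf.split(X_all)):
            sel = select_alpha(
                X_all[tr],
                y_all[tr],
                inner_folds=inner_folds,
                seed=repeat_seeds[j] + i,
                n_alphas=n_alphas,
            )
            model = Lasso(alpha=sel.alpha_star, **LASSO_KW)
            model.fit(X_all[tr], y_all[tr])
            nz = model.coef_ != 0
            selected = tuple(probe_cols[nz[is_probe][: len(probe_cols)]])
            pred = model.predict(X_all[te])
            # a fold model with no active features predicts a constant and
            # carries no ranking information: its correlation is zero
            if np.ptp(pred) < 1e-12 or np.ptp(y_all[te]) < 1e-12:
                rho = 0.0
            else:
                rho = float(stats.pearsonr(pred, y_all[te])[0])
            results.append(
                FoldResult(repeat=j, fold=i, selected=selected, rho=rho, alpha_star=sel.alpha_star)
            )
    return results


def aggregate_site_weights(fold_results: list[FoldResult]) -> SiteWeights:
    """Weight each probe by the summed outer-test correlations of the
    fold models that gave it a nonzero coefficient.

    Correlations are summed as signed values, exactly as the weighting
    formula is stated; a probe never selected has weight zero.
    """
    if not fold_results:
        raise ValueError("no fold results to aggregate")
    acc: dict = {}
    for fr in fold_results:
        for pid in fr.selected:
            acc[pid] = acc.get(pid, 0.0) + fr.rho
    return SiteWeights(weights=pd.Series(acc, dtype=float).sort_index())


def lasso_bic(X: np.ndarray, y: np.ndarray, model: Lasso) -> float:
    """Gaussian BIC with active-set degrees of freedom.

    ``BIC = N ln(RSS/N) + k ln(N)`` where k counts nonzero coefficients
    plus the intercept — the standard df estimator for the LASSO.
    """
    n = len(y)
    resid = y - model.predict(X)
    rss = float(resid @ resid)
    rss = max(rss, np.finfo(float).tiny)
    k = int(np.count_nonzero(model.coef_)) + 1
    return n * np.log(rss / n) + k * np.log(n)


def apply_bic_rule(sizes, bic) -> int:
    """The size-selection rule: largest n with BIC <= min + 0.1 * SD."""
    sizes = np.asarray(sizes)
    bic = np.asarray(bic, dtype=float)
    sd = float(np.std(bic, ddof=1)) if len(bic) > 1 else 0.0
    threshold = float(np.min(bic)) + 0.1 * sd
    return int(np.max(sizes[bic <= threshold]))


def bic_select_n(
    features: pd.DataFrame,
    trait: pd.Series,
    ranked_probes: list,
    covariates: pd.DataFrame | None = None,
    sizes=None,
    max_size: int = 200,
    inner_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 50,
) -> BicPath:
    """Scan model sizes over the ranked probes and pick n* by the BIC rule.

    For each candidate size n a LASSO is refit on the top-n probes (plus
    covariates if supplied) on the full training set, with alpha
    re-selected by inner CV on that restricted design; a larger model is
    preferred as long as its BIC stays within a tenth of an SD of the
    best, because the highest-weight probes are already the most
    trustworthy and extra ones buy robustness.
    """
    if sizes is None:
        sizes = range(1, min(len(ranked_probes), max_size) + 1)
    sizes = np.asarray(sorted(set(int(s) for s in sizes)))
    if sizes.size == 0:
        raise ValueError("no candidate sizes to scan")
    if sizes.max() > len(ranked_probes):
        raise ValueError("candidate size exceeds number of ranked probes")
    y = trait.to_numpy(dtype=float)
    bics, alpha_by_size = [], {}
    for n_sites in sizes:
        sub = features[list(ranked_probes[:n_sites])]
        full, _ = _assemble_features(sub, covariates)
        X = full.to_numpy(dtype=float)
        sel = select_alpha(X, y, inner_folds=inner_folds, seed=seed, n_alphas=n_alphas)
        model = Lasso(alpha=sel.alpha_star, **LASSO_KW)
        model.fit(X, y)
        alpha_by_size[int(n_sites)] = sel.alpha_star
        bics.append(lasso_bic(X, y, model))
    bic = np.asarray(bics)
    n_star = apply_bic_rule(sizes, bic)
    return BicPath(sizes=sizes, bic=bic, n_star=n_star, alpha_by_size=alpha_by_size)


def fit_final_model(
    matrix_values: pd.DataFrame,
    trait: pd.Series,
    ranked_probes: list,
    n_star: int,
    covariates: pd.DataFrame | None = None,
    with_covariates: bool = True,
    alpha: float | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 50,
) -> MultisiteModel:
    """Fit the final LASSO on the top-n* probes (raw inputs, not yet
    standardized; standardization parameters are fitted here and stored).

    Zero-coefficient candidates remain in the model record. With
    ``alpha=None`` the penalty is re-selected by inner CV on the final
    design.
    """
    probes = list(ranked_probes[:n_star])
    feats = matrix_values[probes]
    scaler = Standardizer()
    cov = covariates if (with_covariates and covariates is not None) else None
    full_raw, cov_names = _assemble_features(feats, cov)
    full = scaler.fit_transform(full_raw)
    X = full.to_numpy(dtype=float)
    y = trait.to_numpy(dtype=float)
    if alpha is None:
        alpha = select_alpha(X, y, inner_folds=inner_folds, seed=seed, n_alphas=n_alphas).alpha_star
    model = Lasso(alpha=alpha, **LASSO_KW)
    model.fit(X, y)
    n_probe_cols = len(probes)
    return MultisiteModel(
        probes=probes,
        coefficients=model.coef_[:n_probe_cols].copy(),
        covariate_names=cov_names,
        covariate_coefficients=model.coef_[n_probe_cols:].copy(),
        intercept=float(model.intercept_),
        alpha=float(alpha),
        feature_means=scaler.means.copy(),
        feature_sds=scaler.sds.copy(),
        with_covariates=cov is not None,
    )


def predict_and_evaluate(
    model: MultisiteModel,
    matrix_values: pd.DataFrame,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
    zero_fill_missing: bool = False,
) -> dict:
    """Apply a model and report PCC, SCC and MAE plus per-sample predictions."""
    pred = model.predict(matrix_values, covariates, zero_fill_missing=zero_fill_missing)
    y = trait.reindex(pred.index).to_numpy(dtype=float)
    p = pred.to_numpy()
    if np.ptp(p) < 1e-12 or np.ptp(y) < 1e-12:
        # constant predictions rank nothing: report zero correlation
        pcc = scc = 0.0
    else:
        pcc = float(stats.pearsonr(p, y)[0])
        scc = float(stats.spearmanr(p, y)[0])
    return {
        "pcc": pcc,
        "scc": scc,
        "mae": float(np.mean(np.abs(p - y))),
        "predictions": pred,
    }


def classify_selected_sites(
    matrix_values: pd.DataFrame,
    labels: pd.Series,
    selected_probes: list,
    n_folds: int = 10,
    C: float = 1.0,
    seed: int = 0,
) -> dict:
    """L2 logistic regression on the selected probes, k-fold CV AUROC.

    Checks whether the chosen CpG set separates subjects with and without
    kidney dysfunction. Single-class folds are skipped and counted.
    """
    if len(selected_probes) == 0:
        raise ValueError("empty probe set")
    X_df, scaler = pd.DataFrame(), Standardizer()
    X_df = scaler.fit_transform(matrix_values[list(selected_probes)])
    X = X_df.to_numpy(dtype=float)
    y = labels.reindex(matrix_values.index).astype(int).to_numpy()
    aurocs, skipped = [], 0
    for tr, te in KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(X):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            skipped += 1
            continue
        clf = LogisticRegression(C=C, max_iter=2000)
        clf.fit(X[tr], y[tr])
        aurocs.append(float(roc_auc_score(y[te], clf.decision_function(X[te]))))
    return {
        "fold_aurocs": aurocs,
        "mean_auroc": float(np.mean(aurocs)) if aurocs else np.nan,
        "skipped_folds": skipped,
    }


@dataclass
class MultisitePipelineResult:
    """End-to-end output: the final model, its selection path and held-out metrics."""

    model: MultisiteModel
    fold_results: list
    weights: SiteWeights
    bic_path: BicPath
    test_metrics: dict
    test_samples: pd.Index


def fit_multisite_pipeline(
    matrix_values: pd.DataFrame,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
    test_fraction: float = 0.1,
    outer_folds: int = 10,
    repeats: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 50,
    max_size: int = 200,
    with_covariates: bool = True,
) -> MultisitePipelineResult:
    """The full procedure: excise a test split, run repeated nested CV,
    aggregate weights, choose the model size by BIC and fit/evaluate the
    final model.

    The test split is drawn once up front and only ever touched by the
    final evaluation.
    """
    rng = np.random.default_rng(seed)
    n = len(matrix_values)
    n_test = max(1, int(round(test_fraction * n)))
    test_idx = matrix_values.index[rng.choice(n, size=n_test, replace=False)]
    train_idx = matrix_values.index.difference(test_idx, sort=False)

    train_vals = matrix_values.loc[train_idx]
    train_trait = trait.loc[train_idx]
    cov_train = covariates.loc[train_idx] if covariates is not None else None

    scaler = Standardizer()
    feats = scaler.fit_transform(train_vals)
    cov_scaled = None
    if cov_train is not None and with_covariates:
        cov_scaler = Standardizer()
        cov_scaled = cov_scaler.fit_transform(cov_train)

    folds = run_repeated_nested_cv(
        feats,
        train_trait,
        covariates=cov_scaled,
        outer_folds=outer_folds,
        repeats=repeats,
        inner_folds=inner_folds,
        seed=seed,
        n_alphas=n_alphas,
    )
    weights = aggregate_site_weights(folds)
    ranked = weights.ranked()
    if not ranked:
        # no probe ever earned a nonzero coefficient: the honest final
        # model is intercept-only (typical of null cohorts)
        null_model = MultisiteModel(
            probes=[],
            coefficients=np.zeros(0),
            covariate_names=[],
            covariate_coefficients=np.zeros(0),
            intercept=float(train_trait.mean()),
            alpha=np.inf,
            feature_means=pd.Series(dtype=float),
            feature_sds=pd.Series(dtype=float),
            with_covariates=False,
        )
        test_metrics = predict_and_evaluate(
            null_model, matrix_values.loc[test_idx], trait.loc[test_idx]
        )
        return MultisitePipelineResult(
            model=null_model,
            fold_results=folds,
            weights=weights,
            bic_path=BicPath(sizes=np.array([0]), bic=np.array([np.nan]), n_star=0),
            test_metrics=test_metrics,
            test_samples=test_idx,
        )
    bic_path = bic_select_n(
        feats,
        train_trait,
        ranked,
        covariates=cov_scaled,
        max_size=max_size,
        inner_folds=inner_folds,
        seed=seed,
        n_alphas=n_alphas,
    )
    model = fit_final_model(
        train_vals,
        train_trait,
        ranked,
        bic_path.n_star,
        covariates=cov_train if with_covariates else None,
        with_covariates=with_covariates,
        inner_folds=inner_folds,
        seed=seed,
        n_alphas=n_alphas,
    )
    test_metrics = predict_and_evaluate(
        model,
        matrix_values.loc[test_idx],
        trait.loc[test_idx],
        covariates.loc[test_idx] if (covariates is not None and with_covariates) else None,
    )
    return MultisitePipelineResult(
        model=model,
        fold_results=folds,
        weights=weights,
        bic_path=bic_path,
        test_metrics=test_metrics,
        test_samples=test_idx,
    )


def apply_cross_cohort(
    cohort_a_values: pd.DataFrame,
    trait_a: pd.Series,
    cohort_b_values: pd.DataFrame,
    trait_b: pd.Series,
    model: MultisiteModel,
    retrain: bool = False,
    covariates_a: pd.DataFrame | None = None,
    covariates_b: pd.DataFrame | None = None,
    seed: int = 0,
    **pipeline_kw,
) -> dict:
    """Transfer a model from cohort A to cohort B.

    In direct mode the original model is applied with absent probes'
    standardized values set to zero. In retrain mode the whole pipeline
    is rerun on cohort A restricted to the probe intersection before
    evaluating on cohort B.
    """
    common = cohort_a_values.columns.intersection(cohort_b_values.columns)
    if len(common) == 0:
        raise ValueError("cohorts share no probes")
    if retrain:
        result = fit_multisite_pipeline(
            cohort_a_values[common],
            trait_a,
            covariates=covariates_a,
            seed=seed,
            **pipeline_kw,
        )
        used_model = result.model
    else:
        used_model = model
    metrics = predict_and_evaluate(
        used_model,
        cohort_b_values,
        trait_b,
        covariates=covariates_b if used_model.with_covariates else None,
        zero_fill_missing=True,
    )
    metrics["model"] = used_model
    metrics["n_common_probes"] = int(len(common))
    return metrics
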