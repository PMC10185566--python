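"""Synthetic EWAS cohorts with longitudinal kidney function.

Generates sample x CpG beta-value matrices together with the phenotypes
the downstream analyses expect: baseline eGFR, log-scale eGFR
trajectories following a random-intercept/random-slope model, leukocyte
cell-type composition, batch structure and a probe manifest carrying the
flags the quality filters act on (SNP overlap, non-CpG context, sex
chromosomes, sporadic missingness).

Methylation is simulated on the M (logit) scale, where Gaussian machinery
is natural, and exposed as beta values through the logistic map
``beta = 2^M / (2^M + 1)``. Probes are organised into contiguous blocks
with AR(1) within-block correlation of the latent M values, mimicking the
spatial dependency of neighbouring CpGs. A small set of causal probes
affects baseline eGFR and/or the per-subject eGFR slope linearly on the
M scale; everything else is noise, batch offsets and cell-composition
signal. The ground truth is returned alongside so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import GENOME_CHROMOSOMES, MethylationMatrix, ProbeManifest

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_longitudinal_egfr",
    "simulate_reference_panel",
]

CELL_TYPE_NAMES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator; defaults define the study conditions.

    M-scale quantities are in M-value units. ``effect_size_sd`` scales the
    causal-probe effects on the standardized phenotype. The longitudinal
    block follows the random-slope model: ``beta1`` is the fixed log-eGFR
    slope per year, ``re_sd_intercept``/``re_sd_slope`` the random-effect
    SDs and ``resid_sd`` the visit-level residual SD. The visit-count
    range reflects a registry with a median of a few dozen eGFR measures
    per subject.
    """

    n_samples: int = 200
    n_probes: int = 1000
    n_causal_baseline: int = 10
    n_causal_slope: int = 10
    effect_size_sd: float = 1.0
    block_size: int = 10
    block_rho: float = 0.6
    n_batches: int = 3
    batch_sd: float = 0.15
    n_cell_types: int = 6
    dirichlet_alpha: tuple = (4.0, 3.0, 2.0, 2.0, 3.0, 10.0)
    noise_sd: float = 0.3
    beta1: float = -0.02
    re_sd_intercept: float = 0.25
    re_sd_slope: float = 0.03
    resid_sd: float = 0.1
    followup_years: float = 10.0
    visits_min: int = 10
    visits_max: int = 40
    seed: int = 0
    # fractions of probes carrying filterable flags
    frac_snp_flagged: float = 0.02
    frac_non_cpg: float = 0.01
    frac_sex_chromosome: float = 0.02
    frac_missing_probes: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "n_samples",
            "n_probes",
            "block_size",
            "n_batches",
            "n_cell_types",
            "visits_min",
            "visits_max",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("n_causal_baseline", "n_causal_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
            if getattr(self, name) > self.n_probes:
                raise ValueError(f"{name} cannot exceed n_probes")
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must be in [0, 1)")
        if len(self.dirichlet_alpha) != self.n_cell_types:
            raise ValueError("dirichlet_alpha length must equal n_cell_types")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be positive")
        for name in ("re_sd_intercept", "re_sd_slope", "resid_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.visits_min < 2:
            raise ValueError("visits_min must be >= 2 (slope unidentifiable)")
        if self.visits_max < self.visits_min:
            raise ValueError("visits_max must be >= visits_min")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for scoring recovery."""

    causal_probes_baseline: list
    causal_probes_slope: list
    effects_baseline: pd.Series
    effects_slope: pd.Series
    b0: pd.Series  # random intercepts of log eGFR
    b1: pd.Series  # random slopes (log units / year)
    log_slope: pd.Series  # c_i = beta1 + b1i
    annual_pct: pd.Series  # 100 * (exp(c_i) - 1)
    cell_fractions: pd.DataFrame
    batch: pd.Series
    beta1: float
    beta0: float


@dataclass
class SyntheticCohort:
    """Everything one simulated cohort provides to the pipeline."""

    matrix: MethylationMatrix
    manifest: ProbeManifest
    phenotypes: pd.DataFrame
    longitudinal: pd.DataFrame
    reference_panel: "pd.DataFrame"
    truth: CohortTruth
    config: SimulationConfig = field(repr=False, default=None)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan a global seed out to per-component generators via a counter scheme."""
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(n)]


def _block_ar1_noise(
    rng: np.random.Generator, n_samples: int, n_probes: int, block_size: int, rho: float
) -> np.ndarray:
    """Latent M deviations with AR(1) correlation inside contiguous blocks."""
    z = rng.standard_normal((n_samples, n_probes))
    if rho == 0.0:
        return z
    out = np.empty_like(z)
    scale = np.sqrt(1.0 - rho * rho)
    for start in range(0, n_probes, block_size):
        stop = min(start + block_size, n_probes)
        out[:, start] = z[:, start]
        for j in range(start + 1, stop):
            out[:, j] = rho * out[:, j - 1] + scale * z[:, j]
    return out


def simulate_reference_panel(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Cell-type reference panel of mean beta values.

    Rows are discriminating probes (IDs ``ref_0001``...), columns the cell
    types. Each cell type gets a distinctive methylation pattern: every
    discriminating probe is near-unmethylated in all types except one or
    two where it is near-fully methylated, the structure reference-based
    deconvolution relies on.
    """
    if config.n_cell_types < 2:
        raise ValueError("n_cell_types must be >= 2 for a reference panel")
    if rng is None:
        rng = _child_rngs(config.seed, 8)[6]
    k = config.n_cell_types
    probes_per_type = 10
    n_ref = k * probes_per_type
    base = rng.uniform(0.05, 0.15, size=(n_ref, k))
    for ct in range(k):
        rows = slice(ct * probes_per_type, (ct + 1) * probes_per_type)
        base[rows, ct] = rng.uniform(0.8, 0.95, size=probes_per_type)
    ids = [f"ref_{i:04d}" for i in range(n_ref)]
    names = list(CELL_TYPE_NAMES[:k]) + [f"CT{j}" for j in range(len(CELL_TYPE_NAMES), k)]
    return pd.DataFrame(base, index=ids, columns=names[:k])


def _simulate_covariates(rng: np.random.Generator, n: int, n_batches: int) -> pd.DataFrame:
    """Clinical covariates matching a diabetes-registry phenotype table."""
    sex = rng.integers(0, 2, size=n)
    age = rng.normal(60.0, 10.0, size=n)
    smoking = rng.choice(["never", "ex", "current"], size=n, p=[0.6, 0.25, 0.15])
    duration = rng.gamma(shape=3.0, scale=3.0, size=n)  # years of diabetes
    hba1c = rng.normal(7.5, 1.2, size=n)
    sbp = rng.normal(135.0, 18.0, size=n)
    dbp = rng.normal(78.0, 10.0, size=n)
    batch = rng.integers(0, n_batches, size=n)
    return pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "smoking": smoking,
            "diabetes_duration": duration,
            "hba1c": hba1c,
            "sbp": sbp,
            "dbp": dbp,
            "batch": batch,
        }
    )


def _make_manifest(
    rng: np.random.Generator, config: SimulationConfig, probe_ids, protected_idx=()
) -> ProbeManifest:
    """Probe annotations with filterable flags.

    Flags are never placed on ``protected_idx`` (the causal probes):
    planted signal lives in the probe set that survives quality control,
    since a causal probe removed by QC is unobservable by construction.
    """
    n = config.n_probes
    flaggable = np.array([j for j in range(n) if j not in set(protected_idx)])
    autosomes = [c for c in GENOME_CHROMOSOMES if c not in ("chrX", "chrY", "chrM")]
    chroms = np.array(rng.choice(autosomes, size=n), dtype=object)
    n_sex = min(int(round(config.frac_sex_chromosome * n)), len(flaggable))
    sex_idx = rng.choice(flaggable, size=n_sex, replace=False)
    chroms[sex_idx] = rng.choice(["chrX", "chrY"], size=n_sex)
    positions = rng.integers(10_000, 50_000_000, size=n)
    context = np.array(["CpG"] * n, dtype=object)
    n_ncpg = min(int(round(config.frac_non_cpg * n)), len(flaggable))
    context[rng.choice(flaggable, size=n_ncpg, replace=False)] = "non-CpG"
    snp = np.zeros(n, dtype=bool)
    n_snp = min(int(round(config.frac_snp_flagged * n)), len(flaggable))
    snp[rng.choice(flaggable, size=n_snp, replace=False)] = True
    regions = ["TSS1500", "TSS200", "gene body", "5'UTR", "3'UTR"]
    genes = [
        [(f"GENE{rng.integers(0, max(n // 2, 1)):05d}", regions[rng.integers(0, 5)])]
        if rng.random() < 0.7
        else []
        for _ in range(n)
    ]
    table = pd.DataFrame(
        {
            "chromosome": chroms,
            "position": positions,
            "context": context,
            "snp_overlap": snp,
            "genes": genes,
        },
        index=probe_ids,
    )
    return ProbeManifest(table)


def simulate_longitudinal_egfr(
    config: SimulationConfig,
    truth: CohortTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Visit-level eGFR series following the random-slope generative model.

    ``log(eGFR_ij) = beta0 + beta1*t + b0i + b1i*t + eps_ij`` with i.i.d.
    normal residuals. Every subject has a baseline visit at t=0 plus
    uniformly scattered follow-up times in (0, followup_years].
    """
    if config.visits_min < 2:
        raise ValueError("visits_min must be >= 2 (slope unidentifiable)")
    if rng is None:
        rng = _child_rngs(config.seed, 8)[5]
    rows = []
    for sid in truth.b0.index:
        n_vis = int(rng.integers(config.visits_min, config.visits_max + 1))
        times = np.concatenate(
            [[0.0], np.sort(rng.uniform(0.0, config.followup_years, size=n_vis - 1))]
        )
        eps = rng.normal(0.0, config.resid_sd, size=n_vis)
        log_egfr = (
            truth.beta0
            + truth.beta1 * times
            + truth.b0.loc[sid]
            + truth.b1.loc[sid] * times
            + eps
        )
        for t, v in zip(times, np.exp(log_egfr)):
            rows.append((sid, float(t), float(v)))
    return pd.DataFrame(rows, columns=["subject_id", "time_years", "egfr"])


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; bit-identical for a fixed seed.

    Pipeline: latent M values (probe means + correlated block noise +
    batch offsets + cell-composition signal + causal structure) ->
    logistic map to beta -> sprinkle manifest flags and missingness ->
    phenotypes and longitudinal series tied to the same causal probes.
    """
    cfg = config
    (
        rng_m,
        rng_cov,
        rng_manifest,
        rng_pheno,
        rng_cells,
        rng_long,
        rng_panel,
        rng_missing,
    ) = _child_rngs(cfg.seed, 8)

    n, p = cfg.n_samples, cfg.n_probes
    probe_ids = pd.Index([f"cg{i:06d}" for i in range(p)], name="probe_id")
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")

    # probe-level mean M: bimodal plus an intermediate component, the
    # hallmark shape of array methylation data
    comp = rng_m.choice(3, size=p, p=[0.4, 0.4, 0.2])
    mu = np.where(
        comp == 0,
        rng_m.normal(-3.0, 0.8, size=p),
        np.where(comp == 1, rng_m.normal(3.0, 0.8, size=p), rng_m.normal(0.0, 1.0, size=p)),
    )

    M = mu[None, :] + _block_ar1_noise(rng_m, n, p, cfg.block_size, cfg.block_rho)
    M += rng_m.normal(0.0, cfg.noise_sd, size=(n, p))

    covariates = _simulate_covariates(rng_cov, n, cfg.n_batches)
    covariates.index = sample_ids

    # batch offsets: per (batch, probe) shifts on the M scale
    batch_shift = rng_cov.normal(0.0, cfg.batch_sd, size=(cfg.n_batches, p))
    M += batch_shift[covariates["batch"].to_numpy()]

    # cell-composition signal: fractions load onto a random subset of probes
    fractions = rng_cells.dirichlet(np.asarray(cfg.dirichlet_alpha), size=n)
    cell_names = list(CELL_TYPE_NAMES[: cfg.n_cell_types]) + [
        f"CT{j}" for j in range(len(CELL_TYPE_NAMES), cfg.n_cell_types)
    ]
    cell_df = pd.DataFrame(fractions, index=sample_ids, columns=cell_names)
    n_cell_probes = min(p // 10, 100)
    cell_probe_idx = rng_cells.choice(p, size=n_cell_probes, replace=False)
    cell_loadings = rng_cells.normal(0.0, 1.0, size=(cfg.n_cell_types, n_cell_probes))
    centered = fractions - fractions.mean(axis=0)
    M[:, cell_probe_idx] += centered @ cell_loadings

    # causal probes (disjoint sets for the two traits)
    all_causal = rng_pheno.choice(
        p, size=cfg.n_causal_baseline + cfg.n_causal_slope, replace=False
    )
    causal_base_idx = np.sort(all_causal[: cfg.n_causal_baseline])
    causal_slope_idx = np.sort(all_causal[cfg.n_causal_baseline :])

    # planted effects: random sign, magnitude bounded away from zero so
    # every causal probe genuinely carries signal of the configured scale
    def _effects(k):
        sign = rng_pheno.choice([-1.0, 1.0], size=k)
        return sign * cfg.effect_size_sd * rng_pheno.uniform(0.5, 1.5, size=k)

    eff_base = _effects(cfg.n_causal_baseline)
    eff_slope = _effects(cfg.n_causal_slope)

    def _std(cols):
        x = M[:, cols]
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return (x - x.mean(axis=0)) / sd

    # baseline eGFR: linear in standardized causal M values + covariates + noise
    base_mean = 90.0
    cov_effect = (
        -0.6 * (covariates["age"] - 60.0)
        - 0.8 * (covariates["hba1c"] - 7.5)
        - 0.5 * (covariates["diabetes_duration"] - 9.0)
        - 0.1 * (covariates["sbp"] - 135.0)
    ).to_numpy()
    signal_base = (
        _std(causal_base_idx) @ eff_base if cfg.n_causal_baseline else np.zeros(n)
    )
    baseline_egfr = base_mean + cov_effect + 5.0 * signal_base + rng_pheno.normal(0.0, 8.0, size=n)
    baseline_egfr = np.clip(baseline_egfr, 8.0, None)

    # random slopes: causal M values shift b1i; re_sd_slope is extra noise
    signal_slope = (
        _std(causal_slope_idx) @ eff_slope if cfg.n_causal_slope else np.zeros(n)
    )
    slope_scale = 0.01  # M-value effects expressed in log-eGFR/year units
    b1 = slope_scale * signal_slope + rng_pheno.normal(0.0, cfg.re_sd_slope, size=n)
    beta0 = float(np.log(base_mean))
    b0 = np.log(baseline_egfr) - beta0
    c = cfg.beta1 + b1

    truth = CohortTruth(
        causal_probes_baseline=probe_ids[causal_base_idx].tolist(),
        causal_probes_slope=probe_ids[causal_slope_idx].tolist(),
        effects_baseline=pd.Series(eff_base, index=probe_ids[causal_base_idx]),
        effects_slope=pd.Series(eff_slope, index=probe_ids[causal_slope_idx]),
        b0=pd.Series(b0, index=sample_ids),
        b1=pd.Series(b1, index=sample_ids),
        log_slope=pd.Series(c, index=sample_ids),
        annual_pct=pd.Series(100.0 * np.expm1(c), index=sample_ids),
        cell_fractions=cell_df,
        batch=covariates["batch"].copy(),
        beta1=cfg.beta1,
        beta0=beta0,
    )

    # expose betas via the logistic map; strictly inside (0, 1)
    beta = np.exp2(M) / (1.0 + np.exp2(M))
    beta = np.clip(beta, 1e-12, 1.0 - 1e-12)
    values = pd.DataFrame(beta, index=sample_ids, columns=probe_ids)

    # sporadic missingness on a few non-causal probes so the missing-value
    # filter has work to do without destroying planted signal
    n_missing = int(round(cfg.frac_missing_probes * p))
    causal_set = set(np.concatenate([causal_base_idx, causal_slope_idx]))
    candidates = np.array([j for j in range(p) if j not in causal_set])
    if n_missing > 0 and len(candidates) > 0:
        miss_probes = rng_missing.choice(
            candidates, size=min(n_missing, len(candidates)), replace=False
        )
        for j in miss_probes:
            i = rng_missing.integers(0, n)
            values.iloc[i, j] = np.nan

    manifest = _make_manifest(
        rng_manifest, cfg, probe_ids, protected_idx=np.concatenate([causal_base_idx, causal_slope_idx])
    )

    phenotypes = covariates.copy()
    phenotypes["baseline_egfr"] = baseline_egfr

    longitudinal = simulate_longitudinal_egfr(cfg, truth, rng_long)
    panel = simulate_reference_panel(cfg, rng_panel)

    matrix = MethylationMatrix(values, scale="beta")
    return SyntheticCohort(
        matrix=matrix,
        manifest=manifest,
        phenotypes=phenotypes,
        longitudinal=longitudinal,
        reference_panel=panel,
        truth=truth,
        config=cfg,
    )


def mixture_samples(
    panel: pd.DataFrame,
    fractions: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observed beta values for samples that are mixtures of panel columns.

    ``fractions`` is samples x cell-types on the simplex; observed sample
    beta = panel @ w + optional Gaussian noise, clipped into [0, 1].
    """
    fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
    if fractions.shape[1] != panel.shape[1]:
        raise ValueError("fraction vectors must match panel cell types")
    obs = fractions @ panel.to_numpy().T
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        obs = obs + rng.normal(0.0, noise_sd, size=obs.shape)
    obs = np.clip(obs, 0.0, 1.0)
    return pd.DataFrame(
        obs, index=[f"mix_{i}" for i in range(obs.shape[0])], columns=panel.index
    )
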