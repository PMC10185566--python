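"""Methylation matrix I/O, probe filtering and scale transforms.

The central container is :class:`MethylationMatrix`, a samples x probes
table of methylation levels tagged with its scale: *beta* values (the
methylated signal fraction, in [0, 1]) or *M* values
(``M = log2(beta / (1 - beta))``, the variance-stabilised logit scale).
Probe metadata lives in a :class:`ProbeManifest`; the quality filters that
whittle an array down to analysable CpGs are applied by
:func:`filter_probes` which also returns an auditable :class:`FilterReport`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "ProbeManifest",
    "FilterReport",
    "Standardizer",
    "read_matrix",
    "write_matrix",
    "filter_probes",
    "beta_to_m",
    "m_to_beta",
    "standardize_features",
]

#: Chromosome names accepted in manifests (hg-style naming).
GENOME_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY", "chrM")

SEX_CHROMOSOMES = frozenset({"chrX", "chrY"})

#: Token used for missing values in TSV interchange.
NA_TOKEN = "NA"


class MatrixParseError(ValueError):
    """Raised when a methylation table cannot be parsed or validated."""


@dataclass
class MethylationMatrix:
    """Samples x probes methylation values with an explicit scale tag.

    Parameters
    ----------
    values
        DataFrame indexed by sample ID with probe IDs as columns. Missing
        measurements are NaN and stay masked; nothing here imputes.
    scale
        Either ``"beta"`` or ``"M"``.
    detection_fail
        Optional boolean DataFrame (same shape) marking measurements whose
        detection p-value exceeded the reliability threshold.
    """

    values: pd.DataFrame
    scale: str = "beta"
    detection_fail: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M"):
            raise ValueError(f"scale must be 'beta' or 'M', got {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise MatrixParseError(f"duplicate sample IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise MatrixParseError(f"duplicate probe IDs: {dups}")
        vals = self.values.to_numpy(dtype=float)
        if self.scale == "beta":
            with np.errstate(invalid="ignore"):
                bad = (vals < 0) | (vals > 1)
            if np.any(bad & ~np.isnan(vals)):
                i, j = np.argwhere(bad & ~np.isnan(vals))[0]
                raise MatrixParseError(
                    "beta values outside [0, 1]: e.g. "
                    f"{vals[i, j]!r} at sample {self.values.index[i]!r}, "
                    f"probe {self.values.columns[j]!r}"
                )
        if self.detection_fail is not None:
            if self.detection_fail.shape != self.values.shape:
                raise MatrixParseError("detection_fail mask shape mismatch")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probes) -> "MethylationMatrix":
        keep = self.values.columns.intersection(pd.Index(probes), sort=False)
        det = self.detection_fail[keep] if self.detection_fail is not None else None
        return MethylationMatrix(self.values[keep], self.scale, det)


@dataclass
class ProbeManifest:
    """Per-probe genomic annotation driving filtering and enrichment.

    ``table`` is indexed by probe ID with columns ``chromosome`` (hg-style
    names), ``position`` (1-based), ``context`` (``CpG``/``non-CpG``),
    ``snp_overlap`` (bool) and ``genes`` (list of ``(gene_id, region)``
    tuples; region labels follow array annotation conventions such as
    TSS1500, TSS200, gene body, 5'UTR, 3'UTR).
    """

    table: pd.DataFrame

    REQUIRED = ("chromosome", "position", "context", "snp_overlap", "genes")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate probe IDs in manifest")
        if (self.table["position"] < 1).any():
            bad = self.table.index[self.table["position"] < 1].tolist()
            raise ValueError(f"positions must be >= 1; offending probes: {bad}")
        unknown = set(self.table["chromosome"]) - set(GENOME_CHROMOSOMES)
        if unknown:
            raise ValueError(f"chromosomes not in genome dictionary: {sorted(unknown)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class FilterReport:
    """Counts of probes removed by each quality rule, in application order.

    A probe is attributed to the *first* rule that removes it, so the rule
    counts are disjoint and ``retained_probes + sum(removals) == input``.
    """

    input_probes: int
    input_samples: int
    removed_snp_overlap: int = 0
    removed_unreliable_probes: int = 0
    removed_unreliable_samples: int = 0
    removed_non_cpg: int = 0
    removed_sex_chromosome: int = 0
    removed_missing: int = 0
    retained_probes: int = 0
    retained_samples: int = 0

    def probe_removals(self) -> tuple[int, int, int, int, int]:
        return (
            self.removed_snp_overlap,
            self.removed_unreliable_probes,
            self.removed_non_cpg,
            self.removed_sex_chromosome,
            self.removed_missing,
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_matrix(path, scale: str = "beta") -> MethylationMatrix:
    """Read a probes x samples TSV into a samples x probes matrix.

    The interchange layout is probes as rows (probe IDs in the first
    column) and samples as columns; it is transposed on the way in. The
    missing-value token is ``NA``; missing cells become NaN, never zero.
    """
    try:
        table = pd.read_csv(
            path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise MatrixParseError(f"cannot parse {path}: {exc}") from exc
    for col in table.columns:
        coerced = pd.to_numeric(table[col], errors="coerce")
        newly_bad = coerced.isna() & table[col].notna()
        if newly_bad.any():
            row = table.index[newly_bad.to_numpy().argmax()]
            raise MatrixParseError(
                f"non-numeric cell at probe {row!r}, sample {col!r}: "
                f"{table.loc[row, col]!r}"
            )
        table[col] = coerced
    return MethylationMatrix(table.T, scale=scale)


def write_matrix(matrix: MethylationMatrix, path) -> None:
    """Write a matrix as probes x samples TSV (inverse of :func:`read_matrix`)."""
    matrix.values.T.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def filter_probes(
    matrix: MethylationMatrix,
    manifest: ProbeManifest,
    detection_p_threshold: float = 0.05,
    unreliable_fraction_threshold: float = 0.05,
) -> tuple[MethylationMatrix, FilterReport]:
    """Apply array quality filters in a fixed order and report removals.

    Rules, in order (a probe is charged to the first rule that hits it):

    1. probes overlapping a SNP;
    2. probes, then samples, whose fraction of detection failures (from
       the matrix's ``detection_fail`` mask, already thresholded at the
       detection p cut-off) exceeds ``unreliable_fraction_threshold``;
    3. probes in non-CpG context;
    4. probes on the sex chromosomes;
    5. probes with any missing value in any retained sample.

    ``detection_p_threshold`` is documentation of the mask semantics; the
    mask itself is boolean and assumed to encode failures at that cut-off.
    """
    missing_in_manifest = matrix.probe_ids.difference(manifest.probe_ids)
    if len(missing_in_manifest) > 0:
        raise ValueError(
            f"manifest does not cover probes: {missing_in_manifest.tolist()}"
        )
    meta = manifest.table.loc[matrix.probe_ids]
    report = FilterReport(input_probes=matrix.n_probes, input_samples=matrix.n_samples)

    removed = pd.Series(False, index=matrix.probe_ids)

    snp = meta["snp_overlap"].astype(bool) & ~removed
    report.removed_snp_overlap = int(snp.sum())
    removed |= snp

    samples_keep = pd.Series(True, index=matrix.sample_ids)
    if matrix.detection_fail is not None:
        fail = matrix.detection_fail.astype(bool)
        probe_frac = fail.mean(axis=0)
        unreliable = (probe_frac > unreliable_fraction_threshold) & ~removed
        report.removed_unreliable_probes = int(unreliable.sum())
        removed |= unreliable
        # sample pass computed on probes surviving so far
        kept_cols = matrix.probe_ids[~removed]
        if len(kept_cols) > 0:
            sample_frac = fail[kept_cols].mean(axis=1)
            samples_keep = sample_frac <= unreliable_fraction_threshold
        report.removed_unreliable_samples = int((~samples_keep).sum())

    non_cpg = (meta["context"] != "CpG") & ~removed
    report.removed_non_cpg = int(non_cpg.sum())
    removed |= non_cpg

    sex = meta["chromosome"].isin(SEX_CHROMOSOMES) & ~removed
    report.removed_sex_chromosome = int(sex.sum())
    removed |= sex

    kept_samples = matrix.sample_ids[samples_keep]
    has_missing = matrix.values.loc[kept_samples].isna().any(axis=0) & ~removed
    report.removed_missing = int(has_missing.sum())
    removed |= has_missing

    kept_probes = matrix.probe_ids[~removed]
    report.retained_probes = len(kept_probes)
    report.retained_samples = len(kept_samples)

    det = None
    if matrix.detection_fail is not None:
        det = matrix.detection_fail.loc[kept_samples, kept_probes]
    out = MethylationMatrix(
        matrix.values.loc[kept_samples, kept_probes], matrix.scale, det
    )
    return out, report


DEFAULT_BETA_CLIP = 1e-6


def beta_to_m(
    matrix: MethylationMatrix, clip: float | None = DEFAULT_BETA_CLIP
) -> MethylationMatrix:
    """Transform beta values to M values, ``M = log2(beta / (1 - beta))``.

    Boundary betas (exactly 0 or 1) have infinite M; with ``clip`` set
    (default 1e-6) betas are clipped into ``[clip, 1 - clip]`` first, and
    with ``clip=None`` boundary values raise instead.
    """
    if matrix.scale != "beta":
        raise ValueError("beta_to_m requires a beta-scale matrix")
    vals = matrix.values.to_numpy(dtype=float)
    if clip is None:
        if np.any((vals == 0) | (vals == 1)):
            raise ValueError("beta values at 0 or 1; enable clipping to transform")
        clipped = vals
    else:
        clipped = np.clip(vals, clip, 1.0 - clip)
    m = np.log2(clipped / (1.0 - clipped))
    out = pd.DataFrame(m, index=matrix.sample_ids, columns=matrix.probe_ids)
    return MethylationMatrix(out, scale="M", detection_fail=matrix.detection_fail)


def m_to_beta(matrix: MethylationMatrix) -> MethylationMatrix:
    """Inverse of :func:`beta_to_m`: ``beta = 2^M / (2^M + 1)``."""
    if matrix.scale != "M":
        raise ValueError("m_to_beta requires an M-scale matrix")
    m = matrix.values.to_numpy(dtype=float)
    # logistic in base 2, computed stably for large |M|
    beta = np.where(m >= 0, 1.0 / (1.0 + np.exp2(-m)), np.exp2(m) / (1.0 + np.exp2(m)))
    out = pd.DataFrame(beta, index=matrix.sample_ids, columns=matrix.probe_ids)
    return MethylationMatrix(out, scale="beta", detection_fail=matrix.detection_fail)


@dataclass
class Standardizer:
    """Column-wise zero-mean unit-variance transform with stored parameters.

    The variance denominator is the sample convention (``ddof=1``); the
    choice is recorded in :attr:`ddof` so downstream consumers can tell.
    Fitted parameters are reused to transform new samples (e.g. a held-out
    test set or an external cohort) on the training scale.
    """

    means: pd.Series = field(default_factory=pd.Series)
    sds: pd.Series = field(default_factory=pd.Series)
    ddof: int = 1

    def fit(self, table: pd.DataFrame) -> "Standardizer":
        sds = table.std(ddof=self.ddof)
        zero = sds.index[(sds == 0) | sds.isna()]
        if len(zero) > 0:
            raise ValueError(f"zero-variance columns cannot be standardized: {zero.tolist()}")
        self.means = table.mean()
        self.sds = sds
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in table.columns if c not in self.means.index]
        if missing:
            raise ValueError(f"columns not seen at fit time: {missing}")
        return (table - self.means[table.columns]) / self.sds[table.columns]

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)


def standardize_features(table: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Standardize every column to mean 0, variance 1 (ddof=1).

    Returns the transformed copy and the fitted :class:`Standardizer` so
    the same location/scale can be applied to new samples.
    """
    scaler = Standardizer()
    return scaler.fit_transform(table), scaler
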