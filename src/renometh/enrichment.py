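"""Functional enrichment of selected CpG sites via proximal genes.

CpGs chosen by the single-site or multisite analyses are linked to genes
whose intervals lie within a window (default 1 kb) of the probe position.
Enrichment of prior functional support (methylation, expression, eQTL,
marker-gene or GWAS evidence) among the linked genes is tested two ways:
an exact upper-tail hypergeometric test against a background gene list,
and an empirical null built by resampling equally sized random gene sets
from the CpG-proximal gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ProbeManifest

__all__ = [
    "GeneAnnotation",
    "EnrichmentResult",
    "read_bed_annotation",
    "map_probes_to_genes",
    "support_fraction",
    "hypergeometric_enrichment",
    "resampling_null",
]

SUPPORT_CATEGORIES = ("methylation", "expression", "eqtl", "marker_gene", "gwas")


@dataclass
class GeneAnnotation:
    """Gene intervals plus per-gene evidence flags.

    ``table`` is indexed by gene ID with columns ``chromosome``, ``start``,
    ``end`` (1-based inclusive internally) and boolean support columns
    (any subset of methylation/expression/eqtl/marker_gene/gwas).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("chromosome", "start", "end"):
            if col not in self.table.columns:
                raise ValueError(f"annotation missing column {col!r}")
        if (self.table["start"] > self.table["end"]).any():
            bad = self.table.index[self.table["start"] > self.table["end"]].tolist()
            raise ValueError(f"start > end for genes: {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def supported(self, categories=None) -> pd.Series:
        """Boolean per gene: flagged in at least one evidence category."""
        cols = [c for c in (categories or SUPPORT_CATEGORIES) if c in self.table.columns]
        if not cols:
            return pd.Series(False, index=self.table.index)
        return self.table[cols].astype(bool).any(axis=1)


def read_bed_annotation(path, flags: pd.DataFrame | None = None) -> GeneAnnotation:
    """Read gene intervals from BED (0-based half-open) with optional flags.

    This reader is the only place the coordinate convention changes:
    BED's 0-based half-open ``[start, end)`` becomes the internal 1-based
    inclusive ``[start+1, end]``.
    """
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chromosome", "start0", "end0", "gene_id"],
    )
    table = pd.DataFrame(
        {
            "chromosome": bed["chromosome"].to_numpy(),
            "start": bed["start0"].to_numpy(dtype=int) + 1,
            "end": bed["end0"].to_numpy(dtype=int),
        },
        index=pd.Index(bed["gene_id"].to_numpy(), name="gene_id"),
    )
    if flags is not None:
        table = table.join(flags.astype(bool), how="left").fillna(False)
    return GeneAnnotation(table)


def map_probes_to_genes(
    probes,
    manifest: ProbeManifest,
    annotation: GeneAnnotation,
    window: int = 1000,
) -> pd.DataFrame:
    """Link each probe to every gene within ``window`` bp of its position.

    Distance is from the probe's single-base position to the nearest
    point of the gene interval (zero if the probe falls inside). Probes
    whose chromosome has no annotated gene are reported with a null gene
    link rather than dropped, so unmapped queries stay visible. Rows are
    ordered by probe then gene ID.
    """
    probes = list(probes)
    missing = [p for p in probes if p not in manifest.probe_ids]
    if missing:
        raise ValueError(f"manifest does not cover probes: {missing}")
    meta = manifest.table.loc[probes]
    genes = annotation.table
    rows = []
    by_chrom = {c: g for c, g in genes.groupby("chromosome")}
    for pid, chrom, pos in zip(probes, meta["chromosome"], meta["position"]):
        cand = by_chrom.get(chrom)
        if cand is None:
            rows.append((pid, None, np.nan))
            continue
        start = cand["start"].to_numpy()
        end = cand["end"].to_numpy()
        dist = np.where(
            pos < start, start - pos, np.where(pos > end, pos - end, 0)
        ).astype(float)
        hit = dist <= window
        if not hit.any():
            rows.append((pid, None, np.nan))
            continue
        for gid, d in sorted(zip(cand.index[hit], dist[hit]), key=lambda t: str(t[0])):
            rows.append((pid, gid, float(d)))
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "distance"])


def support_fraction(
    links: pd.DataFrame, annotation: GeneAnnotation, categories=None
) -> dict:
    """Fractions of query sites and genes carrying functional support.

    A site counts as supported if at least one of its linked genes is
    flagged in at least one evidence category; the gene-level fraction
    counts the distinct linked genes directly. Unlinked probes are
    excluded from the site denominator.
    """
    supported = annotation.supported(categories)
    linked = links.dropna(subset=["gene_id"])
    site_support = linked.groupby("probe_id")["gene_id"].apply(
        lambda gids: bool(supported.reindex(gids).fillna(False).any())
    )
    gene_ids = pd.Index(pd.unique(linked["gene_id"]))
    gene_flags = supported.reindex(gene_ids).fillna(False)
    return {
        "n_sites": int(len(site_support)),
        "n_sites_supported": int(site_support.sum()),
        "site_fraction": float(site_support.mean()) if len(site_support) else np.nan,
        "n_genes": int(len(gene_ids)),
        "n_genes_supported": int(gene_flags.sum()),
        "gene_fraction": float(gene_flags.mean()) if len(gene_ids) else np.nan,
    }


@dataclass
class EnrichmentResult:
    """Outcome of an enrichment test on a query gene set."""

    n_query: int
    n_supported: int
    fraction: float
    fold_enrichment: float
    p_hypergeometric: float
    p_resampling: float = np.nan
    n_resamples: int = 0


def hypergeometric_enrichment(
    query_genes,
    supported: pd.Series,
    background_genes=None,
) -> EnrichmentResult:
    """Exact upper-tail hypergeometric test for support enrichment.

    ``supported`` is a boolean Series over the background (all genes);
    the p-value is the probability of drawing at least the observed
    number of supported genes in a random query-sized draw.
    """
    if background_genes is None:
        background = supported.index
    else:
        background = pd.Index(background_genes)
    query = pd.Index(query_genes)
    if len(query) == 0:
        raise ValueError("empty query gene set")
    stray = query.difference(background)
    if len(stray) > 0:
        raise ValueError(f"query genes outside background: {stray.tolist()}")
    flags = supported.reindex(background).fillna(False).astype(bool)
    M = int(len(background))
    K = int(flags.sum())
    N = int(len(query))
    k = int(flags.loc[query].sum())
    p = float(stats.hypergeom.sf(k - 1, M, K, N))
    bg_frac = K / M if M else np.nan
    frac = k / N
    fold = frac / bg_frac if bg_frac > 0 else np.inf
    return EnrichmentResult(
        n_query=N,
        n_supported=k,
        fraction=frac,
        fold_enrichment=float(fold),
        p_hypergeometric=p,
    )


def resampling_null(
    query_size: int,
    observed_supported: int,
    supported: pd.Series,
    universe=None,
    n_reps: int = 10_000,
    seed: int = 0,
) -> dict:
    """Size-matched resampling null from the CpG-proximal gene universe.

    Draws ``n_reps`` random gene sets of ``query_size`` (without
    replacement within a draw) from ``universe`` (default: the index of
    ``supported``) and counts how many achieve at least the observed
    support. The empirical p uses the add-one correction
    ``(1 + #{null >= obs}) / (n_reps + 1)`` so it is never zero.
    """
    uni = pd.Index(universe) if universe is not None else supported.index
    if query_size > len(uni):
        raise ValueError("universe smaller than query size")
    flags = supported.reindex(uni).fillna(False).astype(bool).to_numpy()
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps, dtype=np.int64)
    n_uni = len(uni)
    for r in range(n_reps):
        pick = rng.choice(n_uni, size=query_size, replace=False)
        null[r] = int(flags[pick].sum())
    p = (1 + int((null >= observed_supported).sum())) / (n_reps + 1)
    return {
        "p_empirical": float(p),
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if n_reps > 1 else np.nan,
        "null_counts": null,
        "n_reps": int(n_reps),
    }
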