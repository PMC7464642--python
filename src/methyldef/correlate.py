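"""Secondary correlation analyses around the gene-body methylation factor.

Covers: pairing CpG islands to the gene bodies they belong to (inside the
gene body or in a promoter window upstream of it), cross-sample
correlation of paired gene-body and island methylation, the coefficient of
variation of gene-body betas as a function of mean methylation,
CPM-filtered log-expression, per-gene methylation-expression correlation
grouped by methylation slot, and the factor-versus-expression screen with
Benjamini-Hochberg control that produces the positively / negatively
correlated gene lists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import RegionBetaMatrix, RegionSet, beta_to_decile


@dataclass
class GbCgiPairing:
    gene_id: str
    gb_region_id: str
    cgi_region_id: str
    relation: str  # "inside_gb" or "promoter_window"


def pair_gb_cgi(
    gbs: RegionSet, cgis: RegionSet, promoter_window: int = 2000
) -> list[GbCgiPairing]:
    """Pair each CpG island with the gene bodies it plausibly regulates.

    A CGI pairs with a gene if it overlaps the gene body (relation
    ``inside_gb``) or overlaps the ``promoter_window`` bases immediately
    upstream (lower coordinates; strand is ignored) of the gene-body start
    (relation ``promoter_window``).  One CGI may pair with several genes.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in cgis.data.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"], sub["region_id"])
        )
    pairs: list[GbCgiPairing] = []
    for gb in gbs.data.itertuples(index=False):
        tree = trees.get(gb.chrom)
        if tree is None:
            continue
        inside = {iv.data for iv in tree.overlap(gb.start, gb.end)}
        win_lo = max(0, gb.start - promoter_window)
        upstream = (
            {iv.data for iv in tree.overlap(win_lo, gb.start)} if gb.start > win_lo else set()
        )
        for cgi_id in sorted(inside):
            pairs.append(GbCgiPairing(gb.gene_id, gb.region_id, cgi_id, "inside_gb"))
        for cgi_id in sorted(upstream - inside):
            pairs.append(GbCgiPairing(gb.gene_id, gb.region_id, cgi_id, "promoter_window"))
    return pairs


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def gb_cgi_correlation(
    gb_betas: RegionBetaMatrix,
    cgi_betas: RegionBetaMatrix,
    pairs: list[GbCgiPairing],
    r_threshold: float = 0.8,
    min_n: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Cross-sample Pearson correlation per gene-body / CGI pair.

    Returns a per-pair record table and a summary with the fraction of
    evaluable pairs whose r exceeds ``r_threshold`` (the headline
    "fraction of highly correlated GB-CGI combinations").
    """
    rows = []
    n_insufficient = 0
    n_constant = 0
    common = gb_betas.samples.intersection(cgi_betas.samples)
    for pair in pairs:
        if pair.gb_region_id not in gb_betas.regions or pair.cgi_region_id not in cgi_betas.regions:
            n_insufficient += 1
            continue
        x = gb_betas.avg_beta.loc[common, pair.gb_region_id].to_numpy(float)
        y = cgi_betas.avg_beta.loc[common, pair.cgi_region_id].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_n:
            n_insufficient += 1
            continue
        xs, ys = x[ok], y[ok]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            n_constant += 1
            continue
        r, p = _pearson_with_p(xs, ys)
        rows.append((pair.gb_region_id, pair.cgi_region_id, pair.relation, r, int(ok.sum()), p))
    records = pd.DataFrame(
        rows, columns=["gb_region_id", "cgi_region_id", "relation", "r", "n", "p_value"]
    )
    n_eval = len(records)
    frac = float((records["r"] > r_threshold).mean()) if n_eval else float("nan")
    summary = {
        "n_pairs": len(pairs),
        "n_evaluated": n_eval,
        "n_insufficient": n_insufficient,
        "n_constant": n_constant,
        "r_threshold": r_threshold,
        "fraction_above_threshold": frac,
    }
    return records, summary


def cv_by_mean_slot(betas: RegionBetaMatrix, min_n: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coefficient of variation (%) of each gene's betas vs its mean level.

    CV% = 100 * sd / mean across samples per region; regions are grouped by
    the decile slot of their mean beta and the per-slot CV distribution is
    summarised by its median.  Regions with mean 0 are reported with NaN CV.
    """
    rows = []
    for region_id in betas.regions:
        col = betas.avg_beta[region_id].to_numpy(float)
        col = col[~np.isnan(col)]
        if col.size < min_n:
            continue
        m = float(col.mean())
        sd = float(col.std(ddof=1))
        cv = 100.0 * sd / m if m > 0 else float("nan")
        slot = int(beta_to_decile(np.array([m]))[0])
        rows.append((region_id, m, cv, slot, col.size))
    per_gene = pd.DataFrame(rows, columns=["region_id", "mean_beta", "cv_percent", "slot", "n"])
    per_slot = (
        per_gene.dropna(subset=["cv_percent"])
        .groupby("slot")["cv_percent"]
        .median()
        .rename("median_cv_percent")
        .reset_index()
    )
    return per_gene, per_slot


def filter_normalize_expression(
    counts: pd.DataFrame,
    cpm_threshold: float = 0.5,
    min_sample_fraction: float = 0.5,
    prior: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """CPM-filter raw counts (genes x samples) and return log2(CPM + prior).

    A gene is retained iff its counts-per-million exceed ``cpm_threshold``
    in at least ceil(min_sample_fraction * n_samples) samples.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    cpm = counts.div(lib, axis=1) * 1e6
    need = math.ceil(min_sample_fraction * counts.shape[1])
    keep = (cpm > cpm_threshold).sum(axis=1) >= need
    if not keep.any():
        raise ValueError("all genes removed by the CPM filter")
    logcpm = np.log2(cpm.loc[keep] + prior)
    meta = {
        "normalization": f"log2(CPM + {prior})",
        "cpm_threshold": cpm_threshold,
        "min_samples": need,
        "n_genes_in": int(counts.shape[0]),
        "n_genes_kept": int(keep.sum()),
    }
    return logcpm, meta


def gb_expression_correlation(
    betas: RegionBetaMatrix,
    expr: pd.DataFrame,
    gene_lengths: pd.Series | None = None,
    min_n: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-gene methylation-expression correlation grouped by slot.

    ``expr`` is a normalised genes x samples matrix whose index shares gene
    ids with the beta matrix (via its region->gene mapping).  Returns the
    per-gene records, a per-slot summary (median r, median expression,
    median gene length) and the exclusion counts.
    """
    common_samples = betas.samples.intersection(expr.columns)
    gene_of = betas.region_gene
    rows = []
    n_missing = 0
    n_insufficient = 0
    for region_id in betas.regions:
        gene = gene_of.get(region_id, region_id)
        if gene not in expr.index:
            n_missing += 1
            continue
        x = betas.avg_beta.loc[common_samples, region_id].to_numpy(float)
        y = expr.loc[gene, common_samples].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_n or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            n_insufficient += 1
            continue
        r, p = _pearson_with_p(x[ok], y[ok])
        mean_beta = float(np.nanmean(x))
        slot = int(beta_to_decile(np.array([mean_beta]))[0])
        length = float(gene_lengths.get(gene, np.nan)) if gene_lengths is not None else np.nan
        rows.append((gene, r, int(ok.sum()), p, mean_beta, slot, float(np.nanmedian(y)), length))
    per_gene = pd.DataFrame(
        rows,
        columns=["gene_id", "r", "n", "p_value", "mean_beta", "slot", "median_log_expr", "gene_length"],
    )
    per_slot = (
        per_gene.groupby("slot")
        .agg(
            median_r=("r", "median"),
            median_log_expr=("median_log_expr", "median"),
            median_gene_length=("gene_length", "median"),
            n_genes=("gene_id", "size"),
        )
        .reset_index()
    )
    counts = {"n_missing_expression": n_missing, "n_insufficient": n_insufficient}
    return per_gene, per_slot, counts


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (statsmodels fdr_bh)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def mdf_expression_correlation(
    mdf: pd.Series,
    expr: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    min_samples: int = 10,
) -> tuple[pd.DataFrame, list, list, dict]:
    """Screen genes whose expression tracks the per-sample MDF/MUMF.

    Pearson r and p per gene across samples, BH adjustment over all tested
    genes, and gene lists split by correlation sign at q < ``fdr_cutoff``.
    """
    common = mdf.index.intersection(expr.columns)
    if len(common) < min_samples:
        raise ValueError(f"need at least {min_samples} shared samples")
    v = mdf.loc[common].to_numpy(float)
    if not np.all(np.isfinite(v)):
        warnings.warn("non-finite factor values excluded from the correlation", stacklevel=2)
        finite = np.isfinite(v)
        common = common[finite]
        v = v[finite]
        if len(common) < min_samples:
            raise ValueError("too few samples with finite factor values")
    if np.ptp(v) == 0:
        raise ValueError("constant factor vector")
    M = expr[common].to_numpy(float)
    n = len(common)
    n_excluded = int((M.std(axis=1) == 0).sum())
    keep = M.std(axis=1) > 0
    genes = expr.index[keep]
    M = M[keep]
    # vectorised Pearson r with t-based two-sided p
    vm = v - v.mean()
    Mm = M - M.mean(axis=1, keepdims=True)
    r = (Mm @ vm) / (np.sqrt((Mm**2).sum(axis=1)) * np.sqrt((vm**2).sum()))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(p), 0.0, p)  # |r| == 1 -> p ~ 0
    q = bh_adjust(p)
    records = pd.DataFrame({"gene_id": genes, "r": r, "n": n, "p_value": p, "fdr_q": q})
    sig = records["fdr_q"] < fdr_cutoff
    positive = records.loc[sig & (records["r"] > 0), "gene_id"].tolist()
    negative = records.loc[sig & (records["r"] < 0), "gene_id"].tolist()
    summary = {
        "n_tested": int(len(records)),
        "n_excluded_constant": n_excluded,
        "n_positive": len(positive),
        "n_negative": len(negative),
        "n_nonsignificant": int(len(records) - len(positive) - len(negative)),
        "fdr_cutoff": fdr_cutoff,
    }
    return records, positive, negative, summary
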