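"""Region-level aggregation of per-CpG methylation calls.

Turns per-CpG beta values (counts from bisulfite sequencing or array betas)
into one depth-weighted average beta per region (gene body, exon, intron or
CpG island) per sample, bins the averages into ten methylation deciles, and
trichotomises genes into unmethylated / undefined / methylated classes.

Conventions
-----------
* Coordinates are BED-style 0-based half-open; strand is ignored (CpG
  methylation is treated as strand-collapsed).
* A CpG at position p belongs to region [start, end) iff start <= p < end;
  a CpG overlapping several regions contributes to each independently.
* The weighted average uses w = log10(depth + 0.1); calls require
  depth >= 1 so weights are strictly positive.
* A region/sample average is reported only when at least ``min_cpgs``
  (default 11) called CpGs map into the region.
* Decile d covers [(d-1)/10, d/10) for d = 1..9; decile 10 is closed at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

REGION_KINDS = ("gene_body", "exon", "intron", "cgi")

DEFAULT_MIN_CPGS = 11

#: slot labels used by the trichotomisation
SLOT_UNMETH = "unmethylated"
SLOT_UNDEF = "undefined"
SLOT_METH = "methylated"


@dataclass
class CpGCallTable:
    """Per-CpG methylation evidence for one sample.

    ``data`` holds columns ``chrom`` (str), ``pos`` (0-based int),
    ``beta`` (float in [0,1]) and ``depth`` (int >= 1; NaN in array mode).
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self):
        required = {"chrom", "pos", "beta"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CpGCallTable missing columns: {sorted(missing)}")
        if "depth" not in self.data.columns:
            self.data = self.data.assign(depth=np.nan)
        b = self.data["beta"].to_numpy(float)
        if np.any((b < 0) | (b > 1)):
            raise ValueError("beta values must lie in [0, 1]")
        d = self.data["depth"].to_numpy(float)
        if np.any(d[~np.isnan(d)] < 1):
            raise ValueError("calling depth must be >= 1")
        if self.data.duplicated(["chrom", "pos"]).any():
            raise ValueError(f"duplicate (chrom, pos) in sample {self.sample_id}")

    @property
    def has_depth(self) -> bool:
        return bool(self.data["depth"].notna().all()) and len(self.data) > 0


@dataclass
class RegionSet:
    """Genomic regions with ids, owning genes and a kind.

    ``data`` holds ``region_id``, ``gene_id``, ``chrom``, ``start``, ``end``,
    ``kind`` with 0-based half-open coordinates.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"region_id", "gene_id", "chrom", "start", "end", "kind"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"RegionSet missing columns: {sorted(missing)}")
        if (self.data["start"] >= self.data["end"]).any():
            raise ValueError("regions must satisfy start < end")
        if self.data["region_id"].duplicated().any():
            dup = self.data.loc[self.data["region_id"].duplicated(), "region_id"]
            raise ValueError(f"duplicate region_id(s): {sorted(set(dup))[:5]}")
        bad = set(self.data["kind"]) - set(REGION_KINDS)
        if bad:
            raise ValueError(f"unknown region kind(s): {sorted(bad)}")

    def subset(self, kinds: Iterable[str]) -> "RegionSet":
        kinds = set(kinds)
        return RegionSet(self.data[self.data["kind"].isin(kinds)].reset_index(drop=True))

    @property
    def region_ids(self) -> pd.Index:
        return pd.Index(self.data["region_id"])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class RegionBetaMatrix:
    """Samples x regions weighted-average betas with per-cell CpG counts.

    ``avg_beta`` is NaN exactly where fewer than ``min_cpgs`` CpGs were
    available; ``n_cpg`` always records the number of assigned called CpGs.
    """

    avg_beta: pd.DataFrame
    n_cpg: pd.DataFrame
    min_cpgs: int = DEFAULT_MIN_CPGS
    weighted: bool = True
    region_gene: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self):
        if not self.avg_beta.index.equals(self.n_cpg.index) or not self.avg_beta.columns.equals(
            self.n_cpg.columns
        ):
            raise ValueError("avg_beta and n_cpg must share index/columns")

    @property
    def samples(self) -> pd.Index:
        return self.avg_beta.index

    @property
    def regions(self) -> pd.Index:
        return self.avg_beta.columns


@dataclass
class GeneMethylationClass:
    gene_id: str
    mean_beta: float
    slot: str
    modal_slot: str
    consistency_fraction: float


def _region_trees(regions: RegionSet) -> Mapping[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in regions.data.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"], sub["region_id"])
        )
    return trees


def map_cpgs_to_regions(calls: CpGCallTable, regions: RegionSet) -> pd.DataFrame:
    """Assign each CpG to every region whose interval contains it.

    Returns a long DataFrame with columns ``chrom, pos, region_id`` (one row
    per assignment).  CpGs on chromosomes absent from the region set raise a
    warning and are left unassigned.
    """
    trees = _region_trees(regions)
    out_chrom: list = []
    out_pos: list = []
    out_region: list = []
    missing_chroms = []
    for chrom, sub in calls.data.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            missing_chroms.append(chrom)
            continue
        for pos in sub["pos"].to_numpy():
            for iv in tree.at(int(pos)):
                out_chrom.append(chrom)
                out_pos.append(int(pos))
                out_region.append(iv.data)
    if missing_chroms:
        warnings.warn(
            f"chromosome(s) {missing_chroms} present in calls but absent from "
            f"regions; their CpGs are unassigned",
            stacklevel=2,
        )
    return pd.DataFrame({"chrom": out_chrom, "pos": out_pos, "region_id": out_region})


def cpg_weights(depth: np.ndarray) -> np.ndarray:
    """Depth weight w = log10(depth + 0.1); positive for depth >= 1."""
    return np.log10(np.asarray(depth, dtype=float) + 0.1)


def average_region_beta(
    calls: Sequence[CpGCallTable],
    regions: RegionSet,
    weighted: bool = True,
    min_cpgs: int = DEFAULT_MIN_CPGS,
) -> RegionBetaMatrix:
    """Depth-weighted average beta per region per sample.

    avg_beta(r) = sum_i w_i * beta_i / sum_i w_i over the CpGs assigned to
    region r, with w_i = log10(depth_i + 0.1) when ``weighted`` (bisulfite
    counts mode) and w_i = 1 otherwise (array mode).  Cells with fewer than
    ``min_cpgs`` assigned CpGs are NaN.
    """
    if weighted and not all(c.has_depth for c in calls):
        raise ValueError("weighted averaging requires a depth for every call")
    trees = _region_trees(regions)
    region_ids = regions.region_ids
    sample_ids = [c.sample_id for c in calls]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id among call tables")
    avg = pd.DataFrame(np.nan, index=sample_ids, columns=region_ids)
    ncpg = pd.DataFrame(0, index=sample_ids, columns=region_ids, dtype=int)

    # cache assignments per unique (chrom, pos): samples largely share loci
    assign_cache: dict[tuple, tuple] = {}
    for table in calls:
        df = table.data
        chroms = df["chrom"].to_numpy()
        poss = df["pos"].to_numpy()
        betas = df["beta"].to_numpy(float)
        w = cpg_weights(df["depth"].to_numpy()) if weighted else np.ones(len(df))
        rid_list: list = []
        wb_list: list = []
        w_list: list = []
        for chrom, pos, b, wi in zip(chroms, poss, betas, w):
            key = (chrom, pos)
            hit = assign_cache.get(key)
            if hit is None:
                tree = trees.get(chrom)
                hit = tuple(iv.data for iv in tree.at(int(pos))) if tree is not None else ()
                assign_cache[key] = hit
            for rid in hit:
                rid_list.append(rid)
                wb_list.append(wi * b)
                w_list.append(wi)
        if not rid_list:
            continue
        g = pd.DataFrame({"region_id": rid_list, "wb": wb_list, "w": w_list}).groupby(
            "region_id", sort=False
        )
        sums = g.sum()
        counts = g.size()
        ncpg.loc[table.sample_id, counts.index] = counts
        ok = counts[counts >= min_cpgs].index
        avg.loc[table.sample_id, ok] = (sums.loc[ok, "wb"] / sums.loc[ok, "w"]).to_numpy()

    gene_map = regions.data.set_index("region_id")["gene_id"]
    return RegionBetaMatrix(avg, ncpg, min_cpgs=min_cpgs, weighted=weighted, region_gene=gene_map)


def beta_matrix_from_values(
    values: pd.DataFrame, min_cpgs: int = DEFAULT_MIN_CPGS
) -> RegionBetaMatrix:
    """Wrap an array-style precomputed beta matrix (samples x regions).

    Cells are kept only where the value is present; ``n_cpg`` is set to
    ``min_cpgs`` for present cells so the presence invariant holds.
    """
    present = values.notna()
    ncpg = present.astype(int) * min_cpgs
    gene_map = pd.Series(values.columns, index=values.columns)
    return RegionBetaMatrix(values.copy(), ncpg, min_cpgs=min_cpgs, weighted=False, region_gene=gene_map)


def beta_to_decile(beta) -> np.ndarray:
    """Map beta in [0,1] to decile 1..10 ([l,u) bins, top bin closed)."""
    b = np.asarray(beta, dtype=float)
    d = np.floor(b * 10).astype(float)
    d = np.minimum(d, 9)
    d[np.isnan(b)] = np.nan
    return d + 1


def count_decile_membership(betas: RegionBetaMatrix) -> pd.DataFrame:
    """Per-sample counts of regions per methylation decile.

    Returns a DataFrame indexed by sample with columns ``decile_1`` ..
    ``decile_10``; each row sums to the sample's non-missing region count.
    """
    cols = [f"decile_{d}" for d in range(1, 11)]
    out = pd.DataFrame(0, index=betas.samples, columns=cols, dtype=int)
    vals = betas.avg_beta.to_numpy(float)
    dec = beta_to_decile(vals)
    for i in range(vals.shape[0]):
        row = dec[i]
        row = row[~np.isnan(row)].astype(int)
        binc = np.bincount(row, minlength=11)[1:11]
        out.iloc[i] = binc
    return out


def _slot_of(beta: np.ndarray, low: float, high: float) -> np.ndarray:
    out = np.where(beta < low, SLOT_UNMETH, np.where(beta > high, SLOT_METH, SLOT_UNDEF))
    return out


def classify_genes(
    betas: RegionBetaMatrix,
    low: float = 0.3,
    high: float = 0.7,
    consistency_min: float = 0.9,
) -> tuple[list[GeneMethylationClass], dict[str, list[str]], list[str]]:
    """Trichotomise genes by mean gene-body beta and score consistency.

    A gene's ``slot`` comes from the across-sample mean of its average beta
    (< ``low`` unmethylated, > ``high`` methylated, else undefined); its
    ``consistency_fraction`` is the fraction of samples whose per-sample
    beta falls in the gene's modal per-sample slot.  A gene enters the
    consistent list of its modal slot iff that fraction exceeds
    ``consistency_min``.

    Returns ``(classes, consistent_lists, excluded)`` where
    ``consistent_lists`` maps slot name to gene ids and ``excluded`` lists
    genes with no non-missing sample.
    """
    if not (0 < low < high < 1):
        raise ValueError("need 0 < low < high < 1")
    classes: list[GeneMethylationClass] = []
    consistent: dict[str, list[str]] = {SLOT_UNMETH: [], SLOT_UNDEF: [], SLOT_METH: []}
    excluded: list[str] = []
    for region_id in betas.regions:
        gene_id = betas.region_gene.get(region_id, region_id)
        col = betas.avg_beta[region_id].to_numpy(float)
        col = col[~np.isnan(col)]
        if col.size == 0:
            excluded.append(str(gene_id))
            continue
        mean_beta = float(col.mean())
        slot = str(_slot_of(np.array([mean_beta]), low, high)[0])
        per_sample = _slot_of(col, low, high)
        labels, counts = np.unique(per_sample, return_counts=True)
        modal = str(labels[np.argmax(counts)])
        frac = float(counts.max() / col.size)
        classes.append(GeneMethylationClass(str(gene_id), mean_beta, slot, modal, frac))
        if frac > consistency_min:
            consistent[modal].append(str(gene_id))
    return classes, consistent, excluded
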