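"""Readers and writers for the tab-separated interchange formats.

All tabular inputs are plain TSV with headers; regions come in as BED6.
Matrix outputs carry a JSON sidecar (same path + ``.json``) recording the
aggregation parameters so downstream stages never have to guess
conventions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import CpGCallTable, RegionBetaMatrix, RegionSet

COUNTS_COLUMNS = ["chrom", "pos", "meth_count", "total_count"]
BETA_COLUMNS = ["chrom", "pos", "beta", "depth"]


class ParseError(ValueError):
    pass


def read_cpg_calls(path, mode: str = "counts", sample_id: str | None = None) -> CpGCallTable:
    """Read per-CpG calls from TSV.

    ``counts`` mode expects columns chrom, pos, meth_count, total_count and
    derives beta = meth_count / total_count; ``beta`` mode expects chrom,
    pos, beta and an optional depth column (array data have none).  Rows
    violating the invariants (meth_count > total_count, beta outside [0,1],
    depth < 1, duplicated positions) are rejected with their line numbers.
    """
    path = Path(path)
    if mode not in ("counts", "beta"):
        raise ValueError(f"unknown mode {mode!r}")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc
    sid = sample_id if sample_id is not None else path.stem

    if mode == "counts":
        missing = set(COUNTS_COLUMNS) - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for col in ("pos", "meth_count", "total_count"):
            if not np.issubdtype(df[col].dtype, np.number):
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                raise ParseError(f"{path}: non-numeric {col} at line(s) {_lines(bad)}")
        bad = df.index[df["meth_count"] > df["total_count"]]
        if len(bad):
            raise ParseError(
                f"{path}: meth_count > total_count at line(s) {_lines(bad)}"
            )
        bad = df.index[(df["total_count"] < 1) | (df["meth_count"] < 0)]
        if len(bad):
            raise ParseError(f"{path}: invalid counts at line(s) {_lines(bad)}")
        out = pd.DataFrame(
            {
                "chrom": df["chrom"].astype(str),
                "pos": df["pos"].astype(int),
                "beta": df["meth_count"] / df["total_count"],
                "depth": df["total_count"].astype(int),
            }
        )
    else:
        missing = {"chrom", "pos", "beta"} - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        bad = df.index[(df["beta"] < 0) | (df["beta"] > 1) | df["beta"].isna()]
        if len(bad):
            raise ParseError(f"{path}: beta outside [0,1] at line(s) {_lines(bad)}")
        depth = df["depth"] if "depth" in df.columns else np.nan
        out = pd.DataFrame(
            {
                "chrom": df["chrom"].astype(str),
                "pos": df["pos"].astype(int),
                "beta": df["beta"].astype(float),
                "depth": depth,
            }
        )
    dup = out.index[out.duplicated(["chrom", "pos"])]
    if len(dup):
        raise ParseError(f"{path}: duplicated (chrom, pos) at line(s) {_lines(dup)}")
    return CpGCallTable(sid, out.reset_index(drop=True))


def _lines(idx) -> str:
    # +2: header line plus 1-based numbering
    shown = [str(i + 2) for i in list(idx)[:10]]
    more = "" if len(idx) <= 10 else f" (+{len(idx) - 10} more)"
    return ",".join(shown) + more


def read_regions_bed(path, kind: str | None = None) -> RegionSet:
    """Read regions from BED (>= 4 columns: chrom, start, end, name).

    The name field is either a bare region id or ``region_id|gene_id`` or
    ``region_id|gene_id|kind``; a ``kind`` argument applies file-wide and
    overrides nothing encoded per row.  For gene-linked kinds a bare name
    doubles as the gene id.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln}: need >= 4 BED columns")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            fields = name.split("|")
            region_id = fields[0]
            gene_id = fields[1] if len(fields) > 1 and fields[1] else region_id
            row_kind = fields[2] if len(fields) > 2 and fields[2] else kind
            if row_kind is None:
                raise ParseError(
                    f"{path}:{ln}: region kind neither encoded in name nor supplied"
                )
            rows.append((region_id, gene_id, chrom, start_i, end_i, row_kind))
    df = pd.DataFrame(
        rows, columns=["region_id", "gene_id", "chrom", "start", "end", "kind"]
    )
    return RegionSet(df)


def write_regions_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for r in regions.data.itertuples(index=False):
            name = f"{r.region_id}|{r.gene_id}|{r.kind}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t+\n")


def write_beta_matrix(betas: RegionBetaMatrix, path) -> None:
    """Write avg_beta (samples x regions) TSV plus n_cpg TSV and sidecar."""
    path = Path(path)
    betas.avg_beta.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")
    betas.n_cpg.to_csv(
        path.with_suffix(".ncpg.tsv"), sep="\t", index_label="sample_id"
    )
    sidecar = {
        "min_cpgs": int(betas.min_cpgs),
        "weighted": bool(betas.weighted),
        "coordinates": "0-based half-open",
        "decile_boundaries": "[l,u) with top decile closed at 1.0",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_beta_matrix(path, min_cpgs: int | None = None) -> RegionBetaMatrix:
    path = Path(path)
    avg = pd.read_csv(path, sep="\t", index_col="sample_id")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    mc = min_cpgs if min_cpgs is not None else int(meta.get("min_cpgs", 11))
    ncpg_path = path.with_suffix(".ncpg.tsv")
    if ncpg_path.exists():
        ncpg = pd.read_csv(ncpg_path, sep="\t", index_col="sample_id")
        ncpg.columns = avg.columns
    else:
        ncpg = avg.notna().astype(int) * mc
    gene_map = pd.Series(avg.columns, index=avg.columns)
    return RegionBetaMatrix(
        avg, ncpg, min_cpgs=mc, weighted=bool(meta.get("weighted", False)), region_gene=gene_map
    )


def write_decile_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="sample_id")


def read_decile_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_survival(path, time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
    """Read survival TSV (sample_id, time, event, covariates...)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing sample_id column")
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing {col} column")
    if (df[time_col] <= 0).any():
        raise ParseError(f"{path}: non-positive survival times")
    if not df[event_col].isin([0, 1]).all():
        raise ParseError(f"{path}: event must be 0/1")
    return df.set_index("sample_id")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression count matrix TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise ParseError(f"{path}: negative expression counts")
    return df
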