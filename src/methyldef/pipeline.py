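"""Configuration-driven orchestration of the full analysis.

Stages: region aggregation -> decile counts -> permutation survival screen
-> factor (MDF/MUMF) spec derivation -> per-sample factor -> optimal
cutpoint -> single and multiple (backward-AIC) Cox models -> optional
expression correlation.  Each stage reads and writes files only, so stages
are independently runnable and testable; a manifest records the config
hash, seed and package version for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .correlate import filter_normalize_expression, mdf_expression_correlation
from .regions import RegionSet, average_region_beta, count_decile_membership
from .screen import SamScreenResult, sam_screen
from .survival import (
    CoxFitResult,
    MdfSpec,
    backward_aic,
    compute_mdf,
    dichotomize,
    fit_cox,
    km_table,
    optimal_cutpoint,
)


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML unchanged."""

    # inputs
    calls_paths: list = field(default_factory=list)  # per-sample CpG TSVs
    calls_mode: str = "counts"
    beta_matrix_path: str | None = None  # alternative to calls_paths
    regions_bed: str | None = None
    survival_path: str | None = None
    expression_path: str | None = None
    # aggregation
    min_cpgs: int = 11
    weighted: bool = True
    region_kinds: list = field(default_factory=lambda: ["gene_body"])
    # screen
    fdr_target: float = 0.05
    n_permutations: int = 1000
    s0: float | str = "auto"
    # factor + survival
    mdf_spec: dict | str = "auto"
    covariates: list = field(default_factory=list)
    min_group_frac: float = 0.1
    # expression correlation
    expression_fdr_cutoff: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def derive_mdf_spec(screen: SamScreenResult) -> MdfSpec:
    """Turn screen calls into a factor definition.

    Unfavorable (sign "+") significant deciles form the numerator and
    favorable ones the denominator.  When the significant set splits as
    all-below-0.5 deciles carrying one sign and all-above-0.5 carrying the
    other, with at least four deciles per side, the fixed
    methylated-over-unmethylated factor (deciles 6-10 over 1-5) is selected
    instead.  Patterns assigning both signs to one side of 0.5 in a mixed
    way raise and ask for a manual spec.
    """
    signs = screen.signs()
    if not signs:
        raise ValueError("screen empty; MDF undefined")
    deciles = {int(str(f).rsplit("_", 1)[-1]): s for f, s in signs.items()}
    low = {d for d in deciles if d <= 5}
    high = {d for d in deciles if d >= 6}
    low_signs = {deciles[d] for d in low}
    high_signs = {deciles[d] for d in high}
    if (
        len(low) >= 4
        and len(high) >= 4
        and len(low_signs) == 1
        and len(high_signs) == 1
        and low_signs != high_signs
    ):
        return MdfSpec.mumf()
    defined = frozenset(d for d, s in deciles.items() if s == "+")
    undefined = frozenset(d for d, s in deciles.items() if s == "-")
    if not defined or not undefined:
        raise ValueError(
            "significant deciles all share one sign; specify the factor "
            "decile sets manually"
        )
    return MdfSpec(defined, undefined)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _cox_result_dict(fit: CoxFitResult) -> dict:
    return {
        "terms": {
            str(t): {
                "hazard_ratio": float(r["hazard_ratio"]),
                "ci95": [float(r["ci_low"]), float(r["ci_high"])],
                "p_value": float(r["p"]),
            }
            for t, r in fit.terms.iterrows()
        },
        "log_likelihood": fit.log_likelihood,
        "aic": fit.aic,
        "n": fit.n,
        "n_events": fit.n_events,
        "retained_covariates": list(fit.retained_covariates),
        "excluded_covariates": list(fit.excluded_covariates),
    }


def stage_aggregate(config: PipelineConfig, out_dir: Path) -> tuple[Path, Path]:
    """Aggregate CpG calls (or a precomputed matrix) and count deciles."""
    if config.beta_matrix_path:
        betas = mio.read_beta_matrix(config.beta_matrix_path, min_cpgs=config.min_cpgs)
    else:
        regions = mio.read_regions_bed(config.regions_bed)
        regions = regions.subset(config.region_kinds)
        calls = [
            mio.read_cpg_calls(p, mode=config.calls_mode) for p in config.calls_paths
        ]
        betas = average_region_beta(
            calls, regions, weighted=config.weighted, min_cpgs=config.min_cpgs
        )
    counts = count_decile_membership(betas)
    beta_path = out_dir / "region_betas.tsv"
    counts_path = out_dir / "decile_counts.tsv"
    mio.write_beta_matrix(betas, beta_path)
    mio.write_decile_counts(counts, counts_path)
    return beta_path, counts_path


def stage_screen(config: PipelineConfig, counts_path: Path, out_dir: Path) -> SamScreenResult:
    counts = mio.read_decile_counts(counts_path)
    surv = mio.read_survival(config.survival_path)
    result = sam_screen(
        counts,
        surv,
        fdr_target=config.fdr_target,
        n_permutations=config.n_permutations,
        s0=config.s0,
        seed=config.seed,
    )
    plot_df = result.table.copy()
    plot_df.index.name = "feature"
    plot_df.to_csv(out_dir / "sam_screen.tsv", sep="\t")
    _write_json(
        out_dir / "sam_screen.json",
        {
            "delta": result.delta,
            "s0": result.s0,
            "fdr_target": result.fdr_target,
            "estimated_fdr": result.estimated_fdr,
            "n_permutations": result.n_permutations,
            "seed": result.seed,
            "exhaustive": result.exhaustive,
            "significant": {str(k): v for k, v in result.signs().items()},
            **result.params,
        },
    )
    return result


def stage_mdf(
    config: PipelineConfig, counts_path: Path, spec: MdfSpec, out_dir: Path
) -> pd.Series:
    counts = mio.read_decile_counts(counts_path)
    mdf = compute_mdf(counts, spec)
    mdf.to_frame().to_csv(out_dir / "mdf.tsv", sep="\t", index_label="sample_id")
    _write_json(out_dir / "mdf_spec.json", spec.to_dict())
    return mdf


def stage_survival(
    config: PipelineConfig, mdf: pd.Series, out_dir: Path
) -> dict:
    surv = mio.read_survival(config.survival_path)
    common = mdf.index.intersection(surv.index)
    surv = surv.loc[common]
    mdf = mdf.loc[common]
    cut = optimal_cutpoint(
        mdf,
        surv,
        covariates=config.covariates,
        min_group_frac=config.min_group_frac,
    )
    groups = dichotomize(mdf, cut.cutpoint)
    factor_term = f"{mdf.name or 'MDF'}_high"
    surv2 = surv.copy()
    surv2[factor_term] = groups
    single = fit_cox(surv2, [factor_term])
    multiple = backward_aic(
        surv2, [factor_term] + list(config.covariates), forced=[factor_term]
    )
    km = km_table(surv2, groups.map({1: "high", 0: "low"}))
    km.to_csv(out_dir / "km.tsv", sep="\t", index=False)
    _write_json(
        out_dir / "cutpoint.json",
        {
            "cutpoint": cut.cutpoint,
            "p_at_cutpoint": cut.p_at_cutpoint,
            "n_candidates": cut.n_candidates,
            "group_sizes": {"high": cut.group_sizes[0], "low": cut.group_sizes[1]},
        },
    )
    _write_json(out_dir / "cox_single.json", _cox_result_dict(single))
    _write_json(out_dir / "cox_multiple.json", _cox_result_dict(multiple))
    return {
        "cutpoint": cut,
        "groups": groups,
        "single": single,
        "multiple": multiple,
        "factor_term": factor_term,
    }


def stage_correlate(config: PipelineConfig, mdf: pd.Series, out_dir: Path) -> dict:
    counts = mio.read_expression(config.expression_path)
    logcpm, meta = filter_normalize_expression(counts)
    records, pos, neg, summary = mdf_expression_correlation(
        mdf, logcpm, fdr_cutoff=config.expression_fdr_cutoff
    )
    records.to_csv(out_dir / "mdf_expression.tsv", sep="\t", index=False)
    (out_dir / "genes_positive.txt").write_text("\n".join(pos) + ("\n" if pos else ""))
    (out_dir / "genes_negative.txt").write_text("\n".join(neg) + ("\n" if neg else ""))
    _write_json(out_dir / "mdf_expression.json", {**meta, **summary})
    return {"records": records, "positive": pos, "negative": neg, "summary": summary}


def _report(bundle: dict, out_dir: Path) -> None:
    lines = ["Gene-body methylation definition analysis", "=" * 42, ""]
    scr: SamScreenResult | None = bundle.get("screen")
    if scr is not None:
        lines.append(
            f"samples: {scr.params.get('n_samples')}   events: {scr.params.get('n_events')}"
        )
        sig = ", ".join(f"{k}({v})" for k, v in scr.signs().items()) or "none"
        lines.append(f"significant deciles (FDR {scr.fdr_target:.0%}): {sig}")
    spec: MdfSpec | None = bundle.get("spec")
    if spec is not None:
        lines.append(
            f"factor: {spec.mode}  defined={sorted(spec.defined)}  "
            f"undefined={sorted(spec.undefined)}"
        )
    sv = bundle.get("survival")
    if sv is not None:
        cut = sv["cutpoint"]
        lines.append(
            f"cutpoint: {cut.cutpoint:.4g} (p={cut.p_at_cutpoint:.3g}, "
            f"{cut.group_sizes[0]} high vs {cut.group_sizes[1]} low, "
            f"{cut.n_candidates} candidates)"
        )
        for label, fit in (("univariate", sv["single"]), ("multiple", sv["multiple"])):
            row = fit.terms.loc[sv["factor_term"]]
            lines.append(
                f"{label} Cox: HR {row['hazard_ratio']:.2f} "
                f"({row['ci_low']:.2f}-{row['ci_high']:.2f}) p={row['p']:.4g} "
                f"[n={fit.n}, events={fit.n_events}]"
            )
        if sv["multiple"].retained_covariates or sv["multiple"].excluded_covariates:
            lines.append(
                f"covariates retained: {sv['multiple'].retained_covariates} "
                f"excluded: {sv['multiple'].excluded_covariates}"
            )
    corr = bundle.get("correlate")
    if corr is not None:
        s = corr["summary"]
        lines.append(
            f"expression screen: {s['n_positive']} positively / {s['n_negative']} "
            f"negatively correlated genes of {s['n_tested']} tested "
            f"(FDR < {s['fdr_cutoff']:.0%})"
        )
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all configured stages; returns the in-memory result bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # validate inputs up front so failures are immediate and clear
    needed = list(config.calls_paths)
    for p in (config.beta_matrix_path, config.regions_bed, config.survival_path, config.expression_path):
        if p:
            needed.append(p)
    for p in needed:
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    if not config.beta_matrix_path and not config.calls_paths:
        raise ValueError("config needs calls_paths or beta_matrix_path")
    if config.survival_path is None:
        raise ValueError("config needs survival_path")

    bundle: dict = {}
    _, counts_path = stage_aggregate(config, out_dir)
    screen = stage_screen(config, counts_path, out_dir)
    bundle["screen"] = screen
    if config.mdf_spec == "auto":
        spec = derive_mdf_spec(screen)
    else:
        spec = MdfSpec.from_dict(config.mdf_spec)
    bundle["spec"] = spec
    mdf = stage_mdf(config, counts_path, spec, out_dir)
    bundle["mdf"] = mdf
    bundle["survival"] = stage_survival(config, mdf, out_dir)
    if config.expression_path:
        bundle["correlate"] = stage_correlate(config, mdf, out_dir)
    _write_json(
        out_dir / "manifest.json",
        {"config": config.to_dict(), "config_hash": config.hash(), "seed": config.seed, "version": __version__},
    )
    _report(bundle, out_dir)
    return bundle
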