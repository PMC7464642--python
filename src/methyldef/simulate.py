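"""Synthetic methylome, survival and expression data with known truth.

The generator emulates the structure the pipeline consumes, at desk scale:

* per-gene baseline methylation drawn from a trimodal mixture (peaks near
  0 and 1 plus an intermediate mass), matching the U-with-middle shape of
  per-sample decile histograms of gene-body methylation;
* a per-sample latent "definition" phenotype delta in [0, 1]: betas of a
  sample are pulled toward 0.5 on the logit scale with strength
  (1 - delta), so low-delta ("tumor-like") samples lose extreme
  methylation states and their MDF drops;
* negative-binomial CpG coverage so the log10(depth + 0.1) weighting is
  exercised non-trivially, with binomial methylated counts per CpG;
* exponential survival whose log-hazard is linked to -delta (sign
  flippable), with independent censoring calibrated to a target fraction;
* negative-binomial expression counts with a configured subset of genes
  whose log-mean tracks delta.

Every dataset ships a truth record; identical (config, seed) regenerates
bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special

from .regions import CpGCallTable, RegionSet


@dataclass
class GeneratorConfig:
    n_samples: int = 45
    n_genes: int = 2000
    cgi_fraction: float = 0.7  # fraction of genes carrying a CGI
    coupled_cgi_fraction: float = 0.05  # CGI methylation tracks the GB
    cpgs_per_gene_mean: float = 25.0
    cpgs_per_gene_dispersion: float = 0.3
    cgi_cpgs_mean: float = 15.0
    depth_mean: float = 30.0
    depth_dispersion: float = 0.3
    beta_mixture_weights: tuple = (0.35, 0.30, 0.35)
    beta_mixture_locations: tuple = (0.04, 0.55, 0.95)
    beta_mixture_logit_sd: float = 0.4
    sample_noise_sd: float = 0.3  # per gene-sample logit noise
    cpg_noise_sd: float = 0.05
    delta_beta_params: tuple = (2.0, 2.0)  # definition phenotype prior
    hazard_gamma: float = 3.0  # log-hazard per unit of (1 - delta)
    baseline_rate: float = 0.02  # events per month at delta = 1
    censoring_rate: float = 0.35
    expression_linked_fraction: float = 0.05
    expression_strength: float = 1.0  # log2 shift per unit delta
    expression_dispersion: float = 0.2
    library_size: float = 2e6
    library_size_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.beta_mixture_weights, dtype=float)
        if w.ndim != 1 or len(w) != len(self.beta_mixture_locations):
            raise ValueError("mixture weights and locations must align")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be non-negative and sum to 1")
        locs = np.asarray(self.beta_mixture_locations, dtype=float)
        if np.any((locs <= 0) | (locs >= 1)):
            raise ValueError("mixture locations must lie in (0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def sample_ids(n: int) -> list:
    return [f"S{i + 1:03d}" for i in range(n)]


def gene_ids(n: int) -> list:
    return [f"gene_{i + 1:05d}" for i in range(n)]


def _negbin(rng, mean: float, dispersion: float, size) -> np.ndarray:
    """Gamma-Poisson draw with Var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion, size=size)
    return rng.poisson(lam)


def draw_baseline_betas(config: GeneratorConfig, rng) -> np.ndarray:
    """Per-gene baseline methylation from the trimodal logit-normal mixture."""
    comp = rng.choice(
        len(config.beta_mixture_weights), size=config.n_genes, p=config.beta_mixture_weights
    )
    locs = special.logit(np.asarray(config.beta_mixture_locations, dtype=float))
    z = locs[comp] + rng.normal(0.0, config.beta_mixture_logit_sd, size=config.n_genes)
    return special.expit(z)


def draw_delta(config: GeneratorConfig, rng) -> np.ndarray:
    a, b = config.delta_beta_params
    return rng.beta(a, b, size=config.n_samples)


def target_betas(mu: np.ndarray, delta: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    """Per-sample target betas: logit shrinkage toward 0.5 by (1 - delta).

    Returns an (n_samples, n_genes) array: expit(delta_n * logit(mu_g) +
    noise).  delta = 1 leaves the baseline untouched; delta = 0 collapses
    every gene to intermediate methylation.
    """
    lz = special.logit(np.clip(mu, 1e-6, 1 - 1e-6))
    z = delta[:, None] * lz[None, :]
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=z.shape)
    return special.expit(z)


def simulate_methylome(config: GeneratorConfig):
    """Generate per-sample CpG call tables, regions and the truth record.

    Genes are laid out sequentially on synthetic chromosomes (500 genes
    each); a configured fraction carries a CGI, half overlapping the gene
    start (inside the gene body) and half in the promoter window upstream.
    A small fraction of CGIs is methylation-coupled to its gene body; the
    rest stay near-unmethylated independently, as promoter CGIs mostly are.

    Returns ``(calls, regions, truth)`` with ``truth`` holding delta, the
    baseline betas, each gene's intended slot and the coupled pairs.
    """
    rng = np.random.default_rng(config.seed)
    n_g, n_s = config.n_genes, config.n_samples
    genes = gene_ids(n_g)
    samples = sample_ids(n_s)

    mu = draw_baseline_betas(config, rng)
    delta = draw_delta(config, rng)

    cpg_per_gene = np.maximum(
        _negbin(rng, config.cpgs_per_gene_mean, config.cpgs_per_gene_dispersion, n_g), 3
    )
    spacing = 80
    genes_per_chrom = 500
    chrom_idx = np.arange(n_g) // genes_per_chrom
    offset_in_chrom = np.arange(n_g) % genes_per_chrom
    gene_start = 5000 + offset_in_chrom * 10_000
    gene_end = gene_start + cpg_per_gene * spacing + 200
    chrom_names = np.array([f"chr{c + 1}" for c in chrom_idx])

    has_cgi = rng.random(n_g) < config.cgi_fraction
    cgi_genes = np.flatnonzero(has_cgi)
    cgi_inside = rng.random(len(cgi_genes)) < 0.5
    coupled = rng.random(len(cgi_genes)) < config.coupled_cgi_fraction
    cgi_cpgs = np.maximum(_negbin(rng, config.cgi_cpgs_mean, 0.2, len(cgi_genes)), 3)

    region_rows = [
        (genes[g], genes[g], chrom_names[g], int(gene_start[g]), int(gene_end[g]), "gene_body")
        for g in range(n_g)
    ]
    cgi_start = np.where(
        cgi_inside, gene_start[cgi_genes], np.maximum(0, gene_start[cgi_genes] - 1500)
    )
    cgi_end = cgi_start + 600
    for j, g in enumerate(cgi_genes):
        region_rows.append(
            (f"cgi_{genes[g]}", genes[g], chrom_names[g], int(cgi_start[j]), int(cgi_end[j]), "cgi")
        )
    regions = RegionSet(
        pd.DataFrame(
            region_rows, columns=["region_id", "gene_id", "chrom", "start", "end", "kind"]
        )
    )

    # shared CpG loci: GB CpGs inside the gene, CGI CpGs inside the island
    gb_gene_idx = np.repeat(np.arange(n_g), cpg_per_gene)
    gb_pos = np.concatenate(
        [gene_start[g] + 100 + np.arange(cpg_per_gene[g]) * spacing for g in range(n_g)]
    )
    cgi_rep = np.repeat(np.arange(len(cgi_genes)), cgi_cpgs)
    cgi_pos = np.concatenate(
        [cgi_start[j] + 7 + np.arange(cgi_cpgs[j]) * 37 for j in range(len(cgi_genes))]
    ) if len(cgi_genes) else np.array([], dtype=int)

    chrom_all = np.concatenate([chrom_names[gb_gene_idx], chrom_names[cgi_genes][cgi_rep]])
    pos_all = np.concatenate([gb_pos, cgi_pos]).astype(int)

    # CGI baseline: coupled islands share the gene baseline, others sit low
    cgi_mu = np.where(coupled, mu[cgi_genes], special.expit(rng.normal(-3.0, 0.8, len(cgi_genes))))

    gb_targets = target_betas(mu, delta, config.sample_noise_sd, rng)
    cgi_targets = target_betas(cgi_mu, delta, config.sample_noise_sd, rng) if len(cgi_genes) else np.empty((n_s, 0))

    calls: list[CpGCallTable] = []
    n_cpg_total = len(pos_all)
    for i, sid in enumerate(samples):
        tgt = np.concatenate([gb_targets[i][gb_gene_idx], cgi_targets[i][cgi_rep]])
        if config.cpg_noise_sd > 0:
            tgt = np.clip(tgt + rng.normal(0.0, config.cpg_noise_sd, n_cpg_total), 0.0, 1.0)
        depth = np.maximum(_negbin(rng, config.depth_mean, config.depth_dispersion, n_cpg_total), 1)
        meth = rng.binomial(depth, tgt)
        # guard against duplicate loci where a CGI overlaps its gene's CpG grid
        df = pd.DataFrame(
            {"chrom": chrom_all, "pos": pos_all, "beta": meth / depth, "depth": depth}
        ).drop_duplicates(["chrom", "pos"], keep="first")
        calls.append(CpGCallTable(sid, df.reset_index(drop=True)))

    intended_slot = np.where(mu < 0.3, "unmethylated", np.where(mu > 0.7, "methylated", "undefined"))
    truth = {
        "delta": pd.Series(delta, index=samples, name="delta"),
        "baseline_beta": pd.Series(mu, index=genes, name="baseline_beta"),
        "intended_slot": pd.Series(intended_slot, index=genes, name="intended_slot"),
        "coupled_pairs": [
            (genes[g], f"cgi_{genes[g]}") for g, c in zip(cgi_genes, coupled) if c
        ],
        "config": config.to_dict(),
    }
    return calls, regions, truth


def simulate_decile_counts(
    delta: np.ndarray,
    config: GeneratorConfig | None = None,
    n_regions: int | None = None,
    rng=None,
) -> pd.DataFrame:
    """Region-level shortcut: decile counts straight from target betas.

    Draws each sample's region-average betas from the same
    baseline-mixture-plus-shrinkage model as :func:`simulate_methylome`
    (skipping the CpG layer) and bins them into deciles.  Used by the
    calibration and recovery experiments where only the count matrix
    matters.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    delta = np.asarray(delta, dtype=float)
    n_regions = n_regions or config.n_genes
    comp = rng.choice(
        len(config.beta_mixture_weights), size=n_regions, p=config.beta_mixture_weights
    )
    locs = special.logit(np.asarray(config.beta_mixture_locations, dtype=float))
    mu = special.expit(locs[comp] + rng.normal(0.0, config.beta_mixture_logit_sd, n_regions))
    betas = target_betas(mu, delta, config.sample_noise_sd, rng)
    dec = np.minimum(np.floor(betas * 10).astype(int), 9)
    counts = np.stack([np.bincount(row, minlength=10) for row in dec])
    return pd.DataFrame(
        counts, index=sample_ids(len(delta)), columns=[f"decile_{d}" for d in range(1, 11)]
    )


def _censoring_rate_for(rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate achieving the target censored fraction.

    With event rate lambda_i and censoring rate c the expected censored
    fraction is mean(c / (c + lambda_i)); solved by bisection.
    """
    if target <= 0:
        return 0.0

    def frac(log_c):
        c = np.exp(log_c)
        return float(np.mean(c / (c + rates))) - target

    return float(np.exp(optimize.brentq(frac, -30.0, 30.0)))


def simulate_survival(
    delta: np.ndarray,
    gamma: float | None = None,
    baseline_rate: float | None = None,
    censoring_rate: float | None = None,
    seed: int | None = None,
    config: GeneratorConfig | None = None,
    age_confounding: float = 0.0,
) -> pd.DataFrame:
    """Exponential survival linked to the definition phenotype.

    The event rate of sample n is ``baseline_rate * exp(gamma * (1 -
    delta_n))``: with gamma > 0, poorly defined (low delta) samples die
    faster.  Negative gamma flips the direction.  Independent exponential
    censoring is calibrated so the expected censored fraction matches
    ``censoring_rate``.  Returns a survival table indexed by sample id with
    time (months), event, age and stage columns; ``age_confounding`` adds
    -delta into age.
    """
    config = config or GeneratorConfig()
    gamma = config.hazard_gamma if gamma is None else gamma
    baseline_rate = config.baseline_rate if baseline_rate is None else baseline_rate
    censoring_rate = config.censoring_rate if censoring_rate is None else censoring_rate
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    delta = np.asarray(delta, dtype=float)
    n = len(delta)
    rates = baseline_rate * np.exp(gamma * (1.0 - delta))
    t_event = rng.exponential(1.0 / rates)
    if censoring_rate > 0:
        c = _censoring_rate_for(rates, censoring_rate)
        t_cens = rng.exponential(1.0 / c, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    age = 60.0 + 10.0 * rng.standard_normal(n) + age_confounding * (1.0 - delta)
    stage = rng.choice(["III", "IV"], size=n, p=[0.6, 0.4])
    return pd.DataFrame(
        {
            "time": np.maximum(time, 1e-6),
            "event": event,
            "age": age,
            "stage": stage,
        },
        index=pd.Index(sample_ids(n), name="sample_id"),
    )


def simulate_expression(
    delta: np.ndarray, config: GeneratorConfig | None = None, seed: int | None = None
):
    """Negative-binomial expression counts partially linked to delta.

    A configured fraction of genes has its log2 mean shifted by
    +/- strength * (delta - mean(delta)); library sizes vary log-normally.
    Returns ``(counts genes x samples, truth)`` where truth lists the
    planted positive and negative genes.
    """
    config = config or GeneratorConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    delta = np.asarray(delta, dtype=float)
    n_s, n_g = len(delta), config.n_genes
    genes = gene_ids(n_g)
    samples = sample_ids(n_s)

    log2_abund = rng.normal(4.0, 1.5, size=n_g)
    rel = 2.0**log2_abund
    rel /= rel.sum()
    n_linked = int(round(config.expression_linked_fraction * n_g))
    linked = rng.choice(n_g, size=n_linked, replace=False)
    sign = rng.choice([-1.0, 1.0], size=n_linked)
    shift = np.zeros((n_g, n_s))
    centred = delta - delta.mean()
    shift[linked] = sign[:, None] * config.expression_strength * centred[None, :]
    lib = config.library_size * np.exp(
        rng.normal(0.0, config.library_size_log_sd, size=n_s)
    )
    mean = rel[:, None] * (2.0**shift) * lib[None, :]
    shape = 1.0 / config.expression_dispersion
    lam = rng.gamma(shape, mean * config.expression_dispersion)
    counts = rng.poisson(lam)
    truth = {
        "positive_genes": [genes[i] for i, s in zip(linked, sign) if s > 0],
        "negative_genes": [genes[i] for i, s in zip(linked, sign) if s < 0],
    }
    return pd.DataFrame(counts, index=genes, columns=samples), truth
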