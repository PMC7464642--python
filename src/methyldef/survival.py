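"""MDF/MUMF computation, optimal-cutpoint dichotomisation and Cox models.

The methylation definition factor (MDF) of a sample is the ratio of its
region counts in "defined/extreme" methylation deciles to its counts in
"undefined/intermediate" deciles; the glioblastoma-style
methylation-over-unmethylation factor (MUMF) fixes those sets to deciles
6-10 over 1-5 (average beta above vs below 0.5).  The factor is
dichotomised at the cutpoint minimising the Wald p-value of the
dichotomised term inside a covariate-adjusted Cox model, and the final
single/multiple Cox models (multiple with backward AIC selection, the
factor forced in) are fit with lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError

from ._cox import CoxConvergenceError, cox_newton, sort_survival, wald_p

ALL_DECILES = frozenset(range(1, 11))


@dataclass(frozen=True)
class MdfSpec:
    """Decile index sets defining the factor numerator and denominator."""

    defined: frozenset
    undefined: frozenset
    mode: str = "MDF"

    def __post_init__(self):
        object.__setattr__(self, "defined", frozenset(int(d) for d in self.defined))
        object.__setattr__(self, "undefined", frozenset(int(d) for d in self.undefined))
        if self.mode not in ("MDF", "MUMF"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.defined or not self.undefined:
            raise ValueError("both decile sets must be non-empty")
        if self.defined & self.undefined:
            raise ValueError("defined and undefined decile sets overlap")
        if not (self.defined <= ALL_DECILES and self.undefined <= ALL_DECILES):
            raise ValueError("decile indices must lie in 1..10")
        if self.mode == "MUMF" and (
            self.defined != frozenset(range(6, 11)) or self.undefined != frozenset(range(1, 6))
        ):
            raise ValueError("MUMF fixes numerator 6..10 and denominator 1..5")

    @classmethod
    def mumf(cls) -> "MdfSpec":
        return cls(frozenset(range(6, 11)), frozenset(range(1, 6)), mode="MUMF")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "defined_deciles": sorted(self.defined),
            "undefined_deciles": sorted(self.undefined),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MdfSpec":
        return cls(
            frozenset(d["defined_deciles"]),
            frozenset(d["undefined_deciles"]),
            mode=d.get("mode", "MDF"),
        )


@dataclass
class CutpointResult:
    cutpoint: float
    p_at_cutpoint: float
    candidates: pd.DataFrame  # columns: cutpoint, p, n_high, n_low
    group_sizes: tuple
    n_candidates: int
    permutation_p: float | None = None


@dataclass
class CoxFitResult:
    """Per-term hazard ratios with Wald CIs/p plus model-level summaries."""

    terms: pd.DataFrame  # index term; columns hazard_ratio, ci_low, ci_high, p
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    retained_covariates: list = field(default_factory=list)
    excluded_covariates: list = field(default_factory=list)
    drop_trace: list = field(default_factory=list)


def _decile_cols(counts: pd.DataFrame, deciles) -> list:
    cols = []
    for d in sorted(deciles):
        name = f"decile_{d}"
        if name not in counts.columns:
            raise ValueError(f"counts lack column {name}")
        cols.append(name)
    return cols


def compute_mdf(
    counts: pd.DataFrame, spec: MdfSpec, pseudo_count: float = 0.0
) -> pd.Series:
    """Per-sample factor: defined-decile counts over undefined-decile counts.

    A zero denominator yields +inf (dichotomises as "high") with a warning;
    set ``pseudo_count`` to add the same constant to both sums instead.
    """
    num = counts[_decile_cols(counts, spec.defined)].sum(axis=1).astype(float)
    den = counts[_decile_cols(counts, spec.undefined)].sum(axis=1).astype(float)
    num += pseudo_count
    den += pseudo_count
    zero = den == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) with zero undefined-decile counts: "
            f"factor set to +inf",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        out = num / den
    out.name = spec.mode
    return out


def _encode_covariates(
    surv: pd.DataFrame, covariates, reference_levels: dict | None = None
) -> pd.DataFrame:
    """Treatment-code categoricals against the alphabetically first level."""
    reference_levels = reference_levels or {}
    pieces = []
    for cov in covariates:
        if cov not in surv.columns:
            raise ValueError(f"covariate {cov!r} absent from survival table")
        col = surv[cov]
        if pd.api.types.is_numeric_dtype(col):
            pieces.append(col.astype(float).to_frame(cov))
        else:
            levels = sorted(col.dropna().astype(str).unique())
            ref = reference_levels.get(cov, levels[0] if levels else None)
            cat = pd.Categorical(col.astype(str), categories=[ref] + [l for l in levels if l != ref])
            dummies = pd.get_dummies(cat, prefix=cov, drop_first=True, dtype=float)
            dummies.index = surv.index
            pieces.append(dummies)
    if not pieces:
        return pd.DataFrame(index=surv.index)
    return pd.concat(pieces, axis=1)


def optimal_cutpoint(
    score: pd.Series,
    surv: pd.DataFrame,
    covariates=(),
    min_group_frac: float = 0.1,
    time_col: str = "time",
    event_col: str = "event",
    n_permutations: int = 0,
    seed: int | None = 0,
) -> CutpointResult:
    """Minimal-p dichotomisation cutpoint inside a covariate-adjusted Cox model.

    Candidates are the midpoints between consecutive distinct score values
    whose induced high/low split leaves at least ``min_group_frac`` of the
    samples on each side.  For every candidate a Cox model
    ``surv ~ 1[score > c] + covariates`` is fit and the Wald p of the
    indicator recorded; the candidate with the smallest p wins, ties going
    to the smaller cutpoint.  Minimal-p searches inflate type-I error: the
    number of candidates is reported, and ``n_permutations > 0`` adds a
    permutation-adjusted p for the selected cutpoint.
    """
    common = score.index.intersection(surv.index)
    sc = score.loc[common].to_numpy(float)
    sv = surv.loc[common]
    n = len(common)
    finite = np.unique(sc[np.isfinite(sc)])
    if finite.size < 3:
        raise ValueError("score needs at least 3 distinct finite values")
    mids = (finite[:-1] + finite[1:]) / 2.0
    min_group = min_group_frac * n
    time = sv[time_col].to_numpy(float)
    event = sv[event_col].to_numpy(int)
    ss = sort_survival(time, event)
    Z = _encode_covariates(sv, covariates).to_numpy(float)

    def _scan(scores: np.ndarray, cands: np.ndarray) -> pd.DataFrame:
        rows = []
        for c in cands:
            high = scores > c
            n_high = int(high.sum())
            n_low = n - n_high
            if n_high < min_group or n_low < min_group:
                continue
            X = np.column_stack([high.astype(float), Z]) if Z.size else high.astype(float)[:, None]
            try:
                beta, _, cov = cox_newton(X, ss)
                p = float(wald_p(beta, cov)[0])
            except CoxConvergenceError:
                p = np.nan
            rows.append((float(c), p, n_high, n_low))
        return pd.DataFrame(rows, columns=["cutpoint", "p", "n_high", "n_low"])

    cand_df = _scan(sc, mids)
    if cand_df.empty:
        raise ValueError("no cutpoint candidate satisfies the group-size constraint")
    valid = cand_df.dropna(subset=["p"])
    if valid.empty:
        raise ValueError("no candidate Cox model converged")
    # minimal p, ties -> smaller cutpoint (candidates are in ascending order)
    best = valid.iloc[int(np.argmin(valid["p"].to_numpy()))]

    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm_sc = rng.permutation(sc)
            pdf = _scan(perm_sc, (np.unique(perm_sc[np.isfinite(perm_sc)])[:-1] + np.unique(perm_sc[np.isfinite(perm_sc)])[1:]) / 2)
            pmin = pdf["p"].min() if not pdf.empty else 1.0
            if pmin <= best["p"]:
                hits += 1
        perm_p = (hits + 1) / (n_permutations + 1)

    return CutpointResult(
        cutpoint=float(best["cutpoint"]),
        p_at_cutpoint=float(best["p"]),
        candidates=cand_df.reset_index(drop=True),
        group_sizes=(int(best["n_high"]), int(best["n_low"])),
        n_candidates=len(cand_df),
        permutation_p=perm_p,
    )


def dichotomize(score: pd.Series, cutpoint: float) -> pd.Series:
    """High/low group indicator at the cutpoint (+inf scores are high)."""
    out = (score > cutpoint).astype(int)
    out.name = f"{score.name or 'score'}_high"
    return out


def _design(surv: pd.DataFrame, terms, time_col: str, event_col: str):
    num_terms = [t for t in terms if pd.api.types.is_numeric_dtype(surv[t])]
    cat_terms = [t for t in terms if t not in num_terms]
    enc = _encode_covariates(surv, list(terms))
    term_cols = {t: [t] if t in num_terms else [c for c in enc.columns if c.startswith(f"{t}_")] for t in terms}
    df = pd.concat([surv[[time_col, event_col]], enc], axis=1).dropna()
    return df, term_cols


def fit_cox(
    surv: pd.DataFrame,
    terms,
    forced=(),
    time_col: str = "time",
    event_col: str = "event",
) -> CoxFitResult:
    """Maximum-partial-likelihood Cox fit (Breslow ties) via lifelines.

    Categorical terms are treatment-coded against the alphabetically first
    level; rows with missing values in any used column are dropped
    (complete-case).  Collinear designs raise ValueError.
    """
    terms = list(terms)
    for t in terms:
        if t not in surv.columns:
            raise ValueError(f"term {t!r} absent from survival table")
        col = surv[t].dropna()
        if col.nunique() < 2:
            raise ValueError(f"term {t!r} is constant")
    df, term_cols = _design(surv, terms, time_col, event_col)
    design_cols = [c for t in terms for c in term_cols[t]]
    X = df[design_cols].to_numpy(float)
    if X.shape[1] and np.linalg.matrix_rank(np.column_stack([np.ones(len(df)), X])) < X.shape[1] + 1:
        raise ValueError("rank-deficient design (collinear covariates)")
    n_events = int(df[event_col].sum())
    if n_events < X.shape[1]:
        warnings.warn(
            f"{n_events} events for {X.shape[1]} coefficients: estimates unstable",
            stacklevel=2,
        )
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except _LLConvergenceError as exc:
        raise ValueError(f"Cox model did not converge: {exc}") from exc
    summ = cph.summary
    table = pd.DataFrame(
        {
            "hazard_ratio": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    table.index.name = "term"
    return CoxFitResult(
        terms=table,
        log_likelihood=float(cph.log_likelihood_),
        aic=float(cph.AIC_partial_),
        n=int(len(df)),
        n_events=n_events,
        retained_covariates=[t for t in terms if t not in forced],
    )


def backward_aic(
    surv: pd.DataFrame,
    full_terms,
    forced=(),
    time_col: str = "time",
    event_col: str = "event",
) -> CoxFitResult:
    """Backward stepwise selection minimising the partial-likelihood AIC.

    Starting from ``full_terms``, repeatedly drops the non-forced term whose
    removal lowers AIC the most, until no removal lowers it.  Forced terms
    (the dichotomised factor) are never dropped.  Complete-case rows are
    fixed by the full model so AICs stay comparable across steps.
    """
    full_terms = list(full_terms)
    forced = list(forced)
    if not set(forced) <= set(full_terms):
        raise ValueError("forced terms must be a subset of full_terms")
    used_cols = [time_col, event_col] + full_terms
    base_rows = surv[used_cols].dropna().index
    sub = surv.loc[base_rows]

    current = list(full_terms)
    trace: list[tuple[str, float]] = []
    fit = fit_cox(sub, current, forced, time_col, event_col)
    while True:
        droppable = [t for t in current if t not in forced]
        best_term, best_fit = None, None
        for t in droppable:
            cand = [u for u in current if u != t]
            try:
                f = fit_cox(sub, cand, forced, time_col, event_col)
            except ValueError:
                continue
            if f.aic < fit.aic - 1e-10 and (best_fit is None or f.aic < best_fit.aic):
                best_term, best_fit = t, f
        if best_term is None:
            break
        current.remove(best_term)
        trace.append((best_term, best_fit.aic))
        fit = best_fit
    fit.retained_covariates = [t for t in current if t not in forced]
    fit.excluded_covariates = [t for t in full_terms if t not in current]
    fit.drop_trace = trace
    return fit


def km_table(
    surv: pd.DataFrame,
    groups: pd.Series,
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Kaplan-Meier estimate per group: time, at-risk count, survival."""
    rows = []
    common = groups.index.intersection(surv.index)
    for g, idx in groups.loc[common].groupby(groups.loc[common]).groups.items():
        km = KaplanMeierFitter()
        sub = surv.loc[idx]
        km.fit(sub[time_col], sub[event_col], label=str(g))
        ev = km.event_table
        surv_fn = km.survival_function_.iloc[:, 0]
        for t in ev.index:
            rows.append(
                (str(g), float(t), int(ev.loc[t, "at_risk"]), float(surv_fn.loc[t]))
            )
    return pd.DataFrame(rows, columns=["group", "time", "at_risk", "survival"])
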