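"""MDF arithmetic, optimal cutpoint, Cox fits and backward-AIC selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from methyldef import (
    MdfSpec,
    backward_aic,
    compute_mdf,
    dichotomize,
    fit_cox,
    km_table,
    optimal_cutpoint,
)
from methyldef._cox import cox_newton, sort_survival, wald_p

OVCA_SPEC = MdfSpec(frozenset({1, 10}), frozenset({6, 7}))


def _counts_row(values):
    row = {f"decile_{d}": 0 for d in range(1, 11)}
    row.update({f"decile_{d}": v for d, v in values.items()})
    return row


class TestMdfSpec:
    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            MdfSpec(frozenset({1, 6}), frozenset({6, 7}))

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            MdfSpec(frozenset(), frozenset({6}))

    def test_mumf_sets_are_fixed(self):
        spec = MdfSpec.mumf()
        assert spec.defined == frozenset({6, 7, 8, 9, 10})
        assert spec.undefined == frozenset({1, 2, 3, 4, 5})
        with pytest.raises(ValueError, match="MUMF"):
            MdfSpec(frozenset({6}), frozenset({1}), mode="MUMF")

    def test_roundtrip_dict(self):
        spec = MdfSpec.from_dict(OVCA_SPEC.to_dict())
        assert spec == OVCA_SPEC


class TestComputeMdf:
    def test_worked_ratio(self):
        counts = pd.DataFrame([_counts_row({1: 100, 10: 50, 6: 30, 7: 20})], index=["s"])
        assert compute_mdf(counts, OVCA_SPEC).loc["s"] == pytest.approx(3.0)

    def test_equal_counts_give_set_size_ratio(self):
        counts = pd.DataFrame([{f"decile_{d}": 7 for d in range(1, 11)}], index=["s"])
        value = compute_mdf(counts, OVCA_SPEC).loc["s"]
        assert value == pytest.approx(len(OVCA_SPEC.defined) / len(OVCA_SPEC.undefined))

    def test_mumf_ratio(self):
        counts = pd.DataFrame(
            [{f"decile_{d}": (80 if d >= 6 else 40) for d in range(1, 11)}], index=["s"]
        )
        assert compute_mdf(counts, MdfSpec.mumf()).loc["s"] == pytest.approx(2.0)

    def test_zero_denominator_is_inf_with_warning(self):
        counts = pd.DataFrame([_counts_row({1: 10, 10: 5})], index=["s"])
        with pytest.warns(UserWarning, match="inf"):
            value = compute_mdf(counts, OVCA_SPEC).loc["s"]
        assert np.isinf(value)
        with_pc = compute_mdf(counts, OVCA_SPEC, pseudo_count=1.0).loc["s"]
        assert with_pc == pytest.approx(16.0 / 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 100, (5, 10)),
            columns=[f"decile_{d}" for d in range(1, 11)],
            index=[f"s{i}" for i in range(5)],
        )
        base = compute_mdf(counts, OVCA_SPEC)
        scaled = compute_mdf(counts * 7, OVCA_SPEC)
        pd.testing.assert_series_equal(base, scaled)


def _cohort(seed, n=120, hr=3.0, frac_high=0.4, censor_rate=0.01):
    rng = np.random.default_rng(seed)
    score = rng.normal(0, 1, n)
    thr = np.quantile(score, 1 - frac_high)
    high = score > thr
    rate = 0.02 * hr**high.astype(float)
    time = rng.exponential(1 / rate)
    cens = rng.exponential(1 / censor_rate, n)
    surv = pd.DataFrame(
        {
            "time": np.minimum(time, cens),
            "event": (time <= cens).astype(int),
            "age": rng.normal(60, 10, n),
        },
        index=pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id"),
    )
    return pd.Series(score, index=surv.index, name="MDF"), surv, float(thr)


class TestOptimalCutpoint:
    def test_recovers_a_clean_threshold(self):
        score, surv, thr = _cohort(1, hr=6.0)
        result = optimal_cutpoint(score, surv, covariates=["age"])
        # chosen cutpoint induces nearly the true grouping
        est_groups = dichotomize(score, result.cutpoint)
        true_groups = (score > thr).astype(int)
        assert (est_groups == true_groups).mean() > 0.95

    def test_tie_breaks_to_smaller_cutpoint(self):
        # duplicated block design: two symmetric candidates with equal p
        score = pd.Series(
            [1.0, 1.0, 2.0, 2.0, 3.0, 3.0], index=[f"S{i}" for i in range(6)]
        )
        surv = pd.DataFrame(
            {"time": [5.0, 6, 1, 2, 5, 6], "event": [1, 1, 1, 1, 1, 1]},
            index=score.index,
        )
        res = optimal_cutpoint(score, surv, min_group_frac=0.2)
        cands = res.candidates
        best_p = cands["p"].min()
        tied = cands[np.isclose(cands["p"], best_p, rtol=1e-9)]
        assert res.cutpoint == tied["cutpoint"].min()

    def test_group_size_constraint_enforced(self):
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"S{i}" for i in range(4)])
        surv = pd.DataFrame(
            {"time": [1.0, 2, 3, 4], "event": [1, 1, 1, 1]}, index=score.index
        )
        with pytest.raises(ValueError, match="group-size|distinct"):
            optimal_cutpoint(score, surv, min_group_frac=0.9)

    def test_candidate_groups_meet_minimum_fraction(self):
        score, surv, _ = _cohort(2)
        res = optimal_cutpoint(score, surv, min_group_frac=0.2)
        n = len(score)
        assert (res.candidates[["n_high", "n_low"]].min(axis=1) >= 0.2 * n).all()

    def test_infinite_scores_count_as_high(self):
        score, surv, _ = _cohort(3, n=40)
        score.iloc[:3] = np.inf
        res = optimal_cutpoint(score, surv)
        groups = dichotomize(score, res.cutpoint)
        assert groups.iloc[:3].eq(1).all()


class TestInternalNewtonSolver:
    """The fast cutpoint-scan solver must agree with lifelines."""

    def test_coefficients_se_and_p_match_lifelines(self):
        score, surv, thr = _cohort(5, n=150)
        surv = surv.copy()
        surv["grp"] = (score > thr).astype(float)
        fit = fit_cox(surv, ["grp", "age"])
        ss = sort_survival(surv["time"].to_numpy(), surv["event"].to_numpy())
        X = surv[["grp", "age"]].to_numpy(float)
        beta, ll, cov = cox_newton(X, ss)
        assert np.exp(beta[0]) == pytest.approx(
            fit.terms.loc["grp", "hazard_ratio"], rel=1e-5
        )
        assert wald_p(beta, cov)[0] == pytest.approx(fit.terms.loc["grp", "p"], rel=1e-4)
        assert ll == pytest.approx(fit.log_likelihood, rel=1e-8)


class TestFitCox:
    def test_late_deaths_group_has_negative_log_hr(self):
        surv = pd.DataFrame(
            {
                "time": [1.0, 2, 3, 4, 5, 6],
                "event": [1, 1, 1, 1, 1, 1],
                "x": [0.0, 0, 0, 1, 1, 1],
            },
            index=[f"S{i}" for i in range(6)],
        )
        fit = fit_cox(surv, ["x"])
        assert fit.terms.loc["x", "hazard_ratio"] < 1.0

    def test_matches_bruteforce_partial_likelihood_on_toy(self):
        # interleaved groups so the partial-likelihood maximum is finite
        surv = pd.DataFrame(
            {
                "time": [1.0, 2, 3, 4, 5, 6],
                "event": [1, 1, 1, 1, 1, 1],
                "x": [1.0, 0, 0, 1, 0, 1],
            },
            index=[f"S{i}" for i in range(6)],
        )

        def neg_pl(beta):
            t = surv["time"].to_numpy()
            x = surv["x"].to_numpy()
            ll = 0.0
            for i in range(6):
                risk = x[t >= t[i]]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * risk)))
            return -ll

        best = optimize.minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded")
        fit = fit_cox(surv, ["x"])
        assert np.log(fit.terms.loc["x", "hazard_ratio"]) == pytest.approx(
            best.x, abs=1e-4
        )

    def test_duplicated_covariate_flagged(self):
        score, surv, _ = _cohort(6, n=60)
        surv = surv.copy()
        surv["age_copy"] = surv["age"]
        with pytest.raises(ValueError, match="rank-deficient|collinear"):
            fit_cox(surv, ["age", "age_copy"])

    def test_constant_term_rejected(self):
        score, surv, _ = _cohort(7, n=40)
        surv = surv.copy()
        surv["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_cox(surv, ["flat"])

    def test_categorical_reference_is_alphabetical(self):
        rng = np.random.default_rng(8)
        n = 80
        surv = pd.DataFrame(
            {
                "time": rng.exponential(20, n),
                "event": rng.integers(0, 2, n) | 1,
                "grade": rng.choice(["low", "high"], n),
            },
            index=[f"S{i}" for i in range(n)],
        )
        fit = fit_cox(surv, ["grade"])
        # "high" sorts first so "low" is the coded level
        assert any("grade_low" in str(t) for t in fit.terms.index)

    def test_hr_recovery_on_two_group_exponential(self):
        """True HR 2 at n = 500: Wald CI covers truth, point estimate close."""
        covered = 0
        near = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            n = 500
            grp = (rng.random(n) < 0.5).astype(float)
            rate = 0.02 * 2.0**grp
            time = rng.exponential(1 / rate)
            cens = rng.exponential(1 / 0.008, n)
            surv = pd.DataFrame(
                {
                    "time": np.minimum(time, cens),
                    "event": (time <= cens).astype(int),
                    "grp": grp,
                },
                index=[f"S{i}" for i in range(n)],
            )
            row = fit_cox(surv, ["grp"]).terms.loc["grp"]
            covered += row["ci_low"] <= 2.0 <= row["ci_high"]
            near += 1.7 <= row["hazard_ratio"] <= 2.35
        assert covered >= 0.9 * n_rep
        assert near >= 0.6 * n_rep


class TestBackwardAic:
    def _surv(self, seed, n=200, strong_coef=1.0):
        rng = np.random.default_rng(seed)
        strong = rng.normal(0, 1, n)
        noise = rng.normal(0, 1, n)
        rate = 0.02 * np.exp(strong_coef * strong)
        time = rng.exponential(1 / rate)
        cens = rng.exponential(60, n)
        grp = (rng.random(n) < 0.5).astype(int)
        return pd.DataFrame(
            {
                "time": np.minimum(time, cens),
                "event": (time <= cens).astype(int),
                "mdf_high": grp,
                "strong": strong,
                "noise": noise,
            },
            index=[f"S{i}" for i in range(n)],
        )

    def test_all_forced_is_a_noop(self):
        surv = self._surv(1)
        terms = ["mdf_high", "strong", "noise"]
        full = fit_cox(surv, terms)
        sel = backward_aic(surv, terms, forced=terms)
        assert sel.aic == pytest.approx(full.aic, rel=1e-12)
        assert sel.excluded_covariates == []

    def test_returned_aic_never_exceeds_full_model(self):
        for seed in range(5):
            surv = self._surv(seed)
            terms = ["mdf_high", "strong", "noise"]
            full = fit_cox(surv, terms)
            sel = backward_aic(surv, terms, forced=["mdf_high"])
            assert sel.aic <= full.aic + 1e-9
            assert "mdf_high" in sel.terms.index

    def test_strong_covariate_retained_noise_usually_dropped(self):
        kept_strong = 0
        dropped_noise = 0
        n_rep = 20
        for seed in range(n_rep):
            surv = self._surv(200 + seed)
            sel = backward_aic(
                surv, ["mdf_high", "strong", "noise"], forced=["mdf_high"]
            )
            kept_strong += "strong" in sel.retained_covariates
            dropped_noise += "noise" in sel.excluded_covariates
        assert kept_strong >= 0.9 * n_rep
        # a pure-noise term beats the AIC penalty with chance P(chi2_1 > 2) ~ 16%,
        # so expect it dropped most but not ~always
        assert dropped_noise >= 0.7 * n_rep


def test_km_table_uses_same_groups_as_cox_dichotomisation():
    score, surv, _ = _cohort(9, n=80)
    res = optimal_cutpoint(score, surv)
    groups = dichotomize(score, res.cutpoint)
    km = km_table(surv, groups.map({1: "high", 0: "low"}))
    assert set(km["group"]) == {"high", "low"}
    first_at_risk = km.groupby("group")["at_risk"].max()
    assert first_at_risk["high"] == int(groups.sum())
    assert first_at_risk["low"] == int((1 - groups).sum())
    assert ((km["survival"] >= 0) & (km["survival"] <= 1)).all()
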