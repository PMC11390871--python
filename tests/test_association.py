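"""Association layers: OLS wrapper, covariate models, prioritized
cross-domain regressions, zygosity-stratified z-tests, ExWAS, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from twinprox import (
    bh_fdr,
    cross_domain_models,
    exwas,
    fit_linear,
    pivot_wpps,
    simulate_cohort,
    standardize_features,
    stratified_z_comparison,
    wpps_covariate_models,
    compute_wpps,
)

from conftest import random_pairs_table, small_config


def cohort_wpps(seed=0, n_pairs=120, a2=0.5, c2=0.2, co_residence_prob=0.3):
    cohort = simulate_cohort(
        small_config(seed=seed, n_pairs=n_pairs, a2=a2, c2=c2, co_residence_prob=co_residence_prob)
    )
    tables = [
        compute_wpps(standardize_features(m), cohort.pairs, domain=d)
        for d, m in cohort.domains.items()
    ]
    return cohort, pivot_wpps(pd.concat(tables, ignore_index=True))


class TestFitLinear:
    def test_noiseless_slope_recovered(self):
        x = np.arange(10.0)
        res = fit_linear(2 * x, pd.DataFrame({"x": x}))
        assert res["estimate"].iloc[0] == pytest.approx(2.0, abs=1e-10)
        assert res["r_squared"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_regressor_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0]) - 1 / 3
        res = fit_linear(y, pd.DataFrame({"x": x}))
        assert res["estimate"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_solved_normal_equations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.5, 3.9, 4.1, 5.2])
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        res = fit_linear(y, pd.DataFrame({"x": x}))
        assert res["estimate"].iloc[0] == pytest.approx(beta[1], abs=1e-10)
        resid = y - X @ beta
        s2 = resid @ resid / 3
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res["se"].iloc[0] == pytest.approx(se, abs=1e-10)

    def test_p_consistent_with_t_statistic(self):
        rng = np.random.default_rng(3)
        res = fit_linear(rng.normal(size=30), pd.DataFrame({"x": rng.normal(size=30)}))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(res["statistic"].iloc[0]), df=28)
        assert res["p_nominal"].iloc[0] == pytest.approx(p, abs=1e-6)

    def test_rank_deficient_design_raises(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError, match="rank"):
            fit_linear(x, pd.DataFrame({"a": x, "b": 2 * x}))


class TestCovariateModels:
    def test_genetic_component_yields_positive_mz_coefficient(self):
        cohort, wide = cohort_wpps(seed=42, n_pairs=250)
        res = wpps_covariate_models(wide, cohort.pairs)
        row = res[(res["dependent"] == "proteome") & (res["independent"] == "zygosity_mz")]
        assert row["estimate"].iloc[0] > 0
        assert row["p_nominal"].iloc[0] < 0.05

    def test_no_genetic_component_centers_mz_coefficient_at_zero(self):
        ests = []
        for seed in range(20):
            cohort, wide = cohort_wpps(seed=seed, n_pairs=80, a2=0.0, c2=0.7)
            res = wpps_covariate_models(wide, cohort.pairs)
            row = res[
                (res["dependent"] == "proteome") & (res["independent"] == "zygosity_mz")
            ]
            ests.append(row["estimate"].iloc[0])
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) < 3 * sem

    def test_exposome_zygosity_null_when_coresidence_independent(self):
        ests = []
        for seed in range(20):
            cohort, wide = cohort_wpps(seed=100 + seed, n_pairs=80)
            res = wpps_covariate_models(wide, cohort.pairs)
            row = res[
                (res["dependent"] == "exposome") & (res["independent"] == "zygosity_mz")
            ]
            ests.append(row["estimate"].iloc[0])
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) < 3 * sem

    def test_single_zygosity_rejected(self, rng):
        pairs = random_pairs_table(20, rng)
        pairs["zygosity"] = "MZ"
        wide = pd.DataFrame({"d": rng.random(20)}, index=pairs["pair_id"])
        with pytest.raises(ValueError, match="MZ and DZ"):
            wpps_covariate_models(wide, pairs)


class TestCrossDomain:
    def test_priority_chooses_dependent(self, rng):
        pairs = random_pairs_table(60, rng)
        wide = pd.DataFrame(
            {"proteome": rng.random(60), "exposome": rng.random(60)},
            index=pairs["pair_id"],
        )
        res = cross_domain_models(wide, pairs)
        assert (res["dependent"] == "exposome").all()
        assert (res["independent"] == "proteome").all()

    def test_null_estimates_centered_at_zero(self, rng):
        ests = []
        for _ in range(50):
            pairs = random_pairs_table(100, rng)
            wide = pd.DataFrame(
                {"a": rng.random(100), "b": rng.random(100)}, index=pairs["pair_id"]
            )
            res = cross_domain_models(wide, pairs, priority=("a", "b"))
            ests.append(res["estimate"].iloc[0])
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) < 3 * sem

    def test_planted_slope_recovered(self, rng):
        pairs = random_pairs_table(250, rng)
        w1 = rng.random(250)
        w2 = 0.5 * w1 + rng.normal(0, 0.05, 250)
        wide = pd.DataFrame({"a": w2, "b": w1}, index=pairs["pair_id"])
        res = cross_domain_models(wide, pairs, priority=("a", "b"))
        row = res.iloc[0]
        assert abs(row["estimate"] - 0.5) < 3 * row["se"]

    def test_small_overlap_skipped_with_warning(self, rng):
        pairs = random_pairs_table(8, rng)
        wide = pd.DataFrame(
            {"a": rng.random(8), "b": rng.random(8)}, index=pairs["pair_id"]
        )
        with pytest.warns(UserWarning, match="overlapping"):
            res = cross_domain_models(wide, pairs)
        assert res.empty


class TestStratifiedZ:
    def make_wide(self, rng, n=200, slope_mz=0.5, slope_dz=0.5):
        pairs = random_pairs_table(n, rng)
        is_mz = (pairs["zygosity"] == "MZ").to_numpy()
        w1 = rng.normal(size=n)
        slope = np.where(is_mz, slope_mz, slope_dz)
        w2 = slope * w1 + rng.normal(0, 0.5, n)
        wide = pd.DataFrame({"a": w2, "b": w1}, index=pairs["pair_id"])
        return pairs, wide

    def test_z_and_p_match_manual_formula(self, rng):
        pairs, wide = self.make_wide(rng)
        r = stratified_z_comparison(wide, pairs, ("a", "b"), priority=("a", "b"))
        z = (r.b_mz - r.b_dz) / np.sqrt(r.se_mz**2 + r.se_dz**2)
        assert r.z == pytest.approx(z, abs=1e-12)
        assert r.p_one_sided == pytest.approx(1 - norm.cdf(z), abs=1e-12)

    def test_hand_computed_z_value(self):
        # bMZ=0.40/se 0.10 vs bDZ=0.10/se 0.10 -> z = 0.30/sqrt(0.02)
        z = (0.40 - 0.10) / np.sqrt(0.10**2 + 0.10**2)
        assert z == pytest.approx(2.1213, abs=1e-4)
        assert 1 - norm.cdf(z) == pytest.approx(0.0169, abs=2e-4)

    def test_scale_invariance_of_standardized_comparison(self, rng):
        pairs, wide = self.make_wide(rng)
        r1 = stratified_z_comparison(wide, pairs, ("a", "b"), priority=("a", "b"))
        scaled = wide.copy()
        scaled["a"] = scaled["a"] * 37.0
        scaled["b"] = scaled["b"] * 0.003
        r2 = stratified_z_comparison(scaled, pairs, ("a", "b"), priority=("a", "b"))
        assert r1.b_mz == pytest.approx(r2.b_mz, abs=1e-10)
        assert r1.z == pytest.approx(r2.z, abs=1e-10)

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(60):
            pairs, wide = self.make_wide(rng, n=120)
            r = stratified_z_comparison(wide, pairs, ("a", "b"), priority=("a", "b"))
            ps.append(r.p_one_sided)
        # equal planted slopes: one-sided p should not pile up near zero
        assert 0.2 < np.mean(ps) < 0.8

    def test_genetic_routing_increases_rejection_rate(self):
        """When the cross-domain coupling runs through the additive-genetic
        factor (stronger within-pair similarity coupling in MZ), the
        one-sided test rejects above the nominal level."""
        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(900 + seed)
            pairs = random_pairs_table(250, rng)
            is_mz = (pairs["zygosity"] == "MZ").to_numpy()
            w1 = rng.normal(size=250)
            slope = np.where(is_mz, 0.6, 0.15)
            w2 = slope * w1 + rng.normal(0, 0.5, 250)
            wide = pd.DataFrame({"a": w2, "b": w1}, index=pairs["pair_id"])
            r = stratified_z_comparison(wide, pairs, ("a", "b"), priority=("a", "b"))
            hits += r.p_one_sided < 0.05
        assert hits / n_rep > 0.2

    def test_degenerate_subsample_variance_raises(self, rng):
        pairs = random_pairs_table(40, rng)
        wide = pd.DataFrame(
            {"a": np.ones(40), "b": rng.normal(size=40)}, index=pairs["pair_id"]
        )
        with pytest.raises(ValueError, match="degenerate"):
            stratified_z_comparison(wide, pairs, ("a", "b"), priority=("a", "b"))


class TestBHFDR:
    def test_hand_step_up_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=12)
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_p_and_bounded(self, ps):
        ps = np.asarray(ps)
        q = bh_fdr(ps)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= ps - 1e-12)


class TestExWAS:
    def make_inputs(self, rng, n=150, effect=0.0):
        pairs = random_pairs_table(n, rng)
        w = rng.normal(0.7, 0.15, n)
        disc = pd.DataFrame(index=pd.Index(pairs["pair_id"], name="pair_id"))
        zw = (w - w.mean()) / w.std(ddof=1)
        p = np.clip(0.3 + effect * zw, 0.02, 0.98)
        disc["target"] = (rng.random(n) < p).astype(float)
        for k in range(3):
            disc[f"null{k}"] = (rng.random(n) < 0.3).astype(float)
        wide = pd.DataFrame({"proteome": w}, index=pairs["pair_id"])
        return pairs, wide, disc

    def test_reduces_to_mean_difference_without_covariate(self, rng):
        pairs, wide, disc = self.make_inputs(rng)
        res = exwas(wide, disc, pairs, include_age_covariate=False)
        row = res[res["independent"] == "target"].iloc[0]
        d = disc["target"]
        oracle = wide.loc[d == 1, "proteome"].mean() - wide.loc[d == 0, "proteome"].mean()
        assert row["estimate"] == pytest.approx(oracle, abs=1e-10)

    def test_negative_coupling_recovers_negative_estimate(self, rng):
        pairs, wide, disc = self.make_inputs(rng, n=250, effect=-0.3)
        res = exwas(wide, disc, pairs)
        row = res[res["independent"] == "target"].iloc[0]
        assert row["estimate"] < 0
        assert row["q_fdr"] < 0.2

    def test_missing_discordance_dropped_per_variable(self, rng):
        pairs, wide, disc = self.make_inputs(rng)
        disc.loc[disc.index[:10], "target"] = np.nan
        res = exwas(wide, disc, pairs)
        row = res[res["independent"] == "target"].iloc[0]
        assert row["n_pairs"] == len(pairs) - 10

    def test_degenerate_variable_skipped(self, rng):
        pairs, wide, disc = self.make_inputs(rng)
        disc["flat"] = 0.0
        with pytest.warns(UserWarning, match="flat"):
            res = exwas(wide, disc, pairs)
        assert "flat" not in set(res["independent"])

    def test_fdr_families_per_domain_vs_pooled(self, rng):
        pairs, wide, disc = self.make_inputs(rng)
        wide["metabolome"] = rng.normal(0.6, 0.1, len(pairs))
        per = exwas(wide, disc, pairs, fdr_family="per-domain")
        pooled = exwas(wide, disc, pairs, fdr_family="pooled")
        for domain in ("proteome", "metabolome"):
            mask = per["dependent"] == domain
            np.testing.assert_allclose(
                per.loc[mask, "q_fdr"],
                bh_fdr(per.loc[mask, "p_nominal"].to_numpy()),
                atol=1e-12,
            )
        np.testing.assert_allclose(
            pooled["q_fdr"], bh_fdr(pooled["p_nominal"].to_numpy()), atol=1e-12
        )

    def test_non_binary_discordance_rejected(self, rng):
        pairs, wide, disc = self.make_inputs(rng)
        disc.iloc[0, 0] = 2.0
        with pytest.raises(ValueError, match="0, 1 or missing"):
            exwas(wide, disc, pairs)
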