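"""Imputation, moderated regression, q-values, stability aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from lfqstab import (EBPrior, ImputationSpec, ModeratedStabilitySelector,
                     compute_qvalues, estimate_eb_prior, fit_linear_models,
                     impute_once, moderate, stability_aggregate)
from lfqstab.errors import (AggregationError, DesignError, ImputationError,
                            ValidationError)


def _design(n=3, batches=1):
    samples = [f"d{i}" for i in range(n)] + [f"n{i}" for i in range(n)]
    return pd.DataFrame({
        "sample": samples,
        "group": ["DM"] * n + ["NDM"] * n,
        "batch": [f"B{(i % batches) + 1}" for i in range(n)] * 2})


class TestImputation:
    def test_fully_observed_matrix_unchanged(self, tiny_design):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["p1"],
                         columns=["s1", "s2", "s3", "s4"])
        pd.testing.assert_frame_equal(impute_once(m, tiny_design, 0), m)

    def test_determinism_and_missing_only_replacement(self):
        design = _design(4)
        rng = np.random.default_rng(1)
        values = rng.normal(20, 1, size=(5, 8))
        mask = rng.random((5, 8)) < 0.3
        values[mask] = np.nan
        # keep >= 2 observed per group
        values[:, :2] = rng.normal(20, 1, size=(5, 2))
        values[:, 4:6] = rng.normal(20, 1, size=(5, 2))
        m = pd.DataFrame(values, index=[f"p{i}" for i in range(5)],
                         columns=design["sample"])
        a = impute_once(m, design, 7)
        b = impute_once(m, design, 7)
        c = impute_once(m, design, 8)
        pd.testing.assert_frame_equal(a, b)
        assert not a.isna().any().any()
        observed = m.notna()
        pd.testing.assert_frame_equal(a[observed], m[observed])
        # different seeds differ only at originally-missing cells
        diff = (a != c) & a.notna()
        assert diff.to_numpy().sum() > 0
        assert not (diff & observed).to_numpy().any()

    def test_imputed_values_match_observed_moments(self):
        # protein with observed DM mean 20, sd 1 and 3 missing DM entries
        design = _design(6)
        row = [20.5, 19.5, 21.0, np.nan, np.nan, np.nan,
               20.0, 20.0, 20.0, 20.0, 20.0, 20.0]
        m = pd.DataFrame([row], index=["p1"], columns=design["sample"])
        obs = np.array(row[:3])
        draws = []
        for s in range(3000):
            out = impute_once(m, design, s)
            draws.extend(out.iloc[0, 3:6])
        draws = np.asarray(draws)
        se = obs.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - obs.mean()) < 3 * se
        assert abs(draws.std() - obs.std(ddof=1)) < 0.05

    def test_insufficient_observations_raise_naming_protein(self):
        design = _design(3)
        m = pd.DataFrame([[1.0, np.nan, np.nan, 1.0, 2.0, 3.0]],
                         index=["sparse"], columns=design["sample"])
        with pytest.raises(ImputationError, match="sparse"):
            impute_once(m, design, 0)


class TestLinearModels:
    def test_hand_computed_two_group_fit(self):
        design = _design(3)
        m = pd.DataFrame([[1.0, 2, 3, 2, 3, 4]], index=["p1"],
                         columns=design["sample"])
        fit = fit_linear_models(m, design)
        assert fit.loc["p1", "coef"] == pytest.approx(-1.0)
        assert fit.loc["p1", "s_sq"] == pytest.approx(1.0)
        assert fit.loc["p1", "df_residual"] == 4
        t = fit.loc["p1", "coef"] / fit.loc["p1", "se"]
        assert t == pytest.approx(-1.224744871, abs=1e-8)

    def test_equal_group_means_give_zero_coefficient(self):
        design = _design(3)
        m = pd.DataFrame([[5.0, 6, 7, 5, 6, 7]], index=["p1"],
                         columns=design["sample"])
        assert fit_linear_models(m, design).loc["p1", "coef"] == pytest.approx(0.0)

    def test_batch_shift_moves_only_batch_coefficient(self):
        design = _design(4, batches=2)
        rng = np.random.default_rng(0)
        base = pd.DataFrame(rng.normal(20, 1, (6, 8)),
                            index=[f"p{i}" for i in range(6)],
                            columns=design["sample"])
        shifted = base.copy()
        b2 = design.loc[design.batch == "B2", "sample"]
        shifted[b2] = shifted[b2] + 3.0
        f0 = fit_linear_models(base, design)
        f1 = fit_linear_models(shifted, design)
        np.testing.assert_allclose(f0["coef"], f1["coef"], atol=1e-10)
        np.testing.assert_allclose(f0["s_sq"], f1["s_sq"], atol=1e-10)

    def test_confounded_design_rejected_before_fitting(self):
        design = _design(2)
        design["batch"] = np.where(design.group == "DM", "B1", "B2")
        m = pd.DataFrame([[1.0, 2, 3, 4]], index=["p1"],
                         columns=design["sample"])
        with pytest.raises(DesignError):
            fit_linear_models(m, design)


def _simulate_s_sq(rng, n, d0, s0_sq, df):
    sigma_sq = s0_sq * d0 / rng.chisquare(d0, n)
    return sigma_sq * rng.chisquare(df, n) / df, sigma_sq


class TestEBPrior:
    def test_equal_variances_give_infinite_prior_df(self):
        prior = estimate_eb_prior([0.5] * 20, 10)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.5)

    def test_recovers_generating_hyperparameters(self):
        rng = np.random.default_rng(12)
        s_sq, _ = _simulate_s_sq(rng, 5000, d0=4.0, s0_sq=1.0, df=17)
        prior = estimate_eb_prior(s_sq, 17)
        assert abs(prior.d0 - 4.0) / 4.0 < 0.2
        assert abs(prior.s0_sq - 1.0) < 0.1

    def test_agrees_with_grid_search_likelihood_oracle(self):
        # independent oracle: maximize the scaled-F likelihood of s^2 on a grid
        rng = np.random.default_rng(5)
        df = 12
        s_sq, _ = _simulate_s_sq(rng, 2000, d0=6.0, s0_sq=0.5, df=df)
        d0_grid = np.linspace(2.0, 12.0, 81)
        s0_grid = np.linspace(0.3, 0.8, 81)
        best, best_ll = None, -np.inf
        for d0 in d0_grid:
            for s0 in s0_grid:
                ll = stats.f.logpdf(s_sq, df, d0, scale=s0).sum()
                if ll > best_ll:
                    best, best_ll = (d0, s0), ll
        prior = estimate_eb_prior(s_sq, df)
        assert abs(prior.d0 - best[0]) <= 1.0       # within ~grid resolution
        assert abs(prior.s0_sq - best[1]) <= 0.05

    def test_zero_variances_excluded(self):
        prior = estimate_eb_prior([0.0, 0.0, 1.0, 1.0, 1.0], 8)
        assert prior.s0_sq == pytest.approx(1.0)

    def test_too_few_variances_raise(self):
        from lfqstab.errors import EstimationError
        with pytest.raises(EstimationError):
            estimate_eb_prior([0.0, 1.0], 8)


def _classical_ols_oracle(matrix, design):
    """From-scratch per-protein OLS via statsmodels, for cross-checking."""
    d = design.set_index("sample").loc[list(matrix.columns)]
    X = pd.get_dummies(d[["group", "batch"]], drop_first=False)
    cols = ["group_DM"] + [c for c in X.columns if c.startswith("batch_")][1:]
    X = sm.add_constant(X[cols].astype(float))
    out = []
    for _, row in matrix.iterrows():
        fit = sm.OLS(row.to_numpy(), X).fit()
        out.append((fit.params["group_DM"], fit.tvalues["group_DM"],
                    fit.pvalues["group_DM"]))
    return pd.DataFrame(out, columns=["coef", "t", "p"], index=matrix.index)


class TestModeration:
    def _fits(self, n_proteins=100, seed=0):
        rng = np.random.default_rng(seed)
        design = _design(5, batches=2)
        m = pd.DataFrame(rng.normal(20, 1, (n_proteins, 10)),
                         index=[f"p{i}" for i in range(n_proteins)],
                         columns=design["sample"])
        return fit_linear_models(m, design), design, m

    def test_d0_zero_recovers_classical_ols(self):
        fits, design, m = self._fits()
        mod = moderate(fits, EBPrior(d0=0.0, s0_sq=1.0))
        oracle = _classical_ols_oracle(m, design)
        np.testing.assert_allclose(mod["coef"], oracle["coef"], atol=1e-10)
        np.testing.assert_allclose(mod["t_mod"], oracle["t"], atol=1e-10)
        np.testing.assert_allclose(mod["p"], oracle["p"], atol=1e-10)

    def test_d0_infinity_pools_all_variances(self):
        fits, _, _ = self._fits()
        mod = moderate(fits, EBPrior(d0=math.inf, s0_sq=0.9))
        np.testing.assert_allclose(mod["s_tilde_sq"], 0.9)
        # t ordering equals |coef| ordering under a common variance
        order_t = mod["t_mod"].abs().sort_values().index
        order_c = mod["coef"].abs().sort_values().index
        assert list(order_t) == list(order_c)

    def test_shrinkage_reduces_variance_estimation_error(self):
        rng = np.random.default_rng(3)
        df, d0, s0 = 10, 5.0, 0.4
        s_sq, sigma_sq = _simulate_s_sq(rng, 3000, d0, s0, df)
        fits = pd.DataFrame({"coef": 0.0, "se": 1.0, "s_sq": s_sq,
                             "df_residual": df, "c_dd": 0.2})
        prior = estimate_eb_prior(s_sq, df)
        mod = moderate(fits, prior)
        mse_raw = np.mean((s_sq - sigma_sq) ** 2)
        mse_mod = np.mean((mod["s_tilde_sq"] - sigma_sq) ** 2)
        assert mse_mod <= mse_raw


class TestQValues:
    def test_bh_hand_oracle(self):
        np.testing.assert_allclose(
            compute_qvalues([0.01, 0.02, 0.03, 0.04], "bh"),
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert compute_qvalues([0.01], "bh")[0] == pytest.approx(0.01)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bh_dominates_p_and_is_order_equivariant(self, p):
        q = compute_qvalues(p, "bh")
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = compute_qvalues(np.asarray(p)[perm], "bh")
        np.testing.assert_allclose(q_perm, q[perm])

    def test_storey_scales_bh_by_pi0(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.uniform(0, 1, 300), rng.uniform(0, 0.001, 60)])
        pi0 = min(1.0, np.mean(p > 0.5) / 0.5)
        np.testing.assert_allclose(compute_qvalues(p, "storey"),
                                   np.minimum(pi0 * compute_qvalues(p, "bh"), 1))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            compute_qvalues([0.5, 1.5])


class TestStabilityAggregation:
    def _rounds(self, qs, m=50):
        rounds = []
        for r in range(m):
            rounds.append(pd.DataFrame({
                "coef": [-1.0], "t_mod": [-3.0], "q": [qs[r]],
            }, index=pd.Index(["FASN-like"], name="protein_id")))
        return rounds

    @pytest.mark.parametrize("n_sig,called", [(34, True), (29, False),
                                              (30, True), (50, True)])
    def test_pass_count_threshold_at_30_of_50(self, n_sig, called):
        qs = [0.05] * n_sig + [0.5] * (50 - n_sig)
        res = stability_aggregate(self._rounds(qs), ImputationSpec(50))
        row = res.iloc[0]
        assert row.n_pass == n_sig
        assert row.pass_rate == pytest.approx(n_sig / 50)
        assert bool(row.called) is called
        assert row.direction == ("down" if called else "none")
        assert row.fold_change == pytest.approx(0.5)

    def test_min_pass_scales_with_round_count(self):
        qs = [0.05] * 6 + [0.5] * 4
        res = stability_aggregate(self._rounds(qs, m=10), ImputationSpec(10))
        assert bool(res.iloc[0].called) is True  # 6 >= ceil(0.6*10)
        qs = [0.05] * 5 + [0.5] * 5
        res = stability_aggregate(self._rounds(qs, m=10), ImputationSpec(10))
        assert bool(res.iloc[0].called) is False

    def test_inconsistent_protein_sets_rejected(self):
        rounds = self._rounds([0.05] * 50)
        rounds[10] = rounds[10].rename(index={"FASN-like": "other"})
        with pytest.raises(AggregationError):
            stability_aggregate(rounds, ImputationSpec(50))


class TestSelector:
    def test_fit_is_reproducible_and_coherent(self, small_study):
        from lfqstab import median_normalize, route_by_missingness
        matrix, design, _ = small_study
        norm = median_normalize(matrix)
        routing = route_by_missingness(norm, design)
        sub = norm.loc[routing.quantitative_ids[:150]]
        a = ModeratedStabilitySelector(n_imputations=4, random_state=3).fit(sub, design)
        b = ModeratedStabilitySelector(n_imputations=4, random_state=3).fit(sub, design)
        pd.testing.assert_frame_equal(a.results_, b.results_)
        pd.testing.assert_frame_equal(a.per_round_, b.per_round_)
        # coherence: always-significant => called; never-significant => not
        per_q = a.per_round_.pivot(index="protein_id", columns="round", values="q")
        always = per_q.index[(per_q < 0.1).all(axis=1)]
        never = per_q.index[(per_q >= 0.1).all(axis=1)]
        assert a.results_.loc[always, "called"].all()
        assert not a.results_.loc[never, "called"].any()

    def test_min_pass_validation(self, small_study):
        matrix, design, _ = small_study
        with pytest.raises(ValidationError):
            ModeratedStabilitySelector(n_imputations=5, min_pass=10).fit(
                matrix, design)
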