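"""Normalization and the three per-spot significance frameworks."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from digeflow import io, simulate, spotstats


def _table(sheet, values, log=False, norm=False, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"SSP{i}" for i in range(values.shape[0])]
    return io.SpotTable(ids, values, sheet, log_transformed=log, normalized=norm)


CONDS = np.repeat(["control", "anoxia", "reaeration"], 3)
REPS = np.tile([1, 2, 3], 3)


class TestLog2AndAverage:
    def test_log2_values(self, two_sample_sheet):
        out = spotstats.log2_and_average(_table(two_sample_sheet, [[8.0, 1.0]]))
        np.testing.assert_allclose(out.matrix, [[3.0, 0.0]])
        assert out.log_transformed

    def test_technical_duplicates_averaged_on_log_scale(self):
        # two columns of the same (organ, condition, replicate) sample
        sheet = io.SampleSheet(pd.DataFrame({
            "sample_id": ["a1", "a2"], "organ": ["shoot"] * 2,
            "condition": ["control", "control"], "replicate": [1, 1],
            "gel_id": ["g1", "g2"],
        }))
        out = spotstats.log2_and_average(_table(sheet, [[2.0, 4.0]]))
        assert out.matrix.shape == (1, 1)
        assert out.matrix[0, 0] == pytest.approx(1.5)  # (log2 2 + log2 4) / 2

    def test_zero_replaced_by_half_column_minimum(self, two_sample_sheet):
        with pytest.warns(UserWarning, match="zero"):
            out = spotstats.log2_and_average(
                _table(two_sample_sheet, [[0.0, 8.0], [4.0, 2.0]]))
        assert out.matrix[0, 0] == pytest.approx(np.log2(2.0))  # half of 4

    def test_all_zero_spot_excluded_with_warning(self, two_sample_sheet):
        with pytest.warns(UserWarning, match="SSP0"):
            out = spotstats.log2_and_average(
                _table(two_sample_sheet, [[0.0, 0.0], [4.0, 2.0]]))
        assert out.spot_ids == ["SSP1"]


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self, two_sample_sheet):
        t = _table(two_sample_sheet, [[1, 1], [2, 2], [3, 3]], log=True)
        out = spotstats.quantile_normalize(t)
        np.testing.assert_allclose(out.matrix, t.matrix)

    def test_hand_computed_mean_of_order_statistics(self, two_sample_sheet):
        t = _table(two_sample_sheet, [[1, 2], [2, 4], [3, 6]], log=True)
        out = spotstats.quantile_normalize(t)
        np.testing.assert_allclose(out.matrix, [[1.5, 1.5], [3, 3], [4.5, 4.5]])

    def test_columns_share_sorted_values_and_means(self, null_log2_table):
        out = spotstats.quantile_normalize(null_log2_table)
        s = np.sort(out.matrix, axis=0)
        for j in range(1, s.shape[1]):
            np.testing.assert_allclose(s[:, j], s[:, 0])
        np.testing.assert_allclose(out.matrix.mean(axis=0),
                                   out.matrix.mean(axis=0)[0])

    def test_idempotent(self, null_log2_table):
        once = spotstats.quantile_normalize(null_log2_table)
        twice = spotstats.quantile_normalize(once)
        np.testing.assert_allclose(twice.matrix, once.matrix)

    def test_within_column_ranks_preserved(self, null_log2_table):
        out = spotstats.quantile_normalize(null_log2_table)
        for j in range(out.matrix.shape[1]):
            assert (np.argsort(out.matrix[:, j]) ==
                    np.argsort(null_log2_table.matrix[:, j])).all()

    def test_missing_values_flagged_and_assigned_by_rank(self, two_sample_sheet):
        t = _table(two_sample_sheet, [[1, 2], [2, np.nan], [3, 6]], log=True)
        with pytest.warns(UserWarning, match="missing"):
            out = spotstats.quantile_normalize(t)
        assert np.isnan(out.matrix[1, 1])
        assert np.isfinite(out.matrix[[0, 2], 1]).all()


class TestKruskal:
    def test_hand_computed_h_statistic(self):
        # ranks 1..6, tie-free: H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2
        H, p, flag = spotstats.kruskal_test(
            [np.array([1, 2]), np.array([3, 4]), np.array([5, 6])])
        rbar = [1.5, 3.5, 5.5]
        H_hand = 12.0 / (6 * 7) * sum(2 * (r - 3.5) ** 2 for r in rbar)
        assert H == pytest.approx(H_hand)
        assert H == pytest.approx(4.571, abs=5e-4)

    def test_identical_groups_give_zero_h(self):
        H, _, _ = spotstats.kruskal_test([np.array([1.0, 2, 3])] * 3)
        assert H == pytest.approx(0.0, abs=1e-12)

    def test_constant_data_flagged_with_p_one(self):
        H, p, flag = spotstats.kruskal_test([np.array([5.0, 5]), np.array([5.0, 5])])
        assert np.isnan(H) and p == 1.0 and flag == "constant"

    def test_invariant_to_within_group_ordering(self):
        g = [np.array([3, 1, 7.0]), np.array([2, 9, 4.0]), np.array([6, 5, 8.0])]
        H1, _, _ = spotstats.kruskal_test(g)
        H2, _, _ = spotstats.kruskal_test([x[::-1] for x in g])
        assert H1 == pytest.approx(H2)

    def test_small_sample_p_values_are_valid(self):
        """KW p at 3x3 is discrete; the chi-square p must still be valid:
        P(p <= alpha) <= alpha under the null (up to Monte-Carlo error)."""
        rng = np.random.default_rng(0)
        ps = np.array([
            spotstats.kruskal_test([rng.normal(size=3) for _ in range(3)])[1]
            for _ in range(2000)
        ])
        for alpha in (0.01, 0.05, 0.1):
            assert (ps <= alpha).mean() <= alpha + 0.01


class TestMixedModel:
    def test_zero_variance_component_reduces_to_oneway_anova(self):
        # replicate (group) means identical across replicates -> lambda = 0
        y = np.array([1.3, 0.7, 1.0, 2.7, 3.0, 3.3, 2.0, 2.3, 1.7])
        F, p, lam, flag = spotstats.mixed_model_test(y, CONDS, REPS)
        Fa, pa = stats.f_oneway(y[:3], y[3:6], y[6:])
        if lam == 0.0:
            assert F == pytest.approx(Fa)
            assert p == pytest.approx(pa)
        else:  # construction guarantees a zero between-replicate effect
            pytest.fail(f"expected boundary REML estimate, got lambda={lam}")

    def test_location_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=9)
        F1, p1, _, _ = spotstats.mixed_model_test(y, CONDS, REPS)
        F2, p2, _, _ = spotstats.mixed_model_test(y + 1e3, CONDS, REPS)
        assert F1 == pytest.approx(F2, rel=1e-6)
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_variance_ratio_recovery_on_planted_data(self):
        """Planted random intercepts (sigma_b=1, sigma_e=0.1): the median
        REML variance-ratio estimate over 200 seeds lies within 50% of the
        true ratio 100, cross-checked against direct numerical maximization
        of the restricted likelihood in the (log sigma_b^2, log sigma_e^2)
        parametrization."""
        from scipy.optimize import minimize

        truth = (1.0 / 0.1) ** 2
        lams, oracle_lams = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            b = rng.normal(0, 1.0, 3)
            y = b[np.tile([0, 1, 2], 3)] + rng.normal(0, 0.1, 9)
            _, _, lam, _ = spotstats.mixed_model_test(y, CONDS, REPS)
            lams.append(lam)
            if seed < 20:  # oracle cross-check on a subset
                X = np.column_stack([np.ones(9), CONDS == "anoxia",
                                     CONDS == "reaeration"]).astype(float)
                Z = np.column_stack([(REPS == g).astype(float) for g in (1, 2, 3)])

                def neg_restricted_ll(theta):
                    sb2, se2 = np.exp(theta)
                    V = se2 * np.eye(9) + sb2 * Z @ Z.T
                    Vi = np.linalg.inv(V)
                    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
                    r = y - X @ beta
                    return 0.5 * (np.linalg.slogdet(V)[1]
                                  + np.linalg.slogdet(X.T @ Vi @ X)[1]
                                  + r @ Vi @ r)

                res = minimize(neg_restricted_ll, x0=[0.0, -2.0], method="Nelder-Mead",
                               options={"xatol": 1e-12, "fatol": 1e-14,
                                        "maxiter": 5000})
                sb2, se2 = np.exp(res.x)
                oracle_lams.append(sb2 / se2)
        med = np.median(lams)
        assert abs(med - truth) / truth <= 0.5
        np.testing.assert_allclose(np.array(lams[:20]), np.array(oracle_lams),
                                   rtol=1e-3, atol=1e-4)

    def test_confounded_layout_is_an_error(self):
        y = np.arange(9.0)
        groups = np.repeat(["a", "b", "c"], 3)  # one group per condition
        with pytest.raises(ValueError, match="confounded"):
            spotstats.mixed_model_test(y, CONDS, groups)

    def test_null_p_values_are_calibrated(self):
        rng_master = np.random.default_rng(100)
        ps = []
        for _ in range(400):
            b = rng_master.normal(0, 0.5, 3)
            y = b[np.tile([0, 1, 2], 3)] + rng_master.normal(0, 1.0, 9)
            ps.append(spotstats.mixed_model_test(y, CONDS, REPS)[1])
        ps = np.asarray(ps)
        assert (ps <= 0.05).mean() == pytest.approx(0.05, abs=0.03)


class TestModerated:
    def _toy_table(self, n=12, seed=0, sd_spread=True):
        rng = np.random.default_rng(seed)
        sd = rng.uniform(0.2, 2.0, n) if sd_spread else np.ones(n)
        X = rng.normal(0, 1, (n, 9)) * sd[:, None] + 10
        return _table(simulate.default_design(), X, log=True, norm=True)

    def test_posterior_variance_between_s2_and_prior(self):
        table = self._toy_table()
        prior, res = spotstats.moderated_test(table)
        lo = np.minimum(res["s2"], prior.s0_sq)
        hi = np.maximum(res["s2"], prior.s0_sq)
        assert ((res["s2_post"] >= lo - 1e-12) & (res["s2_post"] <= hi + 1e-12)).all()
        assert (res["statistic"] >= 0).all()

    def test_infinite_prior_df_override_pins_posterior_at_prior(self):
        table = self._toy_table()
        prior = spotstats.ModerationPrior(d0=float("inf"), s0_sq=0.7)
        _, res = spotstats.moderated_test(table, prior=prior)
        np.testing.assert_allclose(res["s2_post"], 0.7)

    def test_equal_residual_variances_give_infinite_d0(self):
        # identical residual pattern for every spot -> zero spread of
        # log-variances -> d0 = inf; the prior variance carries the
        # chi-square log-bias correction exp(log(d/2) - digamma(d/2)), and
        # every moderated F becomes the same multiple of the ordinary F
        from scipy.special import digamma

        sheet = simulate.default_design()
        base = np.array([1.0, 2, 3, 1, 2, 3, 1, 2, 3])
        X = np.vstack([base + shift for shift in np.arange(8.0)])
        table = _table(sheet, X, log=True, norm=True)
        prior, res = spotstats.moderated_test(table)
        assert np.isinf(prior.d0)
        s2 = res["s2"].iloc[0]
        assert prior.s0_sq == pytest.approx(
            s2 * np.exp(np.log(3.0) - digamma(3.0)))
        np.testing.assert_allclose(res["s2_post"], prior.s0_sq)

    def test_matches_limma_oracle(self, tmp_path):
        """d0, s0^2, moderated F and p agree with the reference
        empirical-Bayes implementation in Bioconductor's limma."""
        table = self._toy_table(n=15, seed=4)
        mat_path = tmp_path / "m.csv"
        out_path = tmp_path / "limma.csv"
        pd.DataFrame(table.matrix).to_csv(mat_path, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.csv("{mat_path}"))
            cond <- factor(rep(c("C","A","R"), each=3), levels=c("C","A","R"))
            design <- model.matrix(~cond)
            fit <- eBayes(lmFit(m, design))
            tt <- topTable(fit, coef=2:3, number=Inf, sort.by="none")
            write.csv(data.frame(d0=fit$df.prior, s0=fit$s2.prior,
                                 F=tt$F, p=tt$P.Value),
                      "{out_path}", row.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        ref = pd.read_csv(out_path)
        prior, res = spotstats.moderated_test(table)
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert prior.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(res["statistic"], ref["F"], rtol=1e-5)
        np.testing.assert_allclose(res["p_raw"], ref["p"], rtol=1e-4)

    def test_null_p_values_uniform(self, design):
        rng = np.random.default_rng(11)
        X = rng.normal(10, 0.5, (1000, 9))
        table = _table(design, X, log=True, norm=True)
        _, res = spotstats.moderated_test(table)
        assert stats.kstest(res["p_raw"], "uniform").pvalue > 0.01


class TestAdjustSelect:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(spotstats.adjust_pvalues([0.2], "BH"), [0.2])

    def test_bh_step_up_by_hand(self):
        np.testing.assert_allclose(
            spotstats.adjust_pvalues([0.01, 0.02, 0.03], "BH"), [0.03, 0.03, 0.03])

    def test_holm_step_down_by_hand(self):
        np.testing.assert_allclose(
            spotstats.adjust_pvalues([0.01, 0.04], "Holm"), [0.02, 0.04])

    def test_fdr_is_an_alias_of_bh(self):
        p = [0.01, 0.5, 0.04]
        np.testing.assert_array_equal(spotstats.adjust_pvalues(p, "FDR"),
                                      spotstats.adjust_pvalues(p, "BH"))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_never_below_raw_and_capped(self, p):
        for method in ("BH", "Holm"):
            adj = spotstats.adjust_pvalues(p, method)
            assert (adj >= np.asarray(p) - 1e-12).all()
            assert (adj <= 1.0 + 1e-12).all()

    @given(st.lists(st.floats(min_value=1e-6, max_value=1), min_size=2, max_size=30,
                    unique=True))
    def test_bh_monotone_in_raw_p_rank(self, p):
        adj = spotstats.adjust_pvalues(p, "BH")
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_select_orders_by_p_then_id(self):
        frame = pd.DataFrame({"spot_id": ["b", "a", "c"],
                              "p_adj": [0.01, 0.01, 0.2]})
        assert spotstats.select_significant(frame, 0.05) == ["a", "b"]
        assert spotstats.select_significant(frame, 1.0) == ["a", "b", "c"]


class TestFisher:
    def test_saturated_table_p_is_one(self):
        u = set(range(10))
        _, p = spotstats.overrepresentation_test(u, u, u)
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        # 2x2 table a=3 b=1 c=1 d=5: hits of size 4 from universe of 10,
        # category of size 4; P(X >= 3) by direct enumeration
        from math import comb

        hits = {0, 1, 2, 3}
        category = {0, 1, 2, 4}
        universe = set(range(10))
        _, p = spotstats.overrepresentation_test(hits, category, universe)
        enum = sum(comb(4, x) * comb(6, 4 - x) for x in (3, 4)) / comb(10, 4)
        assert p == pytest.approx(enum, rel=1e-12)

    def test_disjoint_hits_p_is_one_under_greater_tail(self):
        universe = set(range(8))
        _, p = spotstats.overrepresentation_test({0, 1}, {6, 7}, universe)
        assert p == pytest.approx(1.0)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError, match="universe"):
            spotstats.overrepresentation_test(set(), set(), set())
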