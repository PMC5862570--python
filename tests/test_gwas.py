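"""Cumulative-logit association: probabilities, fitting, Wald testing."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

import netheat as nh
from netheat.gwas import (
    CumulativeLogitFit,
    _binlogit_assoc,
    fit_cumlogit_null,
    likelihood_ratio_test,
)


def simulate_table(a1, a2, beta, n_cases, n_controls, seed):
    """Draw (y, x) vectors from the cumulative-logit model itself."""
    rng = np.random.default_rng(seed)
    x = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    q1 = expit(a1 + beta * x)
    q2 = expit(a2 + beta * x)
    u = rng.random(x.size)
    y = np.where(u < q1, 0, np.where(u < q2, 1, 2))
    return y, x


class TestCumlogitProbs:
    def test_ordered_intercepts_required(self):
        with pytest.raises(ValueError, match="alpha1 < alpha2"):
            nh.cumlogit_probs(1.0, 1.0, 0.0, 0)

    def test_logistic_at_zero(self):
        p1, _, _ = nh.cumlogit_probs(0.0, 30.0, 0.0, 0)
        assert p1 == pytest.approx(0.5)

    def test_top_category_vanishes_for_large_alpha2(self):
        _, _, p3 = nh.cumlogit_probs(0.0, 40.0, 0.0, 1)
        assert p3 == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_logistic(self):
        # Q1 = sigma(-1 + 0.5), Q2 = sigma(1 + 0.5) evaluated independently
        p1, p2, p3 = nh.cumlogit_probs(-1.0, 1.0, 0.5, 1)
        q1 = 1 / (1 + np.exp(0.5))
        q2 = 1 / (1 + np.exp(-1.5))
        assert p1 == pytest.approx(q1, rel=1e-12)
        assert p2 == pytest.approx(q2 - q1, rel=1e-12)
        assert p3 == pytest.approx(1 - q2, rel=1e-12)

    def test_probabilities_sum_to_one_exactly(self, rng):
        for _ in range(25):
            a1 = rng.normal()
            a2 = a1 + rng.exponential() + 1e-3
            p = nh.cumlogit_probs(a1, a2, rng.normal(), int(rng.integers(0, 2)))
            assert sum(p) == pytest.approx(1.0, abs=1e-15)
            assert min(p) >= 0


class TestFitCumlogit:
    def test_null_symmetry_gives_zero_beta(self):
        # identical genotype tables in cases and controls
        block = [0] * 10 + [1] * 12 + [2] * 5
        y = np.array(block + block)
        x = np.array([1] * len(block) + [0] * len(block))
        fit = nh.fit_cumlogit(y, x)
        assert fit.converged
        assert fit.beta == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_large_n(self):
        y, x = simulate_table(-0.5, 0.8, 1.0, 10_000, 10_000, seed=5)
        fit = nh.fit_cumlogit(y, x)
        assert fit.converged
        assert 0.9 <= fit.beta <= 1.1
        assert fit.alpha1 < fit.alpha2

    def test_loglik_dominates_null_profile(self):
        y, x = simulate_table(-0.3, 0.9, 0.8, 200, 300, seed=7)
        fit = nh.fit_cumlogit(y, x)
        assert fit.loglik >= fit_cumlogit_null(y, x) - 1e-10

    def test_matches_statsmodels_ordered_model(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        y, x = simulate_table(-0.4, 0.7, 0.6, 800, 1200, seed=3)
        fit = nh.fit_cumlogit(y, x)
        sm = OrderedModel(y, x[:, None], distr="logit").fit(method="bfgs", disp=0)
        # statsmodels: P(y<=j) = sigma(theta_j - b x); thresholds via exp increments
        beta_sm = -sm.params[0]
        theta1 = sm.params[1]
        theta2 = sm.params[1] + np.exp(sm.params[2])
        assert fit.beta == pytest.approx(beta_sm, abs=1e-4)
        assert fit.alpha1 == pytest.approx(theta1, abs=1e-4)
        assert fit.alpha2 == pytest.approx(theta2, abs=1e-4)
        assert fit.se_beta == pytest.approx(sm.bse[0], rel=1e-3)

    def test_two_category_collapse(self):
        # no homozygous-minor calls at all: single-intercept model, alpha2 = +inf
        y = np.array([0] * 30 + [1] * 10 + [0] * 35 + [1] * 25)
        x = np.array([1] * 40 + [0] * 60)
        fit = nh.fit_cumlogit(y, x)
        assert fit.converged
        assert np.isinf(fit.alpha2)
        assert fit.se_beta > 0

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            nh.fit_cumlogit(np.array([1, 1, 1, 1]), np.array([0, 1, 0, 1]))

    def test_one_phenotype_group_raises(self):
        with pytest.raises(ValueError, match="case and one control"):
            nh.fit_cumlogit(np.array([0, 1, 2, 1]), np.array([1, 1, 1, 1]))

    def test_separation_flagged_not_crashed(self):
        # cases all 0, controls all 2: beta diverges
        y = np.array([0] * 20 + [2] * 20 + [1])
        x = np.array([1] * 20 + [0] * 20 + [0])
        fit = nh.fit_cumlogit(y, x)
        assert not fit.converged


class TestWald:
    def _fit(self, beta, se):
        return CumulativeLogitFit(
            alpha1=-1.0, alpha2=1.0, beta=beta, se_beta=se,
            loglik=-10.0, converged=True, n_iter=5, n_used=100,
        )

    def test_zero_beta_gives_p_one(self):
        res = nh.wald_test(self._fit(0.0, 0.5))
        assert res.z == 0.0 and res.p == 1.0

    def test_normal_quantile_identity(self):
        res = nh.wald_test(self._fit(1.959964, 1.0))
        assert res.p == pytest.approx(0.05, rel=1e-5)

    def test_p_monotone_in_abs_z(self):
        ps = [nh.wald_test(self._fit(b, 1.0)).p for b in (0.1, 0.5, 1.0, 3.0, 9.0)]
        assert ps == sorted(ps, reverse=True)

    def test_far_tail_is_positive(self):
        res = nh.wald_test(self._fit(12.0, 1.0))
        assert 0 < res.p < 1e-30

    def test_non_converged_gives_na(self):
        fit = self._fit(1.0, 1.0)
        fit.converged = False
        res = nh.wald_test(fit)
        assert res.status == "non_converged" and np.isnan(res.p)

    def test_wald_and_lrt_rank_together(self, rng):
        """Across random 2x3 tables the two tests order markers identically."""
        wald_ps, lrt_ps = [], []
        for _ in range(100):
            a1 = rng.normal(-0.5, 0.5)
            a2 = a1 + rng.exponential() + 0.2
            beta = rng.normal(0, 0.8)
            y, x = simulate_table(a1, a2, beta, 150, 250, seed=int(rng.integers(2**31)))
            try:
                fit = nh.fit_cumlogit(y, x)
            except ValueError:
                continue
            if not fit.converged:
                continue
            wald_ps.append(nh.wald_test(fit).p)
            lrt_ps.append(likelihood_ratio_test(y, x)[1])
        rho = spearmanr(wald_ps, lrt_ps).statistic
        assert rho > 0.99


class TestRunGwas:
    def test_deterministic_and_ordered(self, default_cohort, cohort_assoc):
        gm_qc, _, assoc, _ = cohort_assoc
        again = nh.run_gwas(gm_qc, default_cohort.snp_map)
        assert assoc.equals(again)
        key = list(zip(assoc["chrom"], assoc["pos"]))
        assert key == sorted(key)

    def test_statuses_and_counts(self, cohort_assoc):
        _, _, assoc, _ = cohort_assoc
        assert set(assoc["status"]) <= {"ok", "monomorphic", "non_converged", "zero_se", "untestable"}
        ok = assoc[assoc["status"] == "ok"]
        assert (ok["p"] > 0).all() and (ok["p"] <= 1).all()
        assert np.allclose(ok["z"], ok["beta"] / ok["se"])

    def test_binlogit_mode_agrees_in_direction(self, default_cohort, cohort_assoc):
        gm_qc, _, assoc, _ = cohort_assoc
        sub = gm_qc.subset_snps(np.arange(60))
        bl = nh.run_gwas(sub, default_cohort.snp_map, model="binlogit")
        both = assoc.merge(bl, on="snp_id", suffixes=("_cl", "_bl"))
        both = both[(both["status_cl"] == "ok") & (both["status_bl"] == "ok")]
        rho = spearmanr(both["p_cl"], both["p_bl"]).statistic
        assert rho > 0.8

    def test_binlogit_single_snp_matches_statsmodels(self):
        import statsmodels.api as smapi

        y, x = simulate_table(-0.4, 0.9, 0.7, 400, 600, seed=9)
        res = _binlogit_assoc(y, x, "s")
        X = np.column_stack([np.ones_like(y, dtype=float), y.astype(float)])
        ref = smapi.Logit(x, X).fit(disp=0)
        assert res.beta == pytest.approx(ref.params[1], abs=1e-6)
        assert res.se_beta == pytest.approx(ref.bse[1], rel=1e-4)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, expected",
        [(0.05, 1, 0.05), (0.01, 100, 1e-4), (0.05, 44542, 0.05 / 44542)],
    )
    def test_arithmetic(self, alpha, m, expected):
        assert nh.bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=1e-12)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            nh.bonferroni_threshold(0.05, 0)
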