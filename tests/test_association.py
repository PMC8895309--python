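"""Age panels, FDR, Bayes factors, maturity-memory links, interactions."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from tractpls import (
    SimConfig,
    age_group_interaction,
    bayes_factor_correlation,
    build_analysis_matrix,
    correlate_with_age,
    fdr_adjust,
    generate_cohort,
    maturity_em_association,
    maturity_scores,
    regress_on_age,
)


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_are_fixed_point(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_order_invariance(self, rng):
        p = rng.uniform(size=12)
        order = rng.permutation(12)
        np.testing.assert_allclose(fdr_adjust(p)[order], fdr_adjust(p[order]))

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(size=20)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestBayesFactor:
    def test_sign_symmetry(self):
        for method in ("jzs", "stretched-beta"):
            assert bayes_factor_correlation(0.37, 30, method=method) == pytest.approx(
                bayes_factor_correlation(-0.37, 30, method=method), rel=1e-12
            )

    def test_monotone_in_r_and_n(self):
        for method in ("jzs", "stretched-beta"):
            assert (
                bayes_factor_correlation(0.5, 30, method=method)
                > bayes_factor_correlation(0.3, 30, method=method)
            )
            assert (
                bayes_factor_correlation(0.4, 60, method=method)
                > bayes_factor_correlation(0.4, 30, method=method)
            )

    def test_small_r_favors_null(self):
        assert bayes_factor_correlation(0.02, 40) < 1
        assert bayes_factor_correlation(0.02, 40, method="stretched-beta") < 1

    def test_perfect_correlation_flagged_infinite(self):
        with pytest.warns(RuntimeWarning):
            assert bayes_factor_correlation(1.0, 20) == np.inf

    def test_stretched_beta_matches_quadrature_oracle(self):
        # marginal-likelihood-ratio quadrature over the uniform (kappa=1)
        # prior, using the exact sampling density of r up to rho-free factors
        r, n = 0.3, 50

        def g(rho):
            return (
                (1 - rho**2) ** ((n - 1) / 2)
                * (1 - rho * r) ** (-(n - 1.5))
                * special.hyp2f1(0.5, 0.5, (2 * n - 1) / 2, (rho * r + 1) / 2)
            )

        num, _ = integrate.quad(lambda rho: 0.5 * g(rho), -1, 1)
        oracle = num / g(0.0)
        got = bayes_factor_correlation(r, n, method="stretched-beta")
        assert got == pytest.approx(oracle, rel=1e-4)

    def test_jzs_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        for r, n in [(0.46, 37), (0.51, 36), (0.3, 50), (-0.2, 25)]:
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
            oracle = float(pingouin.bayesfactor_ttest(t, n, r=np.sqrt(2) / 2))
            assert bayes_factor_correlation(r, n) == pytest.approx(oracle, rel=1e-6)


class TestCorrelateWithAge:
    def test_full_panel_has_24_rows(self, default_cohort):
        cohort, metrics, _ = default_cohort
        table = correlate_with_age(metrics, cohort.ages())
        assert len(table) == 24  # 4 tracts x 2 hemispheres x 3 metrics
        assert set(table["metric"]) == {"fa", "rd", "ad"}

    def test_metric_equal_to_age_gives_unit_r(self, small_cohort, small_metrics):
        df = small_metrics.data.copy()
        ages = small_cohort.ages()
        mask = (df["tract"] == "fornix") & (df["hemisphere"] == "left")
        df.loc[mask, "fa"] = (ages.loc[df.loc[mask, "subject_id"]].to_numpy() / 20.0)
        table = correlate_with_age(type(small_metrics)(data=df), ages)
        row = table.query("tract == 'fornix' and hemisphere == 'left' and metric == 'fa'")
        assert row["r"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_pearson_oracle_cellwise(self, small_cohort, small_metrics):
        ages = small_cohort.ages()
        table = correlate_with_age(small_metrics, ages)
        for _, row in table.iterrows():
            sub = small_metrics.data.query(
                "tract == @row.tract and hemisphere == @row.hemisphere"
            )
            r = stats.pearsonr(
                sub[row["metric"]], ages.loc[sub["subject_id"]]
            ).statistic
            assert row["r"] == pytest.approx(r, abs=1e-12)


class TestRegressOnAge:
    def test_noiseless_line(self):
        age = np.linspace(4, 12, 10)
        res = regress_on_age(2 * age + 1, age)
        assert res.r_squared == pytest.approx(1.0)
        assert res.beta_std == pytest.approx(1.0)

    def test_f_identity_from_printed_r_squared(self):
        # F = (n-2) R^2 / (1 - R^2) reproduces the reported F at n = 37
        assert (37 - 2) * 0.251 / (1 - 0.251) == pytest.approx(11.71, rel=0.01)
        assert (37 - 2) * 0.239 / (1 - 0.239) == pytest.approx(11.02, rel=0.01)

    def test_identities_hold_on_fit(self, rng):
        age = rng.uniform(4, 12, 30)
        y = 0.5 * age + rng.normal(size=30)
        res = regress_on_age(y, age)
        assert res.F == pytest.approx(
            (res.n - 2) * res.r_squared / (1 - res.r_squared), rel=1e-9
        )
        assert res.beta_std**2 == pytest.approx(res.r_squared, rel=1e-9)

    def test_matches_normal_equations_oracle(self):
        age = np.array([4.0, 5.0, 7.0, 8.0, 10.0, 12.0])
        y = np.array([3.0, 4.5, 4.0, 6.0, 7.5, 7.0])
        res = regress_on_age(y, age)
        # independent least-squares route
        A = np.column_stack([np.ones(6), age])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        resid = y - A @ beta
        ss_res = resid @ resid
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - ss_res / ss_tot
        assert res.r_squared == pytest.approx(r2, abs=1e-9)
        assert res.F == pytest.approx((6 - 2) * r2 / (1 - r2), rel=1e-9)
        assert res.beta_std == pytest.approx(
            beta[1] * np.std(age, ddof=1) / np.std(y, ddof=1), abs=1e-9
        )

    def test_sex_covariate_does_not_change_age_significance(self, default_cohort):
        cohort, _, _ = default_cohort
        age = cohort.data["age"].to_numpy()
        y = cohort.data["ldcr"].to_numpy()
        plain = regress_on_age(y, age)
        sex = pd.DataFrame({"sex": (cohort.data["sex"] == "F").astype(float)})
        adj = regress_on_age(y, age, covariates=sex)
        assert (plain.p < 0.05) == (adj.p < 0.05)

    def test_collinear_covariate_raises(self, rng):
        age = rng.uniform(4, 12, 20)
        with pytest.raises(ValueError, match="rank"):
            regress_on_age(rng.normal(size=20), age,
                           covariates=pd.DataFrame({"age2": 2 * age}))


class TestMaturityEmAssociation:
    def _scores(self, cohort, metrics, tracts, seed=0):
        out = {}
        for tract in tracts:
            mat = build_analysis_matrix(cohort, metrics, tract, "age")
            out[tract] = maturity_scores(mat, tract=tract, n_perm=200,
                                         n_boot=100, seed=seed,
                                         allow_insignificant=True)
        return out

    def test_score_identical_to_em_column_survives_fdr(self, default_cohort):
        cohort, metrics, _ = default_cohort
        scores = self._scores(cohort, metrics, ["dorsal_cingulum"])
        ms = scores["dorsal_cingulum"]
        beh = cohort.data.set_index("subject_id")
        ms.score = beh.loc[ms.subject_ids, "sdfr"].to_numpy(float)
        res = maturity_em_association(scores, cohort)
        hit = next(a for a in res if a.behavior == "sdfr")
        assert hit.r == pytest.approx(1.0)
        assert hit.p_fdr < 1e-10
        assert hit.bf10 > 1e10  # overwhelming evidence (r at machine precision of 1)

    def test_fdr_and_bf_bookkeeping(self, default_cohort):
        cohort, metrics, _ = default_cohort
        scores = self._scores(cohort, metrics,
                              ["uncinate_fasciculus", "dorsal_cingulum"])
        res = maturity_em_association(scores, cohort)
        em = [a for a in res if a.panel == "em"]
        spec = [a for a in res if a.panel == "specificity"]
        assert len(em) == 6 and len(spec) == 2
        for a in res:
            assert a.p_fdr >= a.p_raw - 1e-15
            if a.panel == "em":
                assert (a.bf10 is not None) == (a.p_fdr < 0.05)
            else:
                assert a.bf10 is None

    def test_missing_discrimination_warns_and_skips_panel(self, default_cohort):
        cohort, metrics, _ = default_cohort
        import tractpls.cohort as tc

        stripped = tc.Cohort(data=cohort.data.drop(columns=["discrimination"]))
        scores = self._scores(stripped, metrics, ["dorsal_cingulum"])
        with pytest.warns(UserWarning, match="discrimination"):
            res = maturity_em_association(scores, stripped)
        assert all(a.panel == "em" for a in res)

    def test_null_cohort_family_error_near_nominal(self):
        # no planted coupling and no age signal in memory: the chance of any
        # false FDR positive across the family stays near the nominal level
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            cfg = SimConfig(
                seed=3000 + rep,
                em_age_r2={"sdfr": 0.0, "ldfr": 0.0, "ldcr": 0.0},
                em_tract_coupling={},
                failed_reconstructions={},
            )
            cohort, metrics, _ = generate_cohort(cfg)
            scores = self._scores(cohort, metrics, ["uncinate_fasciculus"],
                                  seed=rep)
            res = maturity_em_association(scores, cohort)
            hits += any(a.p_fdr < 0.05 for a in res if a.panel == "em")
        assert hits / n_rep <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_rep)


class TestAgeGroupInteraction:
    def _ms_stub(self, score, tract="uncinate_fasciculus"):
        from tractpls.maturity import MaturityScores

        return MaturityScores(
            tract=tract, subject_ids=[f"s{i}" for i in range(len(score))],
            score=np.asarray(score, float), salience=np.zeros(6),
            x_names=[], age_correlation=0.0, age_correlation_p=1.0,
            sign_flipped=False, lv_p_value=0.01, permutation=None,
            bootstrap=None, model=None, significant=True,
        )

    def test_identical_groups_have_zero_interaction(self, rng):
        n = 40
        m = rng.normal(size=n)
        age = np.r_[rng.uniform(4, 6.9, n // 2), rng.uniform(7.1, 12, n // 2)]
        em = 2.0 + 0.8 * m  # same slope and intercept in both groups
        res = age_group_interaction(self._ms_stub(m), em, age)
        assert res.interaction_coefficient == pytest.approx(0.0, abs=1e-9)
        assert res.slope_young == pytest.approx(res.slope_old, abs=1e-9)

    def test_age_exactly_seven_joins_older_group(self, rng):
        n = 12
        m = rng.normal(size=n)
        age = np.array([5.0] * 5 + [7.0] + [9.0] * 6)
        em = 1.0 + 0.5 * m + rng.normal(size=n) * 0.1
        res = age_group_interaction(self._ms_stub(m), em, age)
        assert res.n_young == 5 and res.n_old == 7

    def test_planted_slope_difference_detected(self):
        detected = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            n = 200
            m = rng.normal(size=n)
            age = np.r_[rng.uniform(4, 6.9, n // 2), rng.uniform(7.1, 12, n // 2)]
            group = (age >= 7).astype(float)
            em = 0.5 * m * group + rng.normal(size=n) * 0.5
            res = age_group_interaction(self._ms_stub(m), em, age)
            detected += res.interaction_p < 0.05
        assert detected >= 18  # >= 90% power at this effect size

    def test_equal_slopes_rarely_flagged_at_n37(self):
        false_pos = 0
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            m = rng.normal(size=37)
            age = rng.uniform(4, 12, 37)
            em = 0.5 * m + rng.normal(size=37) * 0.5
            res = age_group_interaction(self._ms_stub(m), em, age)
            false_pos += res.interaction_p < 0.05
        # nominal 5% type-I rate, allow ~3 SD
        assert false_pos / n_rep < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_empty_group_raises(self, rng):
        m = rng.normal(size=10)
        age = np.full(10, 9.0)
        with pytest.raises(ValueError, match="group"):
            age_group_interaction(self._ms_stub(m), m, age)
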