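"""Association testing: exact tests, logistic models, adjustment, power."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pgxvalidity.association import (
    clinical_covariate_tests,
    code_genetic_model,
    fisher_exact_2x2,
    logistic_assoc,
    p_act_adjust,
    power_simulation,
    run_association,
    subgroup_assoc,
)
from pgxvalidity.nat2 import infer_acetylator
from pgxvalidity.sim import default_config, generate_cohort
from pgxvalidity.types import ContingencyTable2x2, SampleRecord


@pytest.mark.parametrize(
    "dosage, model, expected",
    [
        (2, "additive", 2.0),
        (1, "additive", 1.0),
        (1, "dominant", 1.0),
        (2, "dominant", 1.0),
        (0, "dominant", 0.0),
        (1, "recessive", 0.0),
        (2, "recessive", 1.0),
    ],
)
def test_genetic_model_coding(dosage, model, expected):
    assert code_genetic_model(dosage, model) == expected


def test_genetic_model_missing_propagates():
    out = code_genetic_model(np.array([0.0, np.nan, 2.0]), "recessive")
    assert np.isnan(out[1]) and out[2] == 1.0


class TestFisherExact:
    def test_diagonal_table_enumeration(self):
        # margins (2,2)x(2,2): a in {0,1,2} with weights 1/6, 4/6, 1/6
        res = fisher_exact_2x2(ContingencyTable2x2(2, 0, 0, 2))
        assert res.p == pytest.approx(1 / 3)

    def test_balanced_table_is_modal(self):
        assert fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5)).p == 1.0

    def test_sex_by_status_table_enumeration_value(self):
        # cases (9 M, 15 F) vs controls (59 M, 20 F): point-probability
        # enumeration over the hypergeometric family gives 1.2588e-3
        res = fisher_exact_2x2(ContingencyTable2x2(9, 59, 15, 20))
        assert res.p == pytest.approx(1.2588018088398923e-3, rel=1e-9)

    def test_zero_margin_degenerate(self):
        res = fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4))
        assert res.p == 1.0 and res.degenerate

    def test_zero_cell_odds_ratio_flagged(self):
        res = fisher_exact_2x2(ContingencyTable2x2(3, 0, 1, 4))
        assert np.isinf(res.odds_ratio) and res.zero_cell

    def test_symmetries(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, 4)
            base = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            for t in [(b, a, d, c), (c, d, a, b), (a, c, b, d)]:
                assert fisher_exact_2x2(ContingencyTable2x2(*t)).p == \
                    pytest.approx(base.p, rel=1e-12)

    def test_or_invariant_under_joint_label_swap(self):
        # swapping case/control and inverting exposure: (a,b,c,d)->(d,c,b,a)
        res1 = fisher_exact_2x2(ContingencyTable2x2(8, 3, 2, 9))
        res2 = fisher_exact_2x2(ContingencyTable2x2(9, 2, 3, 8))
        assert res1.odds_ratio == pytest.approx(res2.odds_ratio)


class TestLogistic:
    def test_saturated_fit_matches_cross_product(self):
        # covariate-free binary exposure: logistic OR == (a d)/(b c)
        a, b, c, d = 20, 10, 10, 20
        y = np.array([1] * (a + c) + [0] * (b + d), dtype=float)
        g = np.array([1] * a + [0] * c + [1] * b + [0] * d, dtype=float)
        res = logistic_assoc(y, g)
        assert res.estimable
        assert res.odds_ratio == pytest.approx((a * d) / (b * c), abs=1e-3)

    def test_constant_in_one_group_inestimable(self):
        y = np.array([1] * 10 + [0] * 20, dtype=float)
        g = np.array([0.0] * 10 + [0, 1] * 10)  # no variant carrier among cases
        res = logistic_assoc(y, g)
        assert not res.estimable
        assert "constant in cases" in res.reason

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(12)
        rej = 0
        reps = 500
        for _ in range(reps):
            y = np.array([1] * 50 + [0] * 50, dtype=float)
            g = rng.binomial(2, 0.3, 100).astype(float)
            cov = pd.DataFrame({"female": rng.integers(0, 2, 100).astype(float)})
            res = logistic_assoc(y, g, cov)
            if res.estimable and res.p < 0.05:
                rej += 1
        assert 0.03 <= rej / reps <= 0.07


class TestPactAdjust:
    def test_single_test_unchanged(self):
        adj, _ = p_act_adjust(np.array([0.05]), np.random.default_rng(0).normal(size=(40, 1)))
        assert adj[0] == 0.05

    def test_duplicated_tests_collapse(self):
        x = np.random.default_rng(1).normal(size=(300, 1))
        adj, _ = p_act_adjust(np.array([0.05, 0.05]), np.column_stack([x, x]))
        assert adj == pytest.approx([0.05, 0.05], abs=2e-3)

    def test_independent_tests_reach_sidak(self):
        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.normal(size=(400, 10)))
        adj, _ = p_act_adjust(np.full(10, 0.01), Q)
        sidak = 1 - (1 - 0.01) ** 10
        assert adj == pytest.approx(np.full(10, sidak), abs=2e-3)

    def test_bounds_on_random_families(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            m = int(rng.integers(2, 12))
            P = rng.normal(size=(120, m))
            P[:, 1:] += 0.8 * P[:, [0]]  # induce correlation
            raw = rng.uniform(0.001, 0.6, m)
            adj, _ = p_act_adjust(raw, P)
            sidak = 1 - (1 - raw) ** m
            assert (adj >= raw - 1e-12).all()
            assert (adj <= np.minimum(1, sidak) + 2e-3).all()

    def test_residualization_discounts_covariate_induced_correlation(self):
        # two predictors correlated only through a shared covariate behave
        # as (nearly) independent once residualized
        rng = np.random.default_rng(4)
        z = rng.normal(size=500)
        p1 = z + rng.normal(size=500)
        p2 = z + rng.normal(size=500)
        adj_with, _ = p_act_adjust(
            np.array([0.01, 0.01]), np.column_stack([p1, p2]), z[:, None]
        )
        sidak2 = 1 - (1 - 0.01) ** 2
        assert adj_with == pytest.approx([sidak2, sidak2], abs=2e-3)


class TestDrivers:
    def test_run_association_adjusts_only_estimable_family(self):
        c = generate_cohort(default_config(seed=31, n_background_snps=0))
        out = run_association(c.genotypes, c.samples, adjust=True, seed=1)
        est = out[out.estimable]
        bad = out[~out.estimable]
        assert (est.p_adjusted >= est.p - 1e-12).all()
        assert bad.p_adjusted.isna().all()
        assert (out.family_size == len(est)).all()
        assert set(bad.reason.dropna()) != set()

    def test_single_stratum_subgroup_equals_unstratified(self):
        from pgxvalidity.sim import SimConfig, StratumConfig

        base = default_config().strata[0].haplotype_freqs
        cfg = SimConfig(
            strata=(StratumConfig("Chinese", 15, 45, dict(base)),),
            n_background_snps=0, seed=41,
        )
        c = generate_cohort(cfg)
        exposure = {
            cl.sample_id: cl.exposure for cl in infer_acetylator(c.genotypes)
        }
        sub = subgroup_assoc(c.genotypes, c.samples, exposure=exposure)
        assert len(sub) == 1
        y = np.array([s.is_case for s in c.samples], dtype=float)
        g = np.array([float(exposure[s.sample_id]) for s in c.samples])
        cov = pd.DataFrame({"female": [float(s.sex == "F") for s in c.samples]})
        whole = logistic_assoc(y, g, cov)
        assert sub.OR.iloc[0] == pytest.approx(whole.odds_ratio, rel=1e-9)

    def test_common_effect_keeps_direction_across_strata(self, cohort_replicates):
        frac = np.mean(cohort_replicates["subgroup_direction"])
        assert frac >= 0.90

    def test_empty_stratum_errors(self):
        c = generate_cohort(default_config(seed=43, n_background_snps=0))
        with pytest.raises(ValueError, match="empty stratum"):
            subgroup_assoc(c.genotypes, c.samples, snp="rs1041983",
                           ethnicities=["Martian"])


class TestCovariateTests:
    def test_study_margins_reproduce_printed_p_values(self, study_scale_samples):
        out = clinical_covariate_tests(study_scale_samples)
        sex_p = out[(out.variable == "sex")].p.iloc[0]
        assert f"{sex_p:.2e}" == "1.80e-03"
        eth = out[out.variable == "ethnicity"].set_index("level")
        assert round(eth.loc["Others", "p"], 3) == 0.018
        assert round(eth.loc["Chinese", "p"], 3) == 0.051
        assert round(eth.loc["Malay", "p"], 3) == 0.333
        assert round(eth.loc["Indian", "p"], 3) == 0.677

    def test_constant_variable_flagged(self):
        samples = [
            SampleRecord(f"s{i}", "M", "Chinese",
                         "case" if i < 3 else "control",
                         2 if i < 3 else 0, 50.0)
            for i in range(10)
        ]
        out = clinical_covariate_tests(samples)
        sex_row = out[out.variable == "sex"]
        assert sex_row.p.iloc[0] == 1.0 and sex_row.flag.iloc[0] == "constant"

    def test_mann_whitney_type_one_error(self):
        rng = np.random.default_rng(8)
        rej = 0
        reps = 500
        for _ in range(reps):
            a, b = rng.normal(size=30), rng.normal(size=40)
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rej += p < 0.05
        assert 0.03 <= rej / reps <= 0.07


class TestPower:
    def test_null_matches_alpha(self):
        power, se = power_simulation(24, 79, 0.15, 1.0, alpha=0.05,
                                     n_reps=1000, seed=5)
        assert abs(power - 0.05) < max(3 * se, 0.02)

    def test_extreme_effect_saturates(self):
        power, _ = power_simulation(24, 79, 0.3, 50.0, alpha=0.003,
                                    n_reps=500, seed=6)
        assert power > 0.99

    def test_input_validation(self):
        with pytest.raises(ValueError):
            power_simulation(24, 79, 0.15, 4.5, alpha=0.0)
        with pytest.raises(ValueError):
            power_simulation(24, 79, 1.5, 4.5)
        with pytest.raises(ValueError):
            power_simulation(24, 79, 0.15, 4.5, n_reps=10)
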