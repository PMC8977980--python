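import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import afdm
from afdm import datasets
from afdm.errors import SeparationError, UndefinedMetricError
from afdm.stats import round_half_up


class TestContingency:
    def test_chi_square_equals_textbook_formula(self):
        """Oracle re-implementation: sum (O-E)^2/E on arbitrary tables."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(1, 60, size=(rng.integers(2, 4), rng.integers(2, 4)))
            stat, _, dof, _ = afdm.chi_square_test(t)
            rs, cs, n = t.sum(1, keepdims=True), t.sum(0, keepdims=True), t.sum()
            e = rs * cs / n
            assert stat == pytest.approx(((t - e) ** 2 / e).sum(), rel=1e-12)
            assert dof == (t.shape[0] - 1) * (t.shape[1] - 1)

    def test_published_gender_rac_table_gives_p_003(self):
        stat, p, _, _ = afdm.chi_square_test([[47, 17], [8, 13]])
        assert stat == pytest.approx(8.65, abs=0.02)
        assert round(p, 3) == 0.003

    def test_independent_table_gives_zero_statistic(self):
        stat, p, _, _ = afdm.chi_square_test([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Exhaustive two-sided Fisher p on small tables (n <= 40)."""

        def fisher_oracle(a, b, c, d):
            r1, r2, c1 = a + b, c + d, a + c
            n = r1 + r2
            denom = comb(n, c1, exact=True)
            p_obs = comb(r1, a, exact=True) * comb(r2, c, exact=True) / denom
            p = 0.0
            for x in range(max(0, c1 - r2), min(r1, c1) + 1):
                px = comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / denom
                if px <= p_obs * (1 + 1e-12):
                    p += px
            return p

        for table in ([3, 5, 8, 2], [1, 9, 7, 3], [4, 4, 4, 4], [0, 10, 5, 5]):
            a, b, c, d = table
            _, p = afdm.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)

    def test_small_cells_route_to_fisher(self):
        _, _, method = afdm.contingency_test([[2, 3], [3, 2]])
        assert method == "fisher"
        _, _, method = afdm.contingency_test([[20, 30], [30, 20]])
        assert method == "chi2"

    def test_zero_margin_rejected(self):
        with pytest.raises(UndefinedMetricError):
            afdm.chi_square_test([[0, 0], [5, 5]])


class TestParametricTests:
    def test_identical_samples_t_zero_p_one(self):
        x = np.arange(10.0)
        t, p = afdm.welch_t_test(x, x.copy())
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_separated_normals_have_vanishing_p(self):
        rng = np.random.default_rng(1)
        t, p = afdm.welch_t_test(rng.normal(0, 1, 1000), rng.normal(1, 1, 1000))
        assert p < 1e-10

    def test_equal_proportions_z_zero(self):
        z, p = afdm.proportion_z_test(25, 50, 50, 100)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)


class TestRecurrenceByLocation:
    def test_published_counts_reproduced_exactly(self):
        tab = afdm.recurrence_by_rac_location(datasets.reference_recurrence_cohort())
        assert tab.loc["outside", "pct_display"] == 63.4
        assert tab.loc["inside_only", "pct_display"] == 11.1
        assert tab.loc["none", "pct_display"] == 31.0
        assert tab["n"].sum() == 79 and tab["recurrences"].sum() == 36

    def test_all_recurrence_cohort(self):
        df = pd.DataFrame(
            dict(rac_location_class=["none", "outside"] * 3, recurrence=[1] * 6)
        )
        tab = afdm.recurrence_by_rac_location(df)
        assert tab.loc["none", "pct"] == 100.0 and tab.loc["outside", "pct"] == 100.0
        assert np.isnan(tab.loc["inside_only", "pct"])

    def test_matches_groupby_oracle_on_synthetic_cohort(self):
        df = afdm.simulate_cohort(afdm.SyntheticCohortSpec(seed=8))
        df = afdm.apply_blanking(df)
        tab = afdm.recurrence_by_rac_location(df)
        oracle = df.groupby("rac_location_class")["recurrence"].agg(["size", "sum"])
        for cls in oracle.index:
            assert tab.loc[cls, "n"] == oracle.loc[cls, "size"]
            assert tab.loc[cls, "recurrences"] == oracle.loc[cls, "sum"]

    def test_blanking_excludes_short_followup(self):
        df = pd.DataFrame(
            dict(rac_location_class=["none"] * 4, recurrence=[1, 1, 0, 0],
                 followup_days=[30.0, 100.0, 90.0, 200.0])
        )
        kept = afdm.apply_blanking(df, 90.0)
        assert len(kept) == 2


class TestLogisticOr:
    def test_single_exposure_equals_cross_product_identity(self):
        # 2x2 collapsed data (26,15 / 10,28): OR = 26*28/(15*10)
        rows = (
            [dict(exposure=1, recurrence=1)] * 26
            + [dict(exposure=1, recurrence=0)] * 15
            + [dict(exposure=0, recurrence=1)] * 10
            + [dict(exposure=0, recurrence=0)] * 28
        )
        df = pd.DataFrame(rows)
        res = afdm.logistic_or(df, "exposure")
        assert res.odds_ratio == pytest.approx(26 * 28 / (15 * 10), rel=1e-6)

    def test_null_exposure_gives_or_near_one(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            dict(exposure=rng.integers(0, 2, 10000), recurrence=rng.integers(0, 2, 10000))
        )
        res = afdm.logistic_or(df, "exposure")
        assert res.odds_ratio == pytest.approx(1.0, abs=0.1)
        assert res.covers(1.0)

    def test_ci_ordering_invariant(self):
        df = afdm.simulate_cohort(afdm.SyntheticCohortSpec(seed=9))
        df["rac_outside"] = (df.rac_location_class == "outside").astype(int)
        res = afdm.logistic_or(df, "rac_outside")
        assert res.ci_low <= res.odds_ratio <= res.ci_high
        assert res.ci_low > 0

    def test_complete_separation_detected(self):
        df = pd.DataFrame(dict(exposure=[0] * 20 + [1] * 20, recurrence=[0] * 20 + [1] * 20))
        with pytest.raises(SeparationError):
            afdm.logistic_or(df, "exposure")
        res = afdm.logistic_or(df, "exposure", penalized=True)
        assert res.penalized and res.odds_ratio > 1


@pytest.fixture(scope="module")
def confounded():
    spec = afdm.SyntheticCohortSpec(
        n_men=3000, n_women=1000,
        age_by_gender={"M": (60, 9), "F": (66, 9)},
        hypertension_by_gender={"M": 0.40, "F": 0.60},
        chadsvasc_by_gender={"M": (1.6, 1.3), "F": (2.6, 1.3)},
        bsa_by_gender={"M": (2.05, 0.2), "F": (1.9, 0.2)},
        seed=2,
    )
    return afdm.simulate_cohort(spec)


class TestPropensityMatching:
    def test_balance_achieved_on_confounded_cohort(self, confounded):
        m = afdm.propensity_match(confounded)
        assert max(abs(v) for v in m.smd_before.values()) > 0.4
        assert all(abs(v) < 0.1 for v in m.smd_after.values())

    def test_matching_never_worsens_propensity_smd(self, confounded):
        m = afdm.propensity_match(confounded)
        assert abs(m.propensity_smd_after) <= abs(m.propensity_smd_before)

    def test_pairs_are_one_to_one_without_replacement(self, confounded):
        m = afdm.propensity_match(confounded)
        treated = [t for t, _ in m.pairs]
        controls = [c for _, c in m.pairs]
        assert len(set(treated)) == len(treated)
        assert len(set(controls)) == len(controls)

    def test_zero_caliper_keeps_only_exact_score_matches(self, confounded):
        m = afdm.propensity_match(confounded, caliper=0.0)
        assert len(m.pairs) + m.n_unmatched_treated == (confounded.gender == "F").sum()
        # continuous covariates make exact propensity ties essentially impossible
        assert len(m.pairs) == 0

    def test_unconfounded_treatment_retains_most_treated(self):
        spec = afdm.SyntheticCohortSpec(
            n_men=600, n_women=200,
            age_by_gender={"M": (60, 9), "F": (60, 9)},
            hypertension_by_gender={"M": 0.5, "F": 0.5},
            chadsvasc_by_gender={"M": (2.0, 1.3), "F": (2.0, 1.3)},
            bsa_by_gender={"M": (2.0, 0.2), "F": (2.0, 0.2)},
            seed=3,
        )
        df = afdm.simulate_cohort(spec)
        m = afdm.propensity_match(df)
        assert m.n_unmatched_treated <= 5


class TestTablesAndRounding:
    def test_round_half_up_matches_printed_convention(self):
        assert round_half_up(63.4146, 1) == 63.4
        assert round_half_up(11.1111, 1) == 11.1
        assert round_half_up(0.25, 1) == 0.3  # half rounds up, not to even

    def test_table1_rows_match_direct_recomputation(self):
        df = afdm.simulate_cohort(afdm.SyntheticCohortSpec(seed=10))
        t1 = afdm.build_table(df, "table1")
        age_row = t1[t1.variable == "Age (years)"].iloc[0]
        men = df[df.gender == "M"].age
        assert age_row["men"] == f"{men.mean():.1f} ± {men.std(ddof=1):.1f}"
        _, p = afdm.welch_t_test(men, df[df.gender == "F"].age)
        assert age_row["p"] == pytest.approx(p)

    def test_table3_reproduces_location_percentages(self):
        ref = datasets.reference_recurrence_cohort()
        ref["la_volume_cm3"] = 150.0
        ref["mean_voltage_mv"] = 0.6
        ref["burden"] = 0.3
        t3 = afdm.build_table(ref, "table3")
        loc_rows = t3[t3.variable.str.startswith("RAc location")]
        lookup = {r.variable.split(": ")[1]: (r.af_free, r.recurrence) for r in loc_rows.itertuples()}
        assert lookup["none"] == (20, 9)
        assert lookup["inside_only"] == (8, 1)
        assert lookup["outside"] == (15, 26)

    def test_single_gender_cohort_rejected(self):
        df = afdm.simulate_cohort(afdm.SyntheticCohortSpec(n_women=0, seed=1))
        with pytest.raises(UndefinedMetricError):
            afdm.build_table(df, "table1")
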