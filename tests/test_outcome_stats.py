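import numpy as np
import pytest
from scipy import stats

from cryomargin.errors import (
    CapacityError,
    InestimableError,
    InputError,
    UndefinedCorrelationError,
)
from cryomargin.outcome_stats import (
    CaseRecord,
    _cox_fit,
    _enumerate_tables,
    _log_table_prob,
    _margin_log_const,
    cox_univariable,
    fisher_exact_2x2,
    freeman_halton,
    km_event_free,
    mann_whitney_u,
    read_cohort_csv,
    spearman_rho,
    write_cohort_csv,
)
from cryomargin.synthetic_data import CohortSpec, simulate_cohort


def make_record(case_id="c", mtm=2.0, diam=30.0, time=12.0, event=False, **kw):
    defaults = dict(
        tumor_volume_ml=9.0, iceball_volume_ml=50.0, n_probes=3,
        sex="male", asa="II", renal_category="low",
    )
    defaults.update(kw)
    return CaseRecord(
        case_id=case_id, tumor_diameter_mm=diam, mtm_raw_mm=mtm,
        mtm_mm=int(round(mtm)), ltp=event, time_months=time, event=event,
        **defaults,
    )


class TestMannWhitney:
    def test_identical_samples_no_separation(self):
        res = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value >= 0.99

    def test_small_exact_enumeration(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.method.endswith("exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings

    def test_perfect_separation_thirteen_vs_thirteen(self):
        x = np.arange(13.0)
        y = np.arange(100.0, 113.0)
        res = mann_whitney_u(x, y)
        assert res.p_value < 0.001

    def test_ties_use_asymptotic_branch(self):
        res = mann_whitney_u([1, 1, 2, 3], [2, 3, 3, 4])
        assert res.method.endswith("asymptotic")
        assert 0.0 <= res.p_value <= 1.0

    def test_exact_close_to_asymptotic_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.normal(size=9)
            y = rng.normal(0.5, size=9)
            exact = mann_whitney_u(x, y)
            assert exact.method.endswith("exact")
            approx = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert exact.p_value == pytest.approx(float(approx.pvalue), abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_u([], [1.0])


class TestFisherExact:
    def test_sex_by_outcome_table(self):
        assert fisher_exact_2x2([[17, 3], [9, 3]]).p_value == pytest.approx(0.647, abs=5e-4)

    def test_asa_by_outcome_table(self):
        assert fisher_exact_2x2([[17, 2], [9, 4]]).p_value == pytest.approx(0.194, abs=5e-4)

    def test_zero_row_is_degenerate(self):
        assert fisher_exact_2x2([[0, 0], [5, 7]]).p_value == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_2x2([[1, -1], [2, 3]])

    def test_agrees_with_scipy_exhaustively_small_totals(self):
        # scipy's two-sided probability method is the independent oracle;
        # scan every 2x2 table with grand total <= 20
        for n in range(1, 21):
            for r1 in range(n + 1):
                for c1 in range(n + 1):
                    for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
                        t = [[a, r1 - a], [c1 - a, n - r1 - c1 + a]]
                        ours = fisher_exact_2x2(t).p_value
                        ref = float(stats.fisher_exact(t)[1])
                        assert ours == pytest.approx(ref, abs=1e-9), t

    def test_agrees_with_scipy_on_random_larger_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            t = rng.integers(0, 25, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_2x2(t).p_value == pytest.approx(
                float(stats.fisher_exact(t)[1]), abs=1e-9), t


class TestFreemanHalton:
    RENAL = [[18, 2], [8, 3], [0, 1]]

    def test_renal_by_outcome_table(self):
        assert freeman_halton(self.RENAL).p_value == pytest.approx(0.070, abs=5e-4)

    def test_reduces_to_fisher_on_2x2(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum() == 0 or (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert freeman_halton(t).p_value == pytest.approx(
                fisher_exact_2x2(t).p_value, abs=1e-12)

    def test_single_column_is_certain(self):
        assert freeman_halton([[4], [3], [2]]).p_value == 1.0

    def test_support_probabilities_sum_to_one(self):
        t = np.array(self.RENAL)
        log_const = _margin_log_const(t)
        total = sum(
            np.exp(_log_table_prob(cand, log_const))
            for cand in _enumerate_tables(t.sum(axis=1), t.sum(axis=0))
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_capacity_error_beyond_enumeration_bound(self):
        big = np.full((3, 2), 40)  # grand total 240 > 200
        with pytest.raises(CapacityError, match="monte-carlo"):
            freeman_halton(big)

    def test_monte_carlo_tracks_exact(self):
        ex = freeman_halton(self.RENAL).p_value
        mc = freeman_halton(self.RENAL, method="monte-carlo", n_draws=50_000, seed=0).p_value
        assert mc == pytest.approx(ex, abs=0.01)

    def test_agrees_with_r_convention_three_by_three(self):
        # expected value computed independently with R: fisher.test on this
        # table gives p = 0.05123448
        t = [[3, 1, 0], [1, 4, 1], [0, 1, 3]]
        assert freeman_halton(t).p_value == pytest.approx(0.05123448, abs=1e-7)


class TestSpearman:
    def test_monotone_identity(self):
        res = spearman_rho([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value < 0.01

    def test_antitone(self):
        res = spearman_rho([1, 2, 3, 4], [8, 6, 4, 2])
        assert res.statistic == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([1, 1, 1], [2, 3, 4])

    def test_simulated_cohorts_show_negative_size_margin_trend(self):
        # the generator builds in the inverse size-margin association
        hits = 0
        for seed in range(100):
            recs, _ = simulate_cohort(CohortSpec(n_cases=200), seed=seed)
            res = spearman_rho(
                [r.tumor_diameter_mm for r in recs],
                [r.mtm_raw_mm for r in recs],
            )
            if res.statistic < 0 and res.p_value < 0.01:
                hits += 1
        assert hits >= 95


class TestCox:
    def test_three_subject_closed_form(self):
        # events at t=1 (x=1) and t=2 (x=0), censored at t=3 (x=1):
        # d/dbeta log PL = 0 gives exp(beta) = 1/sqrt(2)
        records = [
            make_record("a", mtm=1.0, time=1.0, event=True),
            make_record("b", mtm=0.0, time=2.0, event=True),
            make_record("c", mtm=1.0, time=3.0, event=False),
        ]
        res = cox_univariable(records, "mtm_raw_mm")
        assert res.coef == pytest.approx(-0.5 * np.log(2.0), abs=1e-7)
        assert res.ci95[0] <= res.hazard_ratio <= res.ci95[1]

    def test_agrees_with_lifelines_on_simulated_cohort(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        recs, _ = simulate_cohort(CohortSpec(n_cases=400), seed=21)
        res = cox_univariable(recs, "mtm_raw_mm")
        df = pd.DataFrame({
            "t": [r.time_months for r in recs],
            "e": [r.event for r in recs],
            "x": [r.mtm_raw_mm for r in recs],
        })
        cph = CoxPHFitter().fit(df, "t", "e")
        # continuous times carry no ties, so Breslow and Efron coincide
        assert res.coef == pytest.approx(float(cph.params_["x"]), abs=1e-5)
        assert res.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)

    def test_null_covariate_recovers_unit_hazard(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        t = rng.exponential(10.0, size=500)
        res = _cox_fit(t, np.ones(500, dtype=bool), x)
        assert 0.85 <= res.hazard_ratio <= 1.18

    def test_diameter_entered_per_cm(self):
        recs, _ = simulate_cohort(CohortSpec(n_cases=300), seed=4)
        per_cm = cox_univariable(recs, "tumor_diameter_mm")
        assert per_cm.unit == "per cm"
        x_mm = np.array([r.tumor_diameter_mm for r in recs])
        t = np.array([r.time_months for r in recs])
        e = np.array([r.event for r in recs])
        raw = _cox_fit(t, e, x_mm)
        assert per_cm.coef == pytest.approx(10.0 * raw.coef, rel=1e-4)

    def test_breslow_and_efron_differ_only_with_ties(self):
        records = [
            make_record("a", mtm=1.0, time=1.0, event=True),
            make_record("b", mtm=0.0, time=1.0, event=True),
            make_record("c", mtm=2.0, time=2.0, event=True),
            make_record("d", mtm=0.5, time=3.0, event=False),
        ]
        breslow = cox_univariable(records, "mtm_raw_mm", ties="breslow")
        efron = cox_univariable(records, "mtm_raw_mm", ties="efron")
        assert breslow.coef != pytest.approx(efron.coef, abs=1e-6)

    def test_zero_events_inestimable(self):
        records = [make_record(str(i), time=float(i + 1)) for i in range(5)]
        with pytest.raises(InestimableError):
            cox_univariable(records, "mtm_raw_mm")

    def test_perfect_separation_caps_with_warning(self):
        records = [
            make_record("a", mtm=-5.0, time=1.0, event=True),
            make_record("b", mtm=-4.0, time=2.0, event=True),
            make_record("c", mtm=5.0, time=10.0, event=False),
            make_record("d", mtm=6.0, time=11.0, event=False),
        ]
        with pytest.warns(UserWarning, match="separation"):
            res = cox_univariable(records, "mtm_raw_mm")
        assert not res.converged
        assert res.warnings


class TestKaplanMeier:
    def test_no_events_stays_at_one(self):
        records = [make_record(str(i), time=10.0 * (i + 1)) for i in range(4)]
        assert km_event_free(records, [6.0, 12.0, 36.0]) == [1.0, 1.0, 1.0]

    def test_hand_computed_product_limit(self):
        records = [
            make_record("a", time=6.0, event=True),
            make_record("b", time=18.0, event=True),
            make_record("c", time=12.0, event=False),
            make_record("d", time=24.0, event=False),
        ]
        s12, s24 = km_event_free(records, [12.0, 24.0])
        assert s12 == pytest.approx(0.75)
        assert s24 == pytest.approx(0.375)

    def test_no_censoring_equals_empirical_survival(self):
        times = [3.0, 5.0, 8.0, 13.0, 21.0]
        records = [make_record(str(i), time=t, event=True) for i, t in enumerate(times)]
        for h in (4.0, 9.0, 30.0):
            expected = np.mean([t > h for t in times])
            assert km_event_free(records, [h])[0] == pytest.approx(expected)

    def test_tracks_generator_truth_at_scale(self):
        recs, truth = simulate_cohort(CohortSpec(n_cases=4000), seed=8)
        est = km_event_free(recs, [12.0])[0]
        mtms = np.array([r.mtm_raw_mm for r in recs])
        true_s12 = np.mean([truth.true_event_free(12.0, m) for m in mtms])
        # binomial error at n=4000 is ~0.008; allow three sigma
        assert est == pytest.approx(true_s12, abs=0.025)

    def test_negative_horizon_rejected(self):
        with pytest.raises(InputError):
            km_event_free([make_record("a")], [-1.0])


class TestCohortCSV:
    def test_round_trip(self, tmp_path):
        recs, _ = simulate_cohort(CohortSpec(), seed=1)
        write_cohort_csv(recs, tmp_path / "cohort.csv")
        back = read_cohort_csv(tmp_path / "cohort.csv")
        assert back == recs

    def test_schema_violations_list_offending_rows(self, tmp_path):
        recs, _ = simulate_cohort(CohortSpec(n_cases=4), seed=1)
        path = tmp_path / "bad.csv"
        write_cohort_csv(recs, path)
        text = path.read_text().replace("male", "other", 1)
        path.write_text(text)
        with pytest.raises(InputError, match="row"):
            read_cohort_csv(path)

    def test_event_implies_ltp(self):
        with pytest.raises(InputError):
            CaseRecord("x", 30, 9, 50, 3, 2.0, 2, "male", "II", "low",
                       ltp=False, time_months=5.0, event=True)
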