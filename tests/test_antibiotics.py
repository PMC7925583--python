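"""Drug grouping, exposure covariates, sample pairing, ridge regression and CV."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hospitalome import composition
from hospitalome.antibiotics import (
    AntibioticImpactModel,
    DrugGroupingSpec,
    RidgeConfig,
    assemble_problem,
    assign_groups,
    build_design,
    build_exposure_matrix,
    drug_frequency,
    fit_ridge,
    infer_susceptibilities,
    make_pairs,
    pair_covariates,
    select_lambda,
    select_taxa,
    RegressionProblem,
)
from hospitalome.synthetic import SimConfig, generate_cohort


def drug_table(rows):
    cols = ["PatientID", "StartTimepoint", "StopTimepoint", "Factor", "Category", "AntiInfective", "Route"]
    return pd.DataFrame(rows, columns=cols)


class TestGrouping:
    def test_selection_and_promotion_rules(self):
        drugs = drug_table([
            ("p1", 0, 2, "vancomycin", "glycopeptide antibiotics", True, "intravenous"),
            ("p1", 0, 2, "atovaquone", "miscellaneous", True, "oral"),
            ("p1", 0, 2, "metronidazole", "miscellaneous", True, "oral"),
            ("p1", 0, 2, "aztreonam", "miscellaneous", True, "intravenous"),
            ("p1", 0, 2, "obscuredrug", "miscellaneous", True, "oral"),
            ("p1", 0, 2, "fluconazole", "antifungals", True, "oral"),
            ("p1", 0, 2, "vancomycin", "glycopeptide antibiotics", True, "topical"),
        ])
        out = assign_groups(drugs)
        got = set(zip(out["Group"], out["Route"]))
        assert got == {
            ("glycopeptide antibiotics", "intravenous"),
            ("metronidazole", "oral"),
            ("aztreonam", "intravenous"),
        }
        # every retained exposure maps to exactly one (group, route)
        assert len(out) == 3

    def test_route_filter_configurable(self):
        drugs = drug_table([
            ("p1", 0, 2, "vancomycin", "glycopeptide antibiotics", True, "oral"),
            ("p1", 0, 2, "vancomycin", "glycopeptide antibiotics", True, "intravenous"),
        ])
        spec = dataclasses.replace(DrugGroupingSpec(), routes=("oral",))
        out = assign_groups(drugs, spec)
        assert set(out["Route"]) == {"oral"}


class TestDrugFrequency:
    def test_fraction_of_patients_ever_exposed(self):
        drugs = drug_table([
            ("p1", 0, 2, "drugX", "penicillins", True, "oral"),
        ])
        hct = pd.DataFrame({"PatientID": ["p1", "p2", "p3", "p4"], "TimepointOfTransplant": [0] * 4})
        freq = drug_frequency(drugs, hct)
        assert freq.loc[0, "fraction"] == 0.25

    def test_repeat_courses_count_once(self):
        drugs = drug_table([
            ("p1", 0, 2, "drugX", "penicillins", True, "oral"),
            ("p1", 10, 12, "drugX", "penicillins", True, "oral"),
        ])
        hct = pd.DataFrame({"PatientID": ["p1", "p2"], "TimepointOfTransplant": [0, 0]})
        freq = drug_frequency(drugs, hct)
        assert freq.loc[0, "n_patients"] == 1 and freq.loc[0, "fraction"] == 0.5

    def test_empty_patient_table_is_error(self):
        with pytest.raises(ValueError, match="empty patient"):
            drug_frequency(drug_table([]), pd.DataFrame({"PatientID": []}))

    def test_matches_set_counting_oracle(self, small_cohort):
        cohort, _ = small_cohort
        freq = drug_frequency(cohort.drugs, cohort.hct)
        total = cohort.hct["PatientID"].nunique()
        for _, row in freq.iterrows():
            mask = (cohort.drugs["Factor"] == row.iloc[0]) & (cohort.drugs["Route"] == row["Route"])
            expect = cohort.drugs.loc[mask, "PatientID"].nunique() / total
            assert row["fraction"] == pytest.approx(expect)


class TestExposureMatrix:
    def test_closed_interval_days(self):
        drugs = drug_table([("p1", 3, 5, "d", "penicillins", True, "oral")])
        em = build_exposure_matrix(drugs)
        cov = em.covariates[0]
        assert em.exposed_days("p1", cov).tolist() == [3, 4, 5]

    def test_overlapping_courses_are_ored(self):
        drugs = drug_table([
            ("p1", 3, 5, "d", "penicillins", True, "oral"),
            ("p1", 5, 7, "d", "penicillins", True, "oral"),
        ])
        em = build_exposure_matrix(drugs)
        assert em.exposed_days("p1", em.covariates[0]).tolist() == [3, 4, 5, 6, 7]

    @given(
        intervals=st.lists(
            st.tuples(st.integers(-10, 30), st.integers(0, 8)), min_size=1, max_size=6
        ),
        window=st.tuples(st.integers(-12, 28), st.integers(1, 6)),
    )
    def test_window_count_matches_day_by_day_oracle(self, intervals, window):
        drugs = drug_table(
            [("p1", a, a + w, "d", "penicillins", True, "oral") for a, w in intervals]
        )
        em = build_exposure_matrix(drugs)
        cov = em.covariates[0]
        start, dt = window
        stop = start + dt
        member = set()
        for a, w in intervals:
            member.update(range(a, a + w + 1))
        oracle = sum(1 for d in member if start < d <= stop)
        assert em.count_in_window("p1", cov, start, stop) == oracle


class TestMakePairs:
    def _samples(self, days, pid="p1"):
        return pd.DataFrame({
            "SampleID": [f"{pid}s{d}" for d in days],
            "PatientID": [pid] * len(days),
            "Timepoint": days,
        })

    def _qpcr(self, sids):
        return pd.DataFrame({"SampleID": list(sids), "qPCR16S": [1e9] * len(sids)})

    def test_gap_filter(self):
        s = self._samples([0, 2, 6])
        pairs = make_pairs(s, self._qpcr(s["SampleID"]))
        assert len(pairs) == 1
        assert (pairs.loc[0, "t_i"], pairs.loc[0, "t_f"]) == (0, 2)

    def test_missing_qpcr_drops_pair_without_repairing(self):
        s = self._samples([0, 2, 6])
        pairs = make_pairs(s, self._qpcr(["p1s0", "p1s6"]))
        assert pairs.empty  # (0,6) is NOT formed by skipping the day-2 sample

    def test_pairs_never_span_patients(self):
        s = pd.concat([self._samples([0, 2], "p1"), self._samples([3, 4], "p2")], ignore_index=True)
        pairs = make_pairs(s, self._qpcr(s["SampleID"]))
        assert set(pairs["PatientID"]) == {"p1", "p2"} and len(pairs) == 2

    def test_duplicate_same_day_keeps_first_by_sample_id(self):
        s = pd.DataFrame({
            "SampleID": ["b", "a", "c"],
            "PatientID": ["p1"] * 3,
            "Timepoint": [0, 0, 2],
        })
        pairs = make_pairs(s, self._qpcr(["a", "b", "c"]))
        assert len(pairs) == 1 and pairs.loc[0, "SampleID_i"] == "a"

    def test_matches_brute_force_enumeration(self, small_cohort):
        cohort, _ = small_cohort
        pairs = make_pairs(cohort.samples, cohort.qpcr)
        qpcr_ids = set(cohort.qpcr["SampleID"])
        expected = set()
        s = cohort.samples.sort_values(["PatientID", "Timepoint", "SampleID"])
        s = s[~s.duplicated(["PatientID", "Timepoint"])]
        for pid, grp in s.groupby("PatientID"):
            seq = grp.sort_values("Timepoint")
            for (_, r1), (_, r2) in zip(seq.iterrows(), seq.iloc[1:].iterrows()):
                dt = int(r2["Timepoint"] - r1["Timepoint"])
                if 0 < dt <= 3 and r1["SampleID"] in qpcr_ids and r2["SampleID"] in qpcr_ids:
                    expected.add((pid, r1["SampleID"], r2["SampleID"]))
        got = set(zip(pairs["PatientID"], pairs["SampleID_i"], pairs["SampleID_f"]))
        assert got == expected


class TestPairCovariates:
    def test_half_open_window_convention(self):
        # drug on days 3-5, pair (2, 5): counts {3,4,5} -> C = 3 = dt
        drugs = drug_table([("p1", 3, 5, "d", "penicillins", True, "oral")])
        em = build_exposure_matrix(drugs)
        pair = pd.Series({"PatientID": "p1", "t_i": 2, "t_f": 5, "dt": 3})
        dt, c = pair_covariates(pair, em)
        assert (dt, c.tolist()) == (3, [3.0])

    def test_exposure_on_initial_day_does_not_count(self):
        drugs = drug_table([("p1", 2, 2, "d", "penicillins", True, "oral")])
        em = build_exposure_matrix(drugs)
        pair = pd.Series({"PatientID": "p1", "t_i": 2, "t_f": 5, "dt": 3})
        _, c = pair_covariates(pair, em)
        assert c.tolist() == [0.0]

    def test_no_exposure_and_full_coverage_bounds(self):
        drugs = drug_table([("p1", 0, 10, "d", "penicillins", True, "oral")])
        em = build_exposure_matrix(drugs)
        pair = pd.Series({"PatientID": "p1", "t_i": 3, "t_f": 6, "dt": 3})
        _, c = pair_covariates(pair, em)
        assert c.tolist() == [3.0]  # C attains its upper bound dt
        pair2 = pd.Series({"PatientID": "p2", "t_i": 3, "t_f": 6, "dt": 3})
        _, c2 = pair_covariates(pair2, em)
        assert c2.tolist() == [0.0]

    def test_c_bounded_by_dt_on_cohort(self, small_cohort):
        cohort, _ = small_cohort
        em = build_exposure_matrix(assign_groups(cohort.drugs))
        pairs = make_pairs(cohort.samples, cohort.qpcr)
        design = build_design(pairs, em)
        assert (design[:, 1:] <= design[:, [0]] + 1e-12).all()
        assert (design >= 0).all()


class TestSelectTaxa:
    def test_dominant_taxon_ranks_first(self):
        counts = pd.DataFrame({
            "SampleID": ["s1", "s1", "s2", "s2"],
            "ASV": ["big", "small", "big", "small"],
            "Count": [90, 10, 85, 15],
        })
        pairs = pd.DataFrame({"SampleID_i": ["s1"], "SampleID_f": ["s2"]})
        assert select_taxa(counts, pairs, k=2)[0] == "big"

    def test_k_larger_than_taxa_warns_and_returns_all(self):
        counts = pd.DataFrame({"SampleID": ["s1"], "ASV": ["a"], "Count": [5]})
        pairs = pd.DataFrame({"SampleID_i": ["s1"], "SampleID_f": ["s1"]})
        with pytest.warns(UserWarning, match="requested top"):
            got = select_taxa(counts, pairs, k=20)
        assert got == ["a"]

    def test_matches_mean_abundance_sort(self, small_cohort):
        cohort, _ = small_cohort
        pairs = make_pairs(cohort.samples, cohort.qpcr)
        got = select_taxa(cohort.counts, pairs, k=5)
        sids = set(pairs["SampleID_i"]) | set(pairs["SampleID_f"])
        rel = composition.relative_abundance(
            cohort.counts[cohort.counts["SampleID"].isin(sids)]
        )
        expect = rel.data.mean(axis=0).sort_values(ascending=False).index[:5].tolist()
        assert got == expect


class TestAssembleProblem:
    def _absolute(self, table):
        return composition.AbundanceTable(table, level="asv", kind="absolute")

    def test_single_pair_log_ratio(self):
        absolute = self._absolute(pd.DataFrame({"t": [10.0, 100.0]}, index=["s1", "s2"]))
        pairs = pd.DataFrame({"PatientID": ["p1"], "SampleID_i": ["s1"], "SampleID_f": ["s2"], "t_i": [0], "t_f": [1], "dt": [1]})
        prob = assemble_problem("t", pairs, absolute, np.array([[1.0]]), [])
        assert prob.y[0] == pytest.approx(np.log(10.0))
        assert prob.design.tolist() == [[1.0]]

    def test_zero_endpoint_discards_row(self):
        absolute = self._absolute(
            pd.DataFrame({"t": [10.0, 0.0, 7.0, 70.0]}, index=["s1", "s2", "s3", "s4"])
        )
        pairs = pd.DataFrame({
            "PatientID": ["p1", "p1"],
            "SampleID_i": ["s1", "s3"],
            "SampleID_f": ["s2", "s4"],
            "t_i": [0, 4], "t_f": [1, 5], "dt": [1, 1],
        })
        prob = assemble_problem("t", pairs, absolute, np.eye(2)[:, :1], [])
        assert prob.n_pairs == 1 and prob.pair_index.tolist() == [1]

    def test_all_zero_taxon_not_estimable(self):
        absolute = self._absolute(pd.DataFrame({"t": [0.0, 0.0]}, index=["s1", "s2"]))
        pairs = pd.DataFrame({"PatientID": ["p1"], "SampleID_i": ["s1"], "SampleID_f": ["s2"], "t_i": [0], "t_f": [1], "dt": [1]})
        with pytest.raises(ValueError, match="not estimable"):
            assemble_problem("t", pairs, absolute, np.array([[1.0]]), [])


class TestFitRidge:
    def test_zero_penalty_equals_ols(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        ols, *_ = np.linalg.lstsq(d, y, rcond=None)
        np.testing.assert_allclose(fit_ridge(d, y, 0.0), ols, atol=1e-12)

    def test_huge_penalty_shrinks_to_zero(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        assert np.linalg.norm(fit_ridge(d, y, 1e9)) < 1e-3

    def test_matches_direct_objective_minimization(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(2)
        d = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        for lam in (0.1, 1.0, 10.0):
            def objective(x):
                r = y - d @ x
                return r @ r + lam * (x @ x)

            def gradient(x):
                return 2.0 * (d.T @ (d @ x - y) + lam * x)

            direct = minimize(
                objective, np.zeros(4), jac=gradient, method="BFGS",
                options={"gtol": 1e-12},
            ).x
            np.testing.assert_allclose(fit_ridge(d, y, lam), direct, atol=1e-8)

    def test_matches_sklearn_ridge(self):
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(3)
        d = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        sk = Ridge(alpha=2.5, fit_intercept=False).fit(d, y).coef_
        np.testing.assert_allclose(fit_ridge(d, y, 2.5), sk, atol=1e-10)

    def test_unpenalized_intercept_option(self):
        rng = np.random.default_rng(4)
        d = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        y = 5.0 + d[:, 1] + rng.normal(size=40) * 0.01
        hard = fit_ridge(d, y, 1e4, penalize_intercept=True)
        soft = fit_ridge(d, y, 1e4, penalize_intercept=False)
        assert abs(hard[0]) < 1.0 < abs(soft[0])

    def test_coefficient_norm_monotone_in_lambda(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        norms = [np.linalg.norm(fit_ridge(d, y, lam)) for lam in np.logspace(-4, 4, 9)]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_rank_deficient_at_zero_gives_min_norm(self):
        d = np.array([[1.0, 1.0], [2.0, 2.0]])
        y = np.array([1.0, 2.0])
        with pytest.warns(UserWarning, match="rank-deficient"):
            x = fit_ridge(d, y, 0.0)
        np.testing.assert_allclose(x, [0.5, 0.5], atol=1e-12)


class TestSelectLambda:
    def _problem(self, y, d):
        return RegressionProblem(taxon="t", y=y, design=d, pair_index=np.arange(len(y)), covariates=[])

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        d = rng.normal(size=(30, 3))
        y = d @ np.array([1.0, -0.5, 0.2]) + rng.normal(size=30) * 0.3
        cfg = RidgeConfig(seed=42)
        lam1, curve1, coef1 = select_lambda(self._problem(y, d), cfg)
        lam2, curve2, coef2 = select_lambda(self._problem(y, d), cfg)
        assert lam1 == lam2
        pd.testing.assert_frame_equal(curve1, curve2)
        np.testing.assert_array_equal(coef1, coef2)

    def test_noiseless_system_picks_smallest_lambda(self):
        rng = np.random.default_rng(7)
        d = rng.normal(size=(60, 3))
        y = d @ np.array([1.0, -0.5, 0.2])  # exactly consistent
        lam, _, _ = select_lambda(self._problem(y, d), RidgeConfig(seed=0))
        assert lam == pytest.approx(min(RidgeConfig().lambda_grid))

    def test_pure_noise_prefers_heavy_shrinkage(self):
        rng = np.random.default_rng(8)
        d = rng.normal(size=(60, 4))
        y = rng.normal(size=60)  # response independent of design
        lam, curve, _ = select_lambda(self._problem(y, d), RidgeConfig(seed=0))
        assert curve["cv_sse"].iloc[-1] <= curve["cv_sse"].iloc[0]
        assert lam > 1.0

    def test_too_few_rows_is_error(self):
        with pytest.raises(ValueError, match="folds"):
            select_lambda(self._problem(np.ones(2), np.ones((2, 1))), RidgeConfig())


class TestInferSusceptibilities:
    def test_drug_free_cohort_recovers_growth_rates(self):
        cfg = SimConfig.noiseless(
            n_patients=20, n_taxa=5, n_drug_groups=1,
            drug_course_rate=0.0, nuisance_drug_rate=0.0, seed=3,
        )
        cohort, truth = generate_cohort(cfg)
        est = infer_susceptibilities(cohort, ridge_config=RidgeConfig(lambda_grid=(1e-8,)), k=5)
        assert est.covariates == []  # no drugs -> no susceptibility columns
        for i, taxon in enumerate(truth.taxa):
            assert est.params.loc[taxon, "growth_rate"] == pytest.approx(truth.g[i], abs=1e-6)

    def test_model_results_round_trip(self, small_cohort, tmp_path):
        cohort, _ = small_cohort
        res = AntibioticImpactModel(
            cohort, ridge_config=RidgeConfig(lambda_grid=(0.1, 10.0), monte_carlo_reps=2), top_k=4
        ).fit()
        assert res.params.shape[1] == 1 + len(res.estimate.covariates)
        assert "growth_rate" in res.summary()
        out = tmp_path / "coef.csv"
        res.to_csv(out)
        written = pd.read_csv(out)
        assert {"taxon", "drug_group", "route", "coefficient"} <= set(written.columns)
        oral = res.susceptibilities("oral")
        assert all(c.endswith("[oral]") for c in oral.columns)
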