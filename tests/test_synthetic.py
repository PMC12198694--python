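import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emrcea import (
    GeneratorConfig,
    VisitRecord,
    estimate_attendance,
    estimate_costs_matched,
    estimate_waiting_proportion,
    generate_cohort,
    parameters_from_cohort,
)
from emrcea.synthetic import (
    PERIODS,
    SETTINGS,
    EstimationError,
    GenerationError,
    MatchingError,
    read_cohort,
    waiting_gamma_params,
    write_cohort,
)


def small_config(seed=42, n=2000):
    return GeneratorConfig(
        seed=seed, n_patients={(s, p): n for s in SETTINGS for p in PERIODS}
    )


def manual_cohort(rows):
    frame = pd.DataFrame(rows)
    frame["wait_days"] = frame.get("wait_days", pd.Series(dtype="float")).astype("Int64")
    for col in ("attended", "duplicate_test"):
        if col in frame:
            frame[col] = frame[col].astype("boolean")
    return frame


class TestVisitRecord:
    def test_valid_records(self):
        VisitRecord("a", "NUP", "pre", "acute", 80.0)
        VisitRecord("b", "SOC", "post", "chronic", 200.0, wait_days=5, attended=True,
                    duplicate_test=False)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(setting="NUP", wait_days=3),  # SOC-only field on a NUP record
            dict(setting="SOC"),  # SOC record without wait/attendance
            dict(setting="SOC", wait_days=3, attended=False, duplicate_test=True),
            dict(setting="NUP", bill=-1.0),
        ],
    )
    def test_invariant_violations(self, kwargs):
        base = dict(patient_id="x", setting="NUP", period="pre", visit_type="acute", bill=1.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            VisitRecord(**base)


class TestGenerator:
    def test_waiting_gamma_hits_target_mass(self):
        for p in (0.37, 0.455, 0.8):
            shape, scale = waiting_gamma_params(p, 0.75)
            assert stats.gamma.cdf(20.0, shape, scale=scale) == pytest.approx(p, abs=1e-12)

    def test_empty_config_yields_empty_cohort(self):
        config = GeneratorConfig(seed=1, n_patients={})
        records = generate_cohort(config)
        assert len(records) == 0
        assert set(records.columns) >= {"setting", "period", "bill"}

    def test_same_seed_reproducible(self):
        a = generate_cohort(small_config())
        b = generate_cohort(small_config())
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(small_config(seed=43))
        assert not a["bill"].equals(c["bill"])

    def test_invalid_probability_rejected(self):
        config = GeneratorConfig(seed=1, p_wait_lt20={"pre": 1.4, "post": 0.455})
        with pytest.raises(GenerationError):
            generate_cohort(config)

    def test_structure_invariants(self):
        records = generate_cohort(small_config())
        nup = records[records["setting"] == "NUP"]
        soc = records[records["setting"] == "SOC"]
        assert nup["wait_days"].isna().all() and nup["attended"].isna().all()
        assert soc["wait_days"].notna().all() and (soc["wait_days"] >= 0).all()
        no_show = soc[~soc["attended"].astype(bool)]
        assert no_show["duplicate_test"].isna().all()
        assert (no_show["bill"] == 0.0).all()
        assert (records["bill"] >= 0).all()

    def test_post_period_waiting_proportion_near_target(self):
        config = GeneratorConfig(
            seed=9, n_patients={("SOC", "pre"): 50_000, ("SOC", "post"): 50_000}
        )
        records = generate_cohort(config)
        p, se = estimate_waiting_proportion(records, "post")
        binom_se = np.sqrt(0.455 * 0.545 / 50_000)
        assert abs(p - 0.455) < 3 * binom_se
        assert se == pytest.approx(binom_se, rel=0.05)

    def test_cohort_csv_round_trip(self, tmp_path):
        records = generate_cohort(small_config(n=200))
        path = tmp_path / "cohort.csv"
        write_cohort(records, path, seed=42)
        assert path.read_text().startswith("# seed=42")
        loaded = read_cohort(path)
        assert len(loaded) == len(records)
        assert loaded["attended"].dtype == records["attended"].dtype


class TestEstimators:
    def test_degenerate_waiting_proportions(self):
        records = manual_cohort(
            [
                dict(patient_id="a", setting="SOC", period="pre", visit_type="acute",
                     wait_days=0, attended=True, duplicate_test=False, bill=10.0),
                dict(patient_id="b", setting="SOC", period="post", visit_type="acute",
                     wait_days=30, attended=True, duplicate_test=False, bill=10.0),
            ]
        )
        assert estimate_waiting_proportion(records, "pre") == (1.0, 0.0)
        assert estimate_waiting_proportion(records, "post") == (0.0, 0.0)

    def test_empty_period_raises(self):
        records = manual_cohort(
            [dict(patient_id="a", setting="NUP", period="pre", visit_type="acute", bill=10.0)]
        )
        with pytest.raises(EstimationError):
            estimate_waiting_proportion(records, "pre")

    def test_attendance_recovery_large_n(self):
        config = GeneratorConfig(seed=5, n_patients={("SOC", "pre"): 50_000})
        records = generate_cohort(config)
        for stratum, truth in (("lt20", 0.866), ("ge20", 0.82)):
            p, se = estimate_attendance(records, "pre", stratum)
            assert abs(p - truth) < 3 * se

    def test_unknown_stratum_rejected(self):
        records = generate_cohort(small_config(n=50))
        with pytest.raises(ValueError):
            estimate_attendance(records, "pre", "lt30")


class TestMatching:
    @staticmethod
    def cost_cohort(post_acute_n, post_chronic_n, acute_bill=100.0, chronic_bill=200.0):
        rows = []
        for i in range(50):
            rows.append(dict(patient_id=f"pre-a{i}", setting="NUP", period="pre",
                             visit_type="acute", bill=acute_bill))
            rows.append(dict(patient_id=f"pre-c{i}", setting="NUP", period="pre",
                             visit_type="chronic", bill=chronic_bill))
        for i in range(post_acute_n):
            rows.append(dict(patient_id=f"post-a{i}", setting="NUP", period="post",
                             visit_type="acute", bill=acute_bill))
        for i in range(post_chronic_n):
            rows.append(dict(patient_id=f"post-c{i}", setting="NUP", period="post",
                             visit_type="chronic", bill=chronic_bill))
        return manual_cohort(rows)

    def test_matched_mean_uses_pre_period_mix(self):
        # post period 80:20 acute:chronic, pre 50:50 with stratum means
        # 100/200: the matched post mean is the 50:50 blend, 150
        records = self.cost_cohort(80, 20)
        costs = estimate_costs_matched(records, "NUP")
        assert costs["post"][0] == pytest.approx(150.0)
        assert costs["pre"][0] == pytest.approx(150.0)

    def test_identical_mixes_equal_plain_mean(self):
        records = self.cost_cohort(50, 50)
        costs = estimate_costs_matched(records, "NUP")
        post = records[(records["setting"] == "NUP") & (records["period"] == "post")]
        assert costs["post"][0] == pytest.approx(float(post["bill"].mean()))

    def test_matching_removes_case_mix_confounding_in_expectation(self):
        # same stratum bill laws in both periods, shifted mix: matched means agree
        config = GeneratorConfig(
            seed=13,
            n_patients={("NUP", "pre"): 40_000, ("NUP", "post"): 40_000},
            bill_means={
                ("NUP", "pre", "acute"): 80.0,
                ("NUP", "pre", "chronic"): 130.0,
                ("NUP", "post", "acute"): 80.0,
                ("NUP", "post", "chronic"): 130.0,
            },
            acute_fraction={"pre": 0.5, "post": 0.8},
        )
        records = generate_cohort(config)
        costs = estimate_costs_matched(records, "NUP")
        (m_pre, se_pre), (m_post, se_post) = costs["pre"], costs["post"]
        assert abs(m_pre - m_post) < 3 * np.hypot(se_pre, se_post)
        # while the raw post mean is visibly confounded by the mix shift
        raw_post = float(
            records[(records["setting"] == "NUP") & (records["period"] == "post")]["bill"].mean()
        )
        assert abs(raw_post - m_pre) > 3 * np.hypot(se_pre, se_post)

    def test_missing_stratum_raises_matching_error(self):
        records = self.cost_cohort(100, 0)
        with pytest.raises(MatchingError):
            estimate_costs_matched(records, "NUP")


class TestParameterRecovery:
    def test_ancillary_rows_pass_through(self, table):
        records = generate_cohort(small_config(n=3000))
        estimated = parameters_from_cohort(records, table)
        for name, arm in (("p_duplicate", "NGEMR"), ("c_admission", "shared"),
                          ("u_admitted", "shared"), ("c_ed_visit", "shared")):
            assert estimated.get(name, arm) == table.get(name, arm)

    def test_estimated_table_is_valid_and_close(self, table):
        records = generate_cohort(small_config(seed=3, n=8000))
        estimated = parameters_from_cohort(records, table)
        assert len(estimated) == 21
        for name, arm in (("p_wait_lt20", "EMR"), ("p_attend_lt20", "NGEMR"),
                          ("c_nup_visit", "EMR"), ("c_soc_visit", "NGEMR")):
            spec = estimated.get(name, arm)
            truth = table.get(name, arm).mean
            assert abs(spec.mean - truth) < 4 * spec.se

    def test_empty_cohort_propagates_estimation_error(self):
        records = generate_cohort(GeneratorConfig(seed=1, n_patients={}))
        with pytest.raises(EstimationError):
            parameters_from_cohort(records)

    def test_missing_ancillary_is_reported(self):
        records = generate_cohort(small_config(n=500))
        with pytest.raises(EstimationError, match="ancillary"):
            parameters_from_cohort(records, {})
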