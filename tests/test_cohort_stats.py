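"""Group comparisons, adjusted regressions, and report assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import respiradar as rr
from respiradar.cohort import CohortConfig, HIGH_GROUP, LOW_GROUP
from respiradar.cohort_stats import (
    SeparationError,
    build_report,
    compare_groups,
    mann_whitney_exact,
    write_report,
)

from _oracles import fisher_enumeration, mannwhitney_enumeration


def _toy_cohort(x_low, x_high, var="age_years"):
    rows = []
    for v in x_low:
        rows.append({var: v, "group": LOW_GROUP, "sex": "male"})
    for v in x_high:
        rows.append({var: v, "group": HIGH_GROUP, "sex": "male"})
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_samples_give_p_one(self):
        df = _toy_cohort([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert compare_groups(df, "age_years")["p_value"] == pytest.approx(1.0)

    def test_exact_small_sample_value(self):
        # x=[1,2] vs y=[3,4]: 6 rank assignments, two as extreme -> p = 1/3
        df = _toy_cohort([1.0, 2.0], [3.0, 4.0])
        res = compare_groups(df, "age_years")
        assert res["method"] == "mann-whitney-exact"
        assert res["p_value"] == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 7))
        # integer draws force ties through midranks
        x = rng.integers(0, 6, n1).astype(float)
        y = rng.integers(0, 6, n2).astype(float)
        _, p = mann_whitney_exact(x, y)
        assert p == pytest.approx(mannwhitney_enumeration(x, y), abs=1e-12)

    def test_large_samples_use_normal_approximation(self, rng):
        df = _toy_cohort(rng.normal(0, 1, 30), rng.normal(1, 1, 30))
        res = compare_groups(df, "age_years")
        assert res["method"] == "mann-whitney-asymptotic"
        assert res["p_value"] < 0.05

    def test_fisher_on_diagonal_table(self):
        # [[10,0],[0,10]] -> two-sided p = 2/C(20,10) = 2/184756
        df = pd.DataFrame(
            {
                "smoking": ["never"] * 10 + ["current"] * 10,
                "group": [LOW_GROUP] * 10 + [HIGH_GROUP] * 10,
            }
        )
        res = compare_groups(df, "smoking")
        assert res["method"] == "fisher-exact"
        assert res["p_value"] == pytest.approx(2.0 / 184756.0, rel=1e-9)
        assert res["p_value"] == pytest.approx(
            fisher_enumeration([[10, 0], [0, 10]]), rel=1e-9
        )

    def test_empty_group_rejected(self):
        df = _toy_cohort([1.0, 2.0], [])
        with pytest.raises(ValueError):
            compare_groups(df, "age_years")


class TestLinearAssociation:
    def _cohort(self, n, rng, beta=-0.5, noise=0.0):
        exposure = rng.uniform(0, 10, n)
        age = rng.uniform(50, 90, n)
        bmi = rng.uniform(20, 32, n)
        sex = rng.choice(["male", "female"], n)
        y = 3.0 + beta * exposure + noise * rng.normal(size=n)
        return pd.DataFrame(
            {
                "outcome": y,
                "exposure": exposure,
                "age_years": age,
                "bmi_kg_m2": bmi,
                "sex": sex,
                "group": rng.choice([LOW_GROUP, HIGH_GROUP], n),
            }
        )

    def test_noise_free_fit_is_exact(self, rng):
        df = self._cohort(60, rng)
        est = rr.fit_linear_association(df, "outcome", "exposure")
        assert est.coefficient == pytest.approx(-0.5, abs=1e-10)
        assert est.ci_high - est.ci_low == pytest.approx(0.0, abs=1e-8)

    def test_permutation_invariance(self, rng):
        df = self._cohort(80, rng, noise=1.0)
        est1 = rr.fit_linear_association(df, "outcome", "exposure")
        est2 = rr.fit_linear_association(
            df.sample(frac=1.0, random_state=1), "outcome", "exposure"
        )
        assert est1.coefficient == pytest.approx(est2.coefficient)
        assert est1.p_value == pytest.approx(est2.p_value)

    def test_rank_deficiency_reported_with_columns(self, rng):
        df = self._cohort(40, rng)
        df["bmi_kg_m2"] = df["age_years"]  # exact collinearity
        with pytest.raises(ValueError, match="rank deficient"):
            rr.fit_linear_association(df, "outcome", "exposure")

    def test_needs_more_rows_than_parameters(self, rng):
        df = self._cohort(4, rng)
        with pytest.raises(ValueError):
            rr.fit_linear_association(df, "outcome", "exposure")


class TestLogisticOr:
    def test_null_exposure_gives_or_near_one(self, rng):
        n = 4000
        df = pd.DataFrame(
            {
                "exposure": rng.normal(10, 3, n),
                "age_years": rng.uniform(50, 90, n),
                "bmi_kg_m2": rng.uniform(20, 32, n),
                "sex": rng.choice(["male", "female"], n),
                "group": rng.choice([LOW_GROUP, HIGH_GROUP], n),
            }
        )
        est = rr.fit_logistic_or(df, "exposure")
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_crude_equals_adjusted_without_confounding(self, rng):
        n = 6000
        exposure = rng.normal(0, 2, n)
        p = 1 / (1 + np.exp(-(0.4 * exposure)))
        df = pd.DataFrame(
            {
                "exposure": exposure,
                "age_years": rng.uniform(50, 90, n),
                "bmi_kg_m2": rng.uniform(20, 32, n),
                "sex": rng.choice(["male", "female"], n),
                "group": np.where(rng.uniform(size=n) < p, LOW_GROUP, HIGH_GROUP),
            }
        )
        crude = rr.fit_logistic_or(df, "exposure", adjusted=False)
        adj = rr.fit_logistic_or(df, "exposure", adjusted=True)
        assert np.log(adj.or_value) == pytest.approx(np.log(crude.or_value), abs=0.02)
        assert not crude.adjusted and adj.adjusted

    def test_complete_separation_flagged(self):
        df = pd.DataFrame(
            {
                "exposure": np.concatenate([np.zeros(10), np.ones(10) * 10]),
                "group": [HIGH_GROUP] * 10 + [LOW_GROUP] * 10,
                "age_years": 70.0,
                "bmi_kg_m2": 25.0,
                "sex": ["male"] * 20,
            }
        )
        with pytest.raises((SeparationError, ValueError)):
            rr.fit_logistic_or(df, "exposure", adjusted=False)


class TestReport:
    @pytest.fixture(scope="class")
    def cohort(self):
        return rr.cohort_to_frame(
            rr.generate_cohort(CohortConfig(seed=8), with_night_specs=False)
        )

    def test_odds_table_has_two_by_two_layout(self, cohort):
        report = build_report(cohort)
        odds = report["odds"]
        assert len(odds) == 4  # 2 exposures x {crude, adjusted}
        assert set(odds["model"]) == {"crude", "adjusted"}

    def test_report_regeneration_is_byte_identical(self, cohort, tmp_path):
        report = build_report(cohort)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_report(report, d1)
        write_report(build_report(cohort.copy()), d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_missing_biomarkers_marked_not_failed(self, cohort):
        stripped = cohort.copy()
        stripped["ntprobnp_pg_ml"] = np.nan
        report = build_report(stripped)
        assert "subgroup n=0" in str(report["biomarkers"].iloc[0].to_dict())

    def test_single_group_cohort_rejected(self, cohort):
        mono = cohort.copy()
        mono["group"] = LOW_GROUP
        with pytest.raises(ValueError, match="single-group"):
            build_report(mono)
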