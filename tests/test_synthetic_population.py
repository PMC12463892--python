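"""Cohort synthesis: truncated-normal ages, state assignment, CSV round-trip."""

import numpy as np
import pytest
from scipy import stats

import ckdsim as ck
from ckdsim.states import State

COHORT_N = 35412
AGE_MEAN, AGE_SD, AGE_MIN = 71.45, 8.18, 45


class TestGenerateAges:
    def test_deterministic_per_seed(self):
        a = ck.generate_ages(500, AGE_MEAN, AGE_SD, AGE_MIN, seed=9)
        b = ck.generate_ages(500, AGE_MEAN, AGE_SD, AGE_MIN, seed=9)
        assert np.array_equal(a, b)
        c = ck.generate_ages(500, AGE_MEAN, AGE_SD, AGE_MIN, seed=10)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mean_recovered(self, seed):
        """Half-year-corrected mean of floored draws matches the normal mean
        (truncation at z≈-3.2 shifts it negligibly; MC SE ≈ 0.04)."""
        ages = ck.generate_ages(COHORT_N, AGE_MEAN, AGE_SD, AGE_MIN, seed=seed)
        assert (ages + 0.5).mean() == pytest.approx(AGE_MEAN, abs=0.15)

    def test_bounds_and_integrality(self):
        ages = ck.generate_ages(20000, AGE_MEAN, AGE_SD, AGE_MIN, seed=4)
        assert ages.min() >= AGE_MIN
        assert ages.max() <= 104  # folded into the terminal [100, 105) bin
        assert np.issubdtype(ages.dtype, np.integer)

    def test_bin_masses_match_analytic(self):
        """Every 5-year bin's share is within 5 MC standard errors of the
        analytic truncated-normal mass."""
        n = 35412
        ages = ck.generate_ages(n, AGE_MEAN, AGE_SD, AGE_MIN, seed=2)
        a = (AGE_MIN - AGE_MEAN) / AGE_SD
        dist = stats.truncnorm(a, np.inf, loc=AGE_MEAN, scale=AGE_SD)
        for lo in range(45, 105, 5):
            hi = lo + 5
            mass = dist.cdf(hi) - dist.cdf(lo)
            if hi == 105:  # terminal bin absorbs the folded upper tail
                mass = 1.0 - dist.cdf(lo)
            observed = np.mean((ages >= lo) & (ages < hi))
            se = max(np.sqrt(mass * (1 - mass) / n), 1e-9)
            assert abs(observed - mass) <= 5 * se, f"bin {lo}"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 0},
            {"n": -5},
            {"sd": 0.0},
            {"sd": -1.0},
            {"min_age": 1000},  # no practical mass left
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(n=10, mean=AGE_MEAN, sd=AGE_SD, min_age=AGE_MIN, seed=0)
        base.update(kwargs)
        with pytest.raises(ck.ParameterError):
            ck.generate_ages(**base)


class TestBinAges:
    def test_direct_counts(self):
        table = ck.bin_ages([45, 45, 50], bin_width=5)
        by_bin = dict(zip(table["bin"], table["frequency"]))
        assert by_bin == {45: 2, 50: 1}
        pct = dict(zip(table["bin"], table["percentage"]))
        assert pct[45] == pytest.approx(66.6667, abs=1e-3)
        assert pct[50] == pytest.approx(33.3333, abs=1e-3)

    def test_conservation_and_total_percentage(self):
        ages = ck.generate_ages(5000, AGE_MEAN, AGE_SD, AGE_MIN, seed=5)
        table = ck.bin_ages(ages)
        assert table["frequency"].sum() == len(ages)
        assert table["percentage"].sum() == pytest.approx(100.0)
        assert table["cumulative_percentage"].iloc[-1] == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ck.EmptyInputError):
            ck.bin_ages([])

    def test_bad_width_rejected(self):
        with pytest.raises(ck.ParameterError):
            ck.bin_ages([50], bin_width=0)


class TestSynthesizeCohort:
    def test_no_ckd_boundary(self):
        cohort = ck.synthesize_cohort(ck.PopulationSpec(n=200, ckd_prevalence=0.0, seed=1))
        assert all(ind.state is State.AT_RISK for ind in cohort)

    def test_all_esrd_boundary(self):
        cohort = ck.synthesize_cohort(
            ck.PopulationSpec(n=200, ckd_prevalence=1.0, stage_v_fraction=1.0, seed=1)
        )
        assert all(ind.state is State.ESRD for ind in cohort)
        assert all(ind.stage_at_entry == "V" for ind in cohort)

    def test_ckd_count_binomial_bound(self):
        n, p = 10000, 0.3
        cohort = ck.synthesize_cohort(ck.PopulationSpec(n=n, ckd_prevalence=p, seed=7))
        ckd = sum(ind.state is not State.AT_RISK for ind in cohort)
        assert abs(ckd - n * p) <= 4 * np.sqrt(n * p * (1 - p))

    def test_entry_state_conservation(self, small_cohort):
        assert len(small_cohort) == 2000
        assert not any(ind.state is State.DEAD for ind in small_cohort)

    def test_high_risk_invariant(self, small_cohort):
        assert all(
            ind.hypertension or ind.diabetes or ind.age >= 65 for ind in small_cohort
        )

    def test_detected_fraction_splits_pre_esrd(self):
        cohort = ck.synthesize_cohort(
            ck.PopulationSpec(
                n=5000, ckd_prevalence=1.0, stage_v_fraction=0.0,
                detected_fraction=1.0, seed=2,
            )
        )
        assert all(ind.state is State.CKD_DIAGNOSED for ind in cohort)

    def test_invalid_proportion_rejected(self):
        with pytest.raises(ck.ParameterError):
            ck.PopulationSpec(ckd_prevalence=1.2)


class TestMicrodataRoundTrip:
    def test_round_trip_identity(self, small_cohort, tmp_path):
        path = tmp_path / "micro.csv"
        ck.write_microdata(small_cohort, path)
        back = ck.read_microdata(path)
        assert back == small_cohort

    def test_byte_identical_per_seed(self, tmp_path):
        spec = ck.PopulationSpec(n=300, seed=6)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        ck.write_microdata(ck.synthesize_cohort(spec), p1)
        ck.write_microdata(ck.synthesize_cohort(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_state_token(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,age,hypertension,diabetes,state,stage_at_entry\n"
            "0,70,1,0,ZOMBIE,NONE\n"
        )
        with pytest.raises(ck.FormatError, match="2"):
            ck.read_microdata(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,age,hypertension,diabetes,state,stage_at_entry\n"
            "0,70,1,0,AT_RISK,NONE\n"
            "1,seventy,1,0,AT_RISK,NONE\n"
        )
        with pytest.raises(ck.FormatError, match="3"):
            ck.read_microdata(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ck.EmptyInputError):
            ck.read_microdata(path)

    def test_header_only_file(self, tmp_path):
        path = tmp_path / "hdr.csv"
        path.write_text("id,age,hypertension,diabetes,state,stage_at_entry\n")
        with pytest.raises(ck.EmptyInputError):
            ck.read_microdata(path)

    def test_empty_cohort_write_rejected(self, tmp_path):
        with pytest.raises(ck.EmptyInputError):
            ck.write_microdata([], tmp_path / "x.csv")
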