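from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinaquant.phenotyping import (
    NormativeReference,
    classify_cohort,
    classify_eye,
    compare_proportions,
    fisher_exact_2x2,
    fit_normative_reference,
    prevalence_table,
    prevalence_with_ci,
    round_half_up,
)
from retinaquant.phenotyping.types import REFERENCE_PARAMETERS
from retinaquant.synthetic_data import CohortSpec, generate_cohort


def make_reference(mean=0.0, sd=1.0):
    return NormativeReference(
        means={p: mean for p in REFERENCE_PARAMETERS},
        sds={p: sd for p in REFERENCE_PARAMETERS},
    )


def fisher_oracle(a, b, c, d):
    """Two-sided exact p by explicit enumeration with binomial coefficients."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)

    def prob(k):
        return comb(row1, k) * comb(row2, col1 - k) / denom

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, col1 - row2), min(row1, col1) + 1):
        if prob(k) <= p_obs * (1 + 1e-7):
            total += prob(k)
    return min(total, 1.0)


class TestNormativeReference:
    def test_fit_recovers_moments(self):
        df, _ = generate_cohort(
            CohortSpec(n_control=10_000, n_dr_normal=0, n_dr_decreased=0,
                       prob_both_eyes=0.0, seed=31)
        )
        ref = fit_normative_reference(df)
        se = 0.005 / np.sqrt(len(df))
        assert abs(ref.means["vd_drcp"] - 0.072) < 2 * se
        assert ref.sds["vd_drcp"] == pytest.approx(0.005, rel=0.05)

    def test_matches_two_pass_oracle(self, rng):
        df = pd.DataFrame({p: rng.normal(10, 2, size=50) for p in REFERENCE_PARAMETERS})
        ref = fit_normative_reference(df)
        for p in REFERENCE_PARAMETERS:
            x = df[p].to_numpy()
            mean = sum(x) / len(x)
            var = sum((v - mean) ** 2 for v in x) / (len(x) - 1)
            assert ref.means[p] == pytest.approx(mean, abs=1e-12)
            assert ref.sds[p] == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_single_record_rejected(self):
        df = pd.DataFrame({p: [1.0] for p in REFERENCE_PARAMETERS})
        with pytest.raises(ValueError, match="two control eyes"):
            fit_normative_reference(df)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({p: [1.0, 1.0, 1.0] for p in REFERENCE_PARAMETERS})
        with pytest.raises(ValueError, match="zero variance"):
            fit_normative_reference(df)


class TestClassifyEye:
    def test_threshold_arithmetic(self):
        # mean 0.072, SD 0.005 -> decrease threshold 0.0622
        ref = make_reference()
        ref.means["vd_drcp"], ref.sds["vd_drcp"] = 0.072, 0.005
        assert ref.threshold("vd_drcp_decrease") == pytest.approx(0.0622)
        record = {p: 0.0 for p in REFERENCE_PARAMETERS}
        record["vd_drcp"] = 0.060
        flags = classify_eye(record, ref)
        assert flags.vd_drcp_decrease
        assert flags.ischemia

    def test_record_at_mean_no_flags(self):
        ref = make_reference(mean=5.0)
        record = {p: 5.0 for p in REFERENCE_PARAMETERS}
        flags = classify_eye(record, ref)
        assert not any(flags.as_dict().values())

    def test_exactly_at_threshold_not_flagged(self):
        ref = make_reference()
        record = {p: 0.0 for p in REFERENCE_PARAMETERS}
        record["gcl_ipl_um"] = -1.96  # exactly mean - 1.96 SD: strict rule
        assert not classify_eye(record, ref).gcl_ipl_thinning
        record["gcl_ipl_um"] = -1.9601
        assert classify_eye(record, ref).gcl_ipl_thinning

    def test_missing_parameter_fails_loudly(self):
        ref = make_reference()
        record = {p: 0.0 for p in REFERENCE_PARAMETERS if p != "opl_um"}
        with pytest.raises(ValueError, match="opl_um"):
            classify_eye(record, ref)

    def test_composites_are_stated_disjunctions(self):
        ref = make_reference()
        for component, composite in [
            ("vd_srcp", "ischemia"), ("rnfl_um", "neurodegeneration"),
            ("inl_um", "subclinical_edema"),
        ]:
            record = {p: 0.0 for p in REFERENCE_PARAMETERS}
            record[component] = 5.0 if component == "inl_um" else -5.0
            flags = classify_eye(record, ref)
            assert getattr(flags, composite)

    def test_null_flag_rate_near_tail(self):
        # 100,000 standard-normal control eyes: each one-sided flag ~2.5%
        rng = np.random.default_rng(77)
        df = pd.DataFrame(
            {p: rng.standard_normal(100_000) for p in REFERENCE_PARAMETERS}
        )
        flags = classify_cohort(df, make_reference())
        for component in (
            "vd_srcp_decrease", "faz_increase", "gcl_ipl_thinning", "opl_thickening"
        ):
            rate = flags[component].mean()
            assert rate == pytest.approx(0.025, abs=0.003)

    def test_vectorised_matches_scalar(self, rng):
        ref = make_reference()
        df = pd.DataFrame({p: rng.standard_normal(200) for p in REFERENCE_PARAMETERS})
        flags = classify_cohort(df, ref)
        for i in (0, 17, 100):
            scalar = classify_eye(df.iloc[i].to_dict(), ref).as_dict()
            for key, value in scalar.items():
                assert bool(flags.iloc[i][key]) == value


class TestPrevalenceCI:
    @pytest.mark.parametrize(
        "count,n,percent,lower,upper",
        [
            (17, 88, 19.3, 11.1, 27.6),
            (21, 44, 47.7, 33.0, 62.5),
            (2, 88, 2.3, 0.0, 5.4),
            (5, 44, 11.4, 2.0, 20.7),
            (4, 44, 9.1, 0.6, 17.6),
            (16, 24, 66.7, 47.8, 85.5),
            (0, 88, 0.0, 0.0, 0.0),
        ],
    )
    def test_printed_cells(self, count, n, percent, lower, upper):
        ci = prevalence_with_ci(count, n)
        assert (ci.percent, ci.lower, ci.upper) == (percent, lower, upper)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            prevalence_with_ci(5, 0)
        with pytest.raises(ValueError):
            prevalence_with_ci(-1, 10)
        with pytest.raises(ValueError):
            prevalence_with_ci(11, 10)

    def test_round_half_up(self):
        assert round_half_up(2.25, 1) == 2.3
        assert round_half_up(2.24, 1) == 2.2
        assert round_half_up(0.0005, 3) == 0.001

    @given(count=st.integers(0, 200), n=st.integers(1, 200))
    @settings(max_examples=200, deadline=None)
    def test_interval_invariants(self, count, n):
        if count > n:
            count = n
        ci = prevalence_with_ci(count, n)
        assert 0 <= ci.lower <= ci.percent <= ci.upper <= 100


class TestContingency:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[0, 88], [5, 39]], 0.004),   # composite neurodegeneration row
            ([[0, 88], [4, 40]], 0.011),   # GCL-IPL thinning row
            ([[0, 88], [2, 42]], 0.109),   # RNFL thinning row
            ([[17, 71], [21, 23]], 0.001), # composite ischemia row
        ],
    )
    def test_printed_p_values(self, table, expected):
        assert round(fisher_exact_2x2(np.array(table)), 3) == expected

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_factorial_enumeration(self, a, b, c, d):
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        table = np.array([[a, b], [c, d]])
        assert fisher_exact_2x2(table) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-9
        )

    def test_symmetry_under_row_and_column_swap(self):
        table = np.array([[3, 10], [8, 2]])
        p = fisher_exact_2x2(table)
        assert fisher_exact_2x2(table[::-1]) == pytest.approx(p)
        assert fisher_exact_2x2(table[:, ::-1]) == pytest.approx(p)

    def test_2xk_uses_chi2(self):
        table = np.array([[8, 13, 17], [48, 39, 7]])
        res = compare_proportions(table)
        assert res.method == "chi2"
        from scipy.stats import chi2_contingency

        expected = chi2_contingency(table, correction=False)[1]
        assert res.p_value == pytest.approx(expected)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            compare_proportions(np.array([[0, 0], [3, 4]]))


class TestComposition:
    def test_prevalence_table_layout(self):
        rng = np.random.default_rng(3)
        flags = pd.DataFrame({
            "vd_drcp_decrease": rng.integers(0, 2, 60),
            "ischemia": rng.integers(0, 2, 60),
        })
        groups = pd.Series(["a"] * 30 + ["b"] * 30)
        table = prevalence_table(flags, groups)
        assert "a_pct_ci" in table.columns and "b_count" in table.columns
        assert set(table.index) == {"vd_drcp_decrease", "ischemia"}

    def test_composite_monotone(self, rng):
        # setting any component true never unsets a composite
        ref = make_reference()
        base = {p: 0.0 for p in REFERENCE_PARAMETERS}
        base["vd_drcp"] = -5.0
        flags = classify_eye(base, ref)
        assert flags.ischemia
        base["faz_area_mm2"] = 5.0
        assert classify_eye(base, ref).ischemia
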