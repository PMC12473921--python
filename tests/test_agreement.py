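import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from lumbargait import (
    BAResult,
    EstimationError,
    PBResult,
    ba_from_loa,
    bland_altman,
    classify_agreement,
    paired_test,
    passing_bablok,
)


def _pb_oracle(x, y, conf=0.95):
    """Exhaustive pairwise-slope median with K-shift (independent loops)."""
    n = len(x)
    S = []
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] != x[i]:
                s = (y[j] - y[i]) / (x[j] - x[i])
                if s != -1.0:
                    S.append(s)
    S = sorted(S)
    N = len(S)
    K = sum(1 for s in S if s < -1.0)
    if N % 2 == 1:
        m = S[(N - 1) // 2 + K]
    else:
        m = 0.5 * (S[N // 2 - 1 + K] + S[N // 2 + K])
    return m, S, K


class TestPairedTest:
    def test_constant_shift_detected_by_t_test(self):
        rng = np.random.default_rng(10)
        b = rng.normal(10.0, 1.0, 30)
        a = b + 0.5 + rng.normal(0.0, 1e-6, 30)  # tiny jitter: sd > 0
        res = paired_test(a, b)
        assert res.test_used == "t_test"
        assert res.p_value < 1e-6
        assert res.significant

    def test_t_p_value_matches_closed_form(self):
        rng = np.random.default_rng(11)
        d = rng.normal(size=30)
        b = rng.normal(50.0, 5.0, 30)
        a = b + d
        res = paired_test(a, b)
        assert res.test_used == "t_test"
        t_stat = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(30))
        p = 2.0 * stats.t.sf(abs(t_stat), df=29)
        assert res.statistic == pytest.approx(t_stat, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_skewed_differences_fall_back_to_wilcoxon(self):
        rng = np.random.default_rng(12)
        d = rng.exponential(1.0, 30) - 1.0
        b = rng.normal(50.0, 5.0, 30)
        res = paired_test(b + d, b)
        assert stats.shapiro(d).pvalue < 0.05  # precondition of this seed
        assert res.test_used == "wilcoxon"

    def test_all_zero_differences_rejected(self):
        a = np.ones(10)
        with pytest.raises(EstimationError):
            paired_test(a, a)


class TestPassingBablok:
    def test_identity_line(self):
        x = np.arange(12, dtype=float)
        pb = passing_bablok(x, x)
        assert pb.m == pytest.approx(1.0)
        assert pb.q == pytest.approx(0.0)
        assert pb.ci_m[0] <= 1.0 <= pb.ci_m[1]
        assert pb.ci_q[0] <= 0.0 <= pb.ci_q[1]
        assert not pb.proportional_error and not pb.constant_error

    def test_exact_linear_data(self):
        x = np.linspace(0.0, 11.0, 12)
        pb = passing_bablok(x, 2.0 * x + 1.0)
        assert pb.m == pytest.approx(2.0)
        assert pb.q == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_slope_equals_exhaustive_pairwise_median(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 21)
        x = rng.normal(50.0, 10.0, n)
        y = rng.uniform(0.3, 2.0) * x + rng.normal(0.0, 3.0, n)
        pb = passing_bablok(x, y)
        m_oracle, _, _ = _pb_oracle(x, y)
        assert pb.m == pytest.approx(m_oracle, abs=1e-12)

    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        c=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_scale_equivariance(self, seed, c):
        rng = np.random.default_rng(seed)
        x = rng.normal(50.0, 10.0, 15)
        y = x + rng.normal(0.0, 2.0, 15)
        pb1 = passing_bablok(x, y)
        pb2 = passing_bablok(c * x, c * y)
        assert pb2.m == pytest.approx(pb1.m, rel=1e-9)

    def test_swapped_arguments_invert_slope_on_exact_linear_data(self):
        x = np.linspace(1.0, 12.0, 12)
        y = 2.0 * x + 1.0
        forward = passing_bablok(x, y)
        backward = passing_bablok(y, x)
        assert backward.m == pytest.approx(1.0 / forward.m)

    def test_small_sample_rejected(self):
        x = np.arange(5, dtype=float)
        with pytest.raises(EstimationError):
            passing_bablok(x, x)

    def test_constant_x_rejected(self):
        with pytest.raises(EstimationError):
            passing_bablok(np.ones(12), np.arange(12, dtype=float))

    def test_interval_coverage_and_power(self):
        # coverage of the slope interval in 90-99% of replicates at the
        # identity, and >90% power against slope 0.4 (n=30, errors in
        # both methods as the model assumes)
        rng = np.random.default_rng(100)
        reps = 300
        cover = fire_at_04 = 0
        for _ in range(reps):
            t = rng.normal(60.0, 3.6, 30)
            x = t + rng.normal(0.0, 1.5, 30)
            y_id = t + rng.normal(0.0, 1.5, 30)
            y_04 = 0.4 * t + 35.0 + rng.normal(0.0, 1.5, 30)
            pb_id = passing_bablok(x, y_id)
            cover += pb_id.ci_m[0] <= 1.0 <= pb_id.ci_m[1]
            fire_at_04 += passing_bablok(x, y_04).proportional_error
        assert 0.90 <= cover / reps <= 0.99
        assert fire_at_04 / reps > 0.90


class TestBlandAltman:
    def test_constant_difference(self):
        a = np.array([2.0, 3.0, 4.0, 5.0])
        ba = bland_altman(a, a - 1.0)
        assert ba.bias == pytest.approx(1.0)
        assert ba.sd == 0.0
        assert ba.loa == (pytest.approx(1.0), pytest.approx(1.0))

    def test_fields_match_closed_form(self):
        rng = np.random.default_rng(13)
        d = rng.normal(0.3, 1.2, 50)
        b = rng.normal(100.0, 5.0, 50)
        ba = bland_altman(b + d, b)
        bias = d.mean()
        sd = d.std(ddof=1)
        assert ba.bias == pytest.approx(bias, abs=1e-12)
        assert ba.loa[0] == pytest.approx(bias - 1.96 * sd, abs=1e-12)
        assert ba.loa[1] == pytest.approx(bias + 1.96 * sd, abs=1e-12)
        assert ba.ci_bias[0] == pytest.approx(bias - 1.96 * sd / np.sqrt(50), abs=1e-12)
        assert ba.ci_bias[1] == pytest.approx(bias + 1.96 * sd / np.sqrt(50), abs=1e-12)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_midpoint_and_width_identities(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        ba = bland_altman(a, b)
        assert ba.bias == pytest.approx(0.5 * (ba.loa[0] + ba.loa[1]), abs=1e-9)
        loa_width = ba.loa[1] - ba.loa[0]
        ci_width = ba.ci_bias[1] - ba.ci_bias[0]
        if loa_width > 0:
            assert ci_width / loa_width == pytest.approx(1.0 / np.sqrt(n), abs=1e-9)

    def test_single_pair_rejected(self):
        with pytest.raises(EstimationError):
            bland_altman(np.array([1.0]), np.array([2.0]))

    def test_reconstruction_from_limits_of_agreement(self):
        # a reported cadence comparison (n=30): LOA (-0.70, 1.50) implies
        # bias 0.40 and bias CI (0.20, 0.60)
        ba = ba_from_loa(-0.70, 1.50, 30)
        assert ba.bias == pytest.approx(0.40, abs=1e-12)
        assert ba.ci_bias[0] == pytest.approx(0.20, abs=0.005)
        assert ba.ci_bias[1] == pytest.approx(0.60, abs=0.005)


class TestClassifyAgreement:
    def _pb(self, m, ci_m, q=0.0, ci_q=(-0.1, 0.1)):
        return PBResult(
            m=m, q=q, ci_m=ci_m, ci_q=ci_q,
            proportional_error=not (ci_m[0] <= 1.0 <= ci_m[1]),
            constant_error=not (ci_q[0] <= 0.0 <= ci_q[1]),
            n=30,
        )

    def _ba(self, bias, ci):
        return BAResult(bias=bias, ci_bias=ci, loa=(bias - 1, bias + 1), n=30, sd=0.5)

    def test_proportional_error_means_no_agreement(self):
        # a stance-like comparison: slope CI (0.14, 0.79) excludes 1
        v = classify_agreement(
            self._pb(0.41, (0.14, 0.79), q=35.36, ci_q=(12.99, 51.87)),
            self._ba(0.13, (-0.58, 0.84)),
            parameter="stance",
        )
        assert v.level == "no_agreement"
        assert "proportional" in v.error_type or v.error_type == "both"

    def test_clean_parameter_agrees_with_no_error(self):
        v = classify_agreement(
            self._pb(1.00, (0.97, 1.00), q=0.0, ci_q=(0.00, 0.03)),
            self._ba(-0.02, (-0.04, 0.00)),
            parameter="gct",
        )
        assert v.level == "agreement"
        assert v.error_type == "none"

    def test_constant_only_error_keeps_agreement_with_flag(self):
        # cadence-like: slope interval contains 1 but the bias interval
        # excludes 0 -> agreement with a constant-error flag
        v = classify_agreement(
            self._pb(1.0, (0.98, 1.02)),
            self._ba(0.40, (0.20, 0.60)),
            parameter="cadence",
        )
        assert v.level == "agreement"
        assert v.error_type == "constant"
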