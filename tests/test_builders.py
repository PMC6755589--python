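"""Bit counting, the two-proportion Z-test and the DFP / SB-DFP rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from sbdfp import (
    UNATTAINABLE,
    BitCountProfile,
    BitMatrix,
    SchemeMismatchError,
    build_dfp,
    build_sbdfp,
    count_bits,
    min_significant_count,
    two_proportion_ztest,
)

# the in-set worked instance: MACCS bit 100 of a 15.4M-compound reference
REF_COUNT, REF_N = 10_892_579, 15_403_690


class TestCountBits:
    def test_direct_column_sums(self, small_matrix):
        prof = count_bits(small_matrix)
        assert prof.counts.tolist() == [1, 2, 1]
        assert prof.n_obs == 2
        assert prof.scheme_tag == "toy"

    def test_all_zero_rows(self):
        m = BitMatrix(ids=["a", "b"], rows=np.zeros((2, 4)), scheme_tag="t")
        assert count_bits(m).counts.tolist() == [0, 0, 0, 0]

    def test_matches_loop_oracle(self, random_matrix):
        prof = count_bits(random_matrix)
        for j in range(random_matrix.n_bits):
            expected = sum(int(row[j]) for row in random_matrix.rows)
            assert prof.counts[j] == expected


class TestTwoProportionZTest:
    def test_worked_example_significant_count(self):
        r = two_proportion_ztest(268, 350, REF_COUNT, REF_N)
        assert r.p_one_sided == pytest.approx(0.008, abs=5e-4)
        assert r.p_t == pytest.approx(0.766, abs=5e-4)
        assert r.p_r == pytest.approx(0.707, abs=5e-4)

    def test_worked_example_insignificant_count(self):
        # a larger-looking proportion that is not significantly larger
        r = two_proportion_ztest(248, 350, REF_COUNT, REF_N)
        assert r.p_one_sided == pytest.approx(0.476, abs=1e-3)
        assert r.p_t == pytest.approx(0.708, abs=1e-3)  # exact 0.70857

    def test_equal_proportions_give_half(self):
        r = two_proportion_ztest(50, 100, 500, 1000)
        assert r.z == 0.0
        assert r.p_one_sided == 0.5

    @pytest.mark.parametrize("ct,cr", [(0, 0), (100, 1000)])
    def test_degenerate_pooled_proportion(self, ct, cr):
        # pooled proportion 0 or 1 forces p_t == p_r: defined as z=0, p=0.5
        r = two_proportion_ztest(ct, 100, cr, 1000)
        assert r.z == 0.0
        assert r.p_one_sided == 0.5

    @pytest.mark.parametrize(
        "ct,nt,cr,nr",
        [(-1, 10, 5, 10), (11, 10, 5, 10), (5, 10, 11, 10), (5, 0, 5, 10)],
    )
    def test_invalid_counts_rejected(self, ct, nt, cr, nr):
        with pytest.raises(ValueError):
            two_proportion_ztest(ct, nt, cr, nr)

    def test_pooled_proportion_between_the_two(self):
        r = two_proportion_ztest(8, 10, 30, 100)
        assert min(r.p_t, r.p_r) <= r.pooled_p <= max(r.p_t, r.p_r)

    def test_monotone_in_target_count_exhaustive_grid(self):
        # p-value non-increasing in count_t for every small configuration
        for n_t in (1, 2, 5, 11):
            for n_r in (1, 7, 20):
                for c_r in range(n_r + 1):
                    ps = [
                        two_proportion_ztest(k, n_t, c_r, n_r).p_one_sided
                        for k in range(n_t + 1)
                    ]
                    assert all(
                        a >= b - 1e-12 for a, b in zip(ps, ps[1:])
                    ), (n_t, c_r, n_r)

    @given(
        nt=st.integers(1, 40),
        nr=st.integers(1, 40),
        data=st.data(),
    )
    @settings(derandomize=True, max_examples=150)
    def test_z_antisymmetric_under_swap(self, nt, nr, data):
        ct = data.draw(st.integers(0, nt))
        cr = data.draw(st.integers(0, nr))
        z_ab = two_proportion_ztest(ct, nt, cr, nr).z
        z_ba = two_proportion_ztest(cr, nr, ct, nt).z
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)

    def test_statsmodels_cross_check(self, rng):
        # independent reference implementation of the pooled one-sided test
        sm = pytest.importorskip("statsmodels.stats.proportion")
        for _ in range(50):
            nt = int(rng.integers(2, 500))
            nr = int(rng.integers(2, 5000))
            ct = int(rng.integers(0, nt + 1))
            cr = int(rng.integers(0, nr + 1))
            r = two_proportion_ztest(ct, nt, cr, nr)
            z_sm, p_sm = sm.proportions_ztest(
                [ct, cr], [nt, nr], alternative="larger"
            )
            if np.isnan(z_sm):  # statsmodels leaves the degenerate case NaN
                assert r.p_one_sided == 0.5
            else:
                assert r.z == pytest.approx(z_sm, abs=1e-10)
                assert r.p_one_sided == pytest.approx(p_sm, abs=1e-10)

    def test_one_sample_normal_limit(self):
        # as n_r -> infinity with p_r fixed, the test converges to the
        # one-sample approximation z = (p_t - p_r)/sqrt(p_r(1-p_r)/n_t)
        n_r = 10**9
        p_r_vals = [0.1, 0.3, 0.707]
        for p_r in p_r_vals:
            c_r = int(round(p_r * n_r))
            for c_t, n_t in [(30, 100), (80, 100), (268, 350)]:
                p = two_proportion_ztest(c_t, n_t, c_r, n_r).p_one_sided
                p_t = c_t / n_t
                pr_eff = c_r / n_r
                z1 = (p_t - pr_eff) / np.sqrt(pr_eff * (1 - pr_eff) / n_t)
                assert p == pytest.approx(norm.sf(z1), abs=5e-4)


class TestBuildDfp:
    def test_tie_at_threshold_sets_bit(self):
        prof = BitCountProfile(counts=[1, 2, 1], n_obs=2, scheme_tag="t")
        assert build_dfp(prof, 0.5).bits.tolist() == [1, 1, 1]

    def test_identical_rows_reproduce_the_row(self, rng):
        row = (rng.random(64) < 0.4).astype(np.uint8)
        m = BitMatrix(
            ids=[f"m{i}" for i in range(9)],
            rows=np.tile(row, (9, 1)),
            scheme_tag="t",
        )
        for thr in (0.3, 0.5, 1.0):
            assert (build_dfp(count_bits(m), thr).bits == row).all()

    def test_matches_per_bit_brute_force(self, rng):
        counts = rng.integers(0, 501, size=166)
        prof = BitCountProfile(counts=counts, n_obs=500, scheme_tag="t")
        fp = build_dfp(prof, 0.5)
        for j in range(166):
            assert fp.bits[j] == (1 if counts[j] / 500 >= 0.5 else 0)

    @pytest.mark.parametrize("thr", [0.0, -0.1, 1.5])
    def test_invalid_threshold(self, thr):
        prof = BitCountProfile(counts=[1], n_obs=2, scheme_tag="t")
        with pytest.raises(ValueError):
            build_dfp(prof, thr)


class TestBuildSbdfp:
    def test_worked_example_bit_decisions(self):
        ref = BitCountProfile(counts=[REF_COUNT], n_obs=REF_N, scheme_tag="m")
        hit = BitCountProfile(counts=[268], n_obs=350, scheme_tag="m")
        miss = BitCountProfile(counts=[248], n_obs=350, scheme_tag="m")
        assert build_sbdfp(hit, ref, alpha=0.01).bits.tolist() == [1]
        assert build_sbdfp(miss, ref, alpha=0.01).bits.tolist() == [0]

    def test_identical_profiles_give_all_zero(self, rng):
        counts = rng.integers(0, 101, size=32)
        prof = BitCountProfile(counts=counts, n_obs=100, scheme_tag="t")
        assert build_sbdfp(prof, prof).n_on_bits == 0

    def test_matches_per_bit_brute_force(self, rng):
        target = BitCountProfile(
            counts=rng.integers(0, 201, size=80), n_obs=200, scheme_tag="t"
        )
        ref = BitCountProfile(
            counts=rng.integers(0, 10001, size=80), n_obs=10000, scheme_tag="t"
        )
        fp = build_sbdfp(target, ref, alpha=0.01)
        for j in range(80):
            p = two_proportion_ztest(
                int(target.counts[j]), 200, int(ref.counts[j]), 10000
            ).p_one_sided
            assert fp.bits[j] == (1 if p < 0.01 else 0)

    def test_set_bit_entails_larger_proportion(self, rng):
        target = BitCountProfile(
            counts=rng.integers(0, 51, size=100), n_obs=50, scheme_tag="t"
        )
        ref = BitCountProfile(
            counts=rng.integers(0, 1001, size=100), n_obs=1000, scheme_tag="t"
        )
        fp = build_sbdfp(target, ref, alpha=0.05)
        on = fp.bits.astype(bool)
        assert (target.proportions[on] > ref.proportions[on]).all()

    def test_scheme_mismatch_rejected(self):
        a = BitCountProfile(counts=[1], n_obs=2, scheme_tag="x")
        b = BitCountProfile(counts=[1], n_obs=2, scheme_tag="y")
        with pytest.raises(SchemeMismatchError):
            build_sbdfp(a, b)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.5])
    def test_invalid_alpha_rejected(self, alpha):
        prof = BitCountProfile(counts=[1], n_obs=2, scheme_tag="t")
        with pytest.raises(ValueError):
            build_sbdfp(prof, prof, alpha=alpha)


class TestMinSignificantCount:
    def test_worked_example(self):
        assert min_significant_count(350, REF_COUNT, REF_N, 0.01) == 268

    def test_boundary_property(self):
        k = min_significant_count(350, REF_COUNT, REF_N, 0.01)
        assert two_proportion_ztest(k, 350, REF_COUNT, REF_N).p_one_sided < 0.01
        assert two_proportion_ztest(k - 1, 350, REF_COUNT, REF_N).p_one_sided >= 0.01

    def test_matches_exhaustive_scan_on_small_instances(self, rng):
        for _ in range(60):
            n_t = int(rng.integers(1, 31))
            n_r = int(rng.integers(1, 1001))
            c_r = int(rng.integers(0, n_r + 1))
            alpha = float(rng.choice([0.001, 0.01, 0.05, 0.1]))
            expected = UNATTAINABLE
            for k in range(n_t + 1):
                if two_proportion_ztest(k, n_t, c_r, n_r).p_one_sided < alpha:
                    expected = k
                    break
            assert min_significant_count(n_t, c_r, n_r, alpha) == expected

    def test_unattainable_when_reference_saturated(self):
        # reference all-ones: no target count can be significantly higher
        assert min_significant_count(10, 1000, 1000, 0.01) is UNATTAINABLE
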