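"""Design construction: stage-one size, interim estimators, stage-two rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gehanflex import (
    DesignParams,
    GehanDesign,
    build_gehan_design,
    cp_interval,
    interim_conservative,
    interim_original,
    n2_fEL,
    n2_fG,
    n2_fL,
    normal_quantile,
    stage_one_size,
)
from gehanflex.binom import cp_length_many, pmf_vector
from conftest import dupuis_params


class TestStageOneSize:
    @pytest.mark.parametrize(
        "pi1, beta1, expected",
        [(0.3, 0.1, 7), (1.0, 0.5, 1), (0.2, 0.05, 14), (0.5, 0.05, 5)],
    )
    def test_examples(self, pi1, beta1, expected):
        assert stage_one_size(pi1, beta1) == expected

    @settings(derandomize=True, max_examples=50)
    @given(
        pi1=st.floats(min_value=0.05, max_value=0.99),
        beta1=st.floats(min_value=0.01, max_value=0.5),
    )
    def test_minimality(self, pi1, beta1):
        n1 = stage_one_size(pi1, beta1)
        assert (1 - pi1) ** n1 <= beta1 + 1e-12
        if n1 > 1:
            assert (1 - pi1) ** (n1 - 1) > beta1 - 1e-9

    def test_domain(self):
        with pytest.raises(ValueError):
            stage_one_size(0.0, 0.1)


class TestInterimEstimators:
    def test_original_boundaries(self):
        assert interim_original(7, 7, 0.75) == 1.0  # clipped at 1
        assert interim_original(0, 7, 0.75) == 0.0

    def test_original_formula(self):
        z = normal_quantile(0.875)
        expected = 1 / 7 + z * math.sqrt(1 * 6 / 7**3)
        assert interim_original(1, 7, 0.75) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.2950, abs=5e-5)

    @settings(derandomize=True, max_examples=40)
    @given(n1=st.integers(min_value=1, max_value=30), s1=st.integers(min_value=0, max_value=30))
    def test_original_at_least_mle(self, n1, s1):
        s1 = min(s1, n1)
        assert interim_original(s1, n1) >= s1 / n1 - 1e-12

    def test_conservative_all_successes(self):
        assert interim_conservative(7, 7, 0.75) == pytest.approx(
            0.125 ** (1 / 7), abs=1e-12
        )

    def test_conservative_mle_at_half(self):
        # The MLE is exactly 1/2: distance zero wins outright.
        assert interim_conservative(2, 4, 0.75) == 0.5

    def test_conservative_picks_candidate_closest_to_half(self):
        lo, hi = cp_interval(1, 7, 0.25)  # 75% interval: 12.5% tails
        cands = [lo, hi, 1 / 7]
        expected = min(cands, key=lambda x: abs(x - 0.5))
        assert interim_conservative(1, 7, 0.75) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(n1=st.integers(min_value=2, max_value=25), s1=st.integers(min_value=1, max_value=25))
    def test_conservative_within_exact_limits(self, n1, s1):
        s1 = min(s1, n1 - 1)
        lo, hi = cp_interval(s1, n1, 0.25)
        est = interim_conservative(s1, n1, 0.75)
        assert lo - 1e-12 <= est <= hi + 1e-12

    def test_conservative_undefined_at_zero(self):
        with pytest.raises(ValueError):
            interim_conservative(0, 7)


class TestStageTwoRules:
    def test_fg_zero_variance(self):
        assert n2_fG(1.0, 7, 0.1) == 0
        assert n2_fG(0.0, 7, 0.1) == 0

    def test_fg_worked_values(self):
        assert n2_fG(interim_original(1, 7), 7, 0.1) == 14
        assert n2_fG(interim_conservative(7, 7), 7, 0.1) == 13

    def test_fg_closed_form_cross_check(self):
        for pi_hat in (0.21, 0.5, 0.88):
            for n1, gamma in [(7, 0.1), (11, 0.05), (14, 0.2)]:
                closed = max(0, math.ceil(pi_hat * (1 - pi_hat) / gamma**2 - n1 - 1e-12))
                assert n2_fG(pi_hat, n1, gamma) == closed

    def test_fl_constant_for_worked_design(self):
        for s1 in (1, 7):
            assert n2_fL(s1, 7, 0.1, 0.05) == 21

    def test_fl_guarantee(self):
        # For the returned n2, every reachable outcome meets the length target.
        z = normal_quantile(0.975)
        for s1 in (1, 4, 7):
            n2 = n2_fL(s1, 7, 0.1, 0.05)
            lengths = cp_length_many(np.arange(s1, s1 + n2 + 1), 7 + n2, 0.05)
            assert lengths.max() <= 2 * 0.1 * z + 1e-12

    def test_fl_small_instance_matches_brute_scan(self):
        z = normal_quantile(0.975)
        for s1 in (1, 2, 3):
            expected = next(
                n2
                for n2 in range(500)
                if 0.5 / z * cp_length_many(
                    np.arange(s1, s1 + n2 + 1), 3 + n2, 0.05
                ).max()
                <= 0.3 + 1e-12
            )
            assert n2_fL(s1, 3, 0.3, 0.05) == expected

    def test_fel_worked_values(self):
        assert n2_fEL(interim_original(1, 7), 1, 7, 0.1, 0.05) == 14
        assert n2_fEL(interim_conservative(7, 7), 7, 7, 0.1, 0.05) == 6

    def test_fel_degenerate_estimate_matches_direct_summation(self):
        # pi_hat = 1: stage two is deterministic, the expected length is the
        # length at s2 = n2.
        z = normal_quantile(0.975)
        n2 = n2_fEL(1.0, 7, 7, 0.1, 0.05)
        length = float(cp_length_many(np.array([7 + n2]), 7 + n2, 0.05)[0])
        assert 0.5 / z * length <= 0.1 + 1e-12
        if n2 > 0:
            prev = float(cp_length_many(np.array([7 + n2 - 1]), 7 + n2 - 1, 0.05)[0])
            assert 0.5 / z * prev > 0.1 - 1e-12

    def test_fel_expected_length_is_pmf_weighted(self):
        # Cross-check the defining sum at the returned size.
        z = normal_quantile(0.975)
        pi_hat = interim_original(1, 7)
        n2 = n2_fEL(pi_hat, 1, 7, 0.1, 0.05)
        lengths = cp_length_many(np.arange(1, 1 + n2 + 1), 7 + n2, 0.05)
        el = float(pmf_vector(n2, pi_hat) @ lengths)
        assert 0.5 / z * el <= 0.1 + 1e-12

    @settings(derandomize=True, max_examples=25)
    @given(
        pi_hat=st.floats(min_value=0.0, max_value=1.0),
        n1=st.integers(min_value=1, max_value=20),
        gamma=st.floats(min_value=0.05, max_value=0.5),
    )
    def test_fg_minimality(self, pi_hat, n1, gamma):
        n2 = n2_fG(pi_hat, n1, gamma)
        var = pi_hat * (1 - pi_hat)
        assert var / (n1 + n2) <= gamma**2 + 1e-12
        if n2 > 0:
            assert var / (n1 + n2 - 1) > gamma**2 - 1e-12

    def test_gamma_monotonicity(self):
        # Tightening the precision bound never shrinks a stage-two size.
        for rule in ("f_G", "f_L", "f_EL"):
            prev = None
            for gamma in (0.2, 0.15, 0.1, 0.08):
                params = dupuis_params("original", rule, gamma=gamma)
                sched = build_gehan_design(params).n2_schedule
                if prev is not None:
                    assert all(a >= b for a, b in zip(sched, prev))
                prev = sched


class TestBuildDesign:
    def test_worked_schedules(self, dupuis_original_fg, dupuis_conservative_fg,
                              dupuis_original_fl):
        assert dupuis_original_fg.design.n2_schedule == (0, 14, 18, 16, 10, 2, 0, 0)
        assert dupuis_conservative_fg.design.n2_schedule == (
            0, 18, 18, 18, 18, 18, 18, 13)
        assert dupuis_original_fl.design.n2_schedule == (0,) + (21,) * 7

    def test_vacuous_precision_gives_empty_stage_two(self):
        params = dupuis_params("original", "f_G", gamma=1.0)
        assert build_gehan_design(params).n2_schedule == (0,) * 8

    def test_schedule_minimality_recheck(self, dupuis_original_fg):
        design = dupuis_original_fg.design
        for s1 in range(1, design.n1 + 1):
            pi_hat = interim_original(s1, design.n1)
            n2 = design.n2_schedule[s1]
            var = pi_hat * (1 - pi_hat)
            assert var / (design.n1 + n2) <= 0.1**2 + 1e-12
            if n2 > 0:
                assert var / (design.n1 + n2 - 1) > 0.1**2 - 1e-12

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            GehanDesign(n1=3, n2_schedule=(1, 0, 0, 0))  # n2(0) must be 0
        with pytest.raises(ValueError):
            GehanDesign(n1=3, n2_schedule=(0, 0))  # wrong length

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DesignParams(pi0=0.3, pi1=0.15, alpha=0.05, beta1=0.1, gamma=0.1)
        with pytest.raises(ValueError):
            dupuis_params(method="bogus")
        with pytest.raises(ValueError):
            dupuis_params(rule="f_X")
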