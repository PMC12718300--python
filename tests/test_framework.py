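"""Unit and property tests for the decomposition math."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import airdisparity as ad
from airdisparity.errors import DomainError, ShapeError, ValidationError


def make_record(emissions, pwm_group, pwm_total, group="alpha"):
    """Build a decomposition record directly from its defining PWMs."""
    return ad.DisparityDecomposition(
        group_label=group,
        emissions=emissions,
        exposure_factor=pwm_total / emissions,
        relative_disparity=(pwm_group - pwm_total) / pwm_total,
        absolute_disparity=pwm_group - pwm_total,
        pwm_group=pwm_group,
        pwm_total=pwm_total,
    )


class TestPopulationWeightedMean:
    @pytest.mark.parametrize("conc, pop, expected", [
        (np.full((3, 3), 2.5), np.ones((3, 3)), 2.5),            # constant field
        (np.array([[1.0, 7.0], [3.0, 9.0]]),
         np.array([[0.0, 4.0], [0.0, 0.0]]), 7.0),               # single support
        (np.array([2.0, 6.0]), np.array([1.0, 3.0]), 5.0),       # hand evaluation
    ])
    def test_examples(self, conc, pop, expected):
        assert ad.population_weighted_mean(conc, pop) == pytest.approx(expected)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            ad.population_weighted_mean(np.ones((2, 2)), np.ones((3, 3)))

    def test_zero_population(self):
        with pytest.raises(DomainError):
            ad.population_weighted_mean(np.ones((2, 2)), np.zeros((2, 2)))

    def test_negative_population(self):
        with pytest.raises(ValidationError):
            ad.population_weighted_mean(np.ones(2), np.array([1.0, -1.0]))

    def test_bounded_by_populated_extremes(self, rng):
        conc = rng.uniform(0, 5, (6, 6))
        pop = rng.uniform(0, 2, (6, 6))
        pop[pop < 0.5] = 0.0
        pop[0, 0] = 1.0  # ensure support
        pwm = ad.population_weighted_mean(conc, pop)
        populated = conc[pop > 0]
        assert populated.min() <= pwm <= populated.max()


class TestScalarComponents:
    @pytest.mark.parametrize("pg, pt, expected", [
        (5.0, 4.0, 1.0), (4.0, 4.0, 0.0), (3.0, 4.0, -1.0)])
    def test_absolute(self, pg, pt, expected):
        assert ad.absolute_disparity(pg, pt) == expected

    @pytest.mark.parametrize("pg, pt, expected", [
        (5.0, 4.0, 0.25), (4.0, 4.0, 0.0)])
    def test_relative(self, pg, pt, expected):
        assert ad.relative_disparity(pg, pt) == pytest.approx(expected)

    def test_relative_undefined_at_zero_exposure(self):
        with pytest.raises(DomainError):
            ad.relative_disparity(4.0, 0.0)

    @pytest.mark.parametrize("pt, e, expected", [
        (1.0e-4, 10.0, 1.0e-5), (0.0, 5.0, 0.0)])
    def test_exposure_factor(self, pt, e, expected):
        assert ad.exposure_factor(pt, e) == pytest.approx(expected)

    def test_exposure_factor_undefined_for_zero_emissions(self):
        with pytest.raises(DomainError):
            ad.exposure_factor(1.0, 0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            ad.absolute_disparity(np.nan, 1.0)


class TestDecompose:
    def test_identity_on_random_field(self, rng):
        conc = rng.uniform(0, 3, (8, 8))
        pop_a = rng.uniform(0, 5, (8, 8))
        pop_t = pop_a + rng.uniform(0, 5, (8, 8))
        rec = ad.decompose(conc, pop_a, pop_t, emissions=7.0)
        product = rec.emissions * rec.exposure_factor * rec.relative_disparity
        assert product == pytest.approx(rec.absolute_disparity, rel=1e-12)
        assert rec.absolute_disparity == rec.pwm_group - rec.pwm_total

    def test_uniform_field_has_no_disparity(self):
        conc = np.full((4, 4), 2.0)
        pop_a = np.arange(16, dtype=float).reshape(4, 4)
        pop_t = pop_a + 1.0
        rec = ad.decompose(conc, pop_a, pop_t, emissions=3.0)
        assert rec.relative_disparity == pytest.approx(0.0, abs=1e-15)
        assert rec.absolute_disparity == pytest.approx(0.0, abs=1e-15)

    def test_joint_scaling_homogeneity(self, rng):
        """Scaling field and emissions together leaves XF and D_R fixed;
        scaling the field alone scales D_A linearly."""
        conc = rng.uniform(0.1, 3, (5, 5))
        pop_a = rng.uniform(0, 5, (5, 5))
        pop_t = pop_a + rng.uniform(0.1, 5, (5, 5))
        base = ad.decompose(conc, pop_a, pop_t, emissions=2.0)
        joint = ad.decompose(conc * 3.0, pop_a, pop_t, emissions=6.0)
        assert joint.exposure_factor == pytest.approx(base.exposure_factor,
                                                      rel=1e-12)
        assert joint.relative_disparity == pytest.approx(
            base.relative_disparity, rel=1e-12)
        scaled = ad.decompose(conc * 3.0, pop_a, pop_t, emissions=2.0)
        assert scaled.absolute_disparity == pytest.approx(
            3.0 * base.absolute_disparity, rel=1e-12)
        assert scaled.relative_disparity == pytest.approx(
            base.relative_disparity, rel=1e-12)

    def test_share_weighted_group_disparities_sum_to_zero(self, rng):
        """Over an exhaustive two-group partition, the population-share
        weighted group disparities cancel exactly."""
        conc = rng.uniform(0, 3, (6, 6))
        pop_a = rng.uniform(0, 5, (6, 6))
        pop_b = rng.uniform(0, 5, (6, 6))
        pop_t = pop_a + pop_b
        rec_a = ad.decompose(conc, pop_a, pop_t, emissions=1.0, group_label="a")
        rec_b = ad.decompose(conc, pop_b, pop_t, emissions=1.0, group_label="b")
        share_a = pop_a.sum() / pop_t.sum()
        total = share_a * rec_a.absolute_disparity \
            + (1 - share_a) * rec_b.absolute_disparity
        assert total == pytest.approx(0.0, abs=1e-15 * conc.max())


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=12),
       st.lists(st.floats(0.0, 50.0), min_size=12, max_size=12),
       st.floats(1e-3, 1e3))
def test_identity_property(conc_values, pop_values, emissions):
    """E x XF x D_R == D_A for arbitrary nonnegative fields with at
    least one populated, exposed cell."""
    m = len(conc_values)
    conc = np.asarray(conc_values)
    pop_a = np.asarray(pop_values[:m]) + 1e-6
    pop_t = pop_a + np.asarray(pop_values[:m][::-1])
    if ad.population_weighted_mean(conc, pop_t) == 0:
        conc = conc + 0.5
    rec = ad.decompose(conc, pop_a, pop_t, emissions)
    product = rec.emissions * rec.exposure_factor * rec.relative_disparity
    assert product == pytest.approx(rec.absolute_disparity, rel=1e-12,
                                    abs=1e-300)


class TestPercentChange:
    @pytest.mark.parametrize("start, end, expected", [
        (0.1, 0.12, 20.0), (0.7, 0.7, 0.0), (0.2, 0.1, -50.0)])
    def test_examples(self, start, end, expected):
        assert ad.percent_change(start, end) == pytest.approx(expected,
                                                              rel=1e-12)

    def test_zero_start(self):
        with pytest.raises(DomainError):
            ad.percent_change(0.0, 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-1e6, 1e6).filter(lambda v: abs(v) > 1e-9),
           st.floats(-1e6, 1e6))
    def test_sign_follows_value_not_magnitude(self, start, end):
        change = ad.percent_change(start, end)
        assert (change > 0) == ((end - start) / start > 0) or change == 0


class TestChangeDecomposition:
    def test_identity_policy_gives_zero_changes(self):
        rec = make_record(10.0, 5.0, 4.0)
        change = ad.change_decomposition(rec, rec)
        assert (change.frac_change_E, change.frac_change_XF,
                change.frac_change_DR, change.frac_change_DA) == (0, 0, 0, 0)

    def test_halving_emissions_halves_absolute_disparity(self):
        base = make_record(10.0, 5.0, 4.0)
        policy = make_record(5.0, 2.5, 2.0)  # same spatial pattern, half E
        change = ad.change_decomposition(base, policy)
        assert change.frac_change_E == pytest.approx(-0.5)
        assert change.frac_change_XF == pytest.approx(0.0, abs=1e-15)
        assert change.frac_change_DR == pytest.approx(0.0, abs=1e-15)
        assert change.frac_change_DA == pytest.approx(-0.5, rel=1e-12)

    def test_halving_emissions_and_relative_disparity(self):
        base = make_record(10.0, 5.0, 4.0)      # XF=0.4, DR=0.25
        policy = make_record(5.0, 2.25, 2.0)    # XF=0.4, DR=0.125
        change = ad.change_decomposition(base, policy)
        assert change.frac_change_DA == pytest.approx(-0.75, rel=1e-12)

    def test_group_mismatch(self):
        with pytest.raises(ValidationError):
            ad.change_decomposition(make_record(1, 2, 1, "alpha"),
                                    make_record(1, 2, 1, "beta"))

    def test_zero_baseline_component_named(self):
        base = make_record(10.0, 4.0, 4.0)  # D_R = 0
        with pytest.raises(DomainError, match="DR"):
            ad.change_decomposition(base, make_record(10.0, 5.0, 4.0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100), st.floats(0.1, 100),
           st.floats(0.1, 100), st.floats(0.1, 100),
           st.floats(0.01, 10), st.floats(0.01, 10))
    def test_multiplicative_consistency_and_round_trip(
            self, e_b, e_p, pt_b, pt_p, ratio_b, ratio_p):
        """(1+dE)(1+dXF)(1+dDR) == 1+dDA, and applying the fractional
        changes to the baseline reconstructs the policy components."""
        base = make_record(e_b, pt_b * (1 + ratio_b), pt_b)
        policy = make_record(e_p, pt_p * (1 + ratio_p), pt_p)
        ch = ad.change_decomposition(base, policy)
        lhs = (1 + ch.frac_change_E) * (1 + ch.frac_change_XF) \
            * (1 + ch.frac_change_DR)
        assert lhs == pytest.approx(1 + ch.frac_change_DA, rel=1e-10)
        assert base.emissions * (1 + ch.frac_change_E) == pytest.approx(
            policy.emissions, rel=1e-10)
        assert base.absolute_disparity * (1 + ch.frac_change_DA) == \
            pytest.approx(policy.absolute_disparity, rel=1e-10)
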