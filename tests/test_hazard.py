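"""Probability distributions, hazard transform, blurring, and segment shuffles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fpseq import hazard, paradigm
from fpseq.hazard import (
    HazardSeries,
    NATIVE_TIMES,
    Pmf,
    apply_segment_order,
    blur_hazard,
    conditional_pmf,
    empirical_pmf,
    hazard_from_pmf,
    interpolate_hazard,
    segment_shuffle,
)


def brute_force_hazard(mass: np.ndarray) -> np.ndarray:
    """Direct f(t) / (1 - C(t)) with exclusive cumulative, max-normalized."""
    c_excl = np.concatenate([[0.0], np.cumsum(mass)[:-1]])
    raw = mass / (1.0 - c_excl)
    return raw / raw.max()


class TestEmpiricalPmf:
    def test_single_trial_is_delta(self):
        import pandas as pd
        table = pd.DataFrame({
            "position": ["FP1"], "foreperiod_s": [0.8], "fp1_context_s": [np.nan],
        })
        pmf = empirical_pmf(table, "FP1")
        assert pmf.mass[np.isclose(pmf.times, 0.8)] == 1.0
        assert pmf.mass.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("block", [1, 2, 3, 4])
    def test_pooled_short_long_split_is_even(self, actual_session, block):
        pmf = empirical_pmf(actual_session[actual_session["block"] == block])
        assert pmf.short_mass == pytest.approx(0.5)
        assert pmf.long_mass == pytest.approx(0.5)

    def test_empty_selection_fails(self, actual_session):
        with pytest.raises(ValueError, match="position"):
            empirical_pmf(actual_session, "FP3")


class TestConditionalPmf:
    @pytest.mark.parametrize(
        "block,key,attr,expected",
        [
            (1, "L", "long_mass", 1.0),   # long FP2 always follows long FP1
            (2, "L", "short_mass", 1.0),  # Block 2 swaps categories
            (2, "S", "long_mass", 1.0),
            (3, "L", "long_mass", 0.8),   # 20-80 split after long FP1
            (4, "L", "short_mass", 0.8),  # 80-20 split after long FP1
        ],
    )
    def test_category_conditionals_match_design(self, actual_session, block, key, attr, expected):
        cps = conditional_pmf(actual_session[actual_session["block"] == block])
        assert getattr(cps.mapping[key], attr) == pytest.approx(expected)

    def test_absent_context_key_omitted(self, actual_session):
        block1 = actual_session[actual_session["block"] == 1]
        cps = conditional_pmf(block1, "per_duration")
        # 1.8 s never occurs as FP1 in actual mode, so it cannot be a key
        assert 1.8 not in cps.mapping
        for pmf in cps.mapping.values():
            assert pmf.mass.sum() == pytest.approx(1.0)


class TestHazardTransform:
    def test_uniform_four_point_hand_example(self):
        pmf = Pmf(np.array([0.4, 0.5, 0.6, 0.7]), np.full(4, 0.25))
        hz = hazard_from_pmf(pmf)
        np.testing.assert_allclose(hz.values, [0.25, 1 / 3, 0.5, 1.0], atol=1e-12)

    def test_delta_pmf(self):
        """A point mass hazards to 1 at its duration (0 before); once the
        survival probability hits zero the cap holds the running maximum."""
        mass = np.zeros(len(NATIVE_TIMES))
        mass[4] = 1.0
        hz = hazard_from_pmf(Pmf(NATIVE_TIMES, mass))
        expected = np.zeros(len(NATIVE_TIMES))
        expected[4:] = 1.0  # capped at max of preceding values beyond the delta
        np.testing.assert_allclose(hz.values, expected)

    def test_normalized_max_is_one(self, actual_session):
        hz = hazard_from_pmf(empirical_pmf(actual_session))
        assert hz.values.max() == pytest.approx(1.0)
        assert np.all((hz.values >= 0) & (hz.values <= 1))

    def test_all_zero_mass_fails(self):
        with pytest.raises(ValueError):
            Pmf(NATIVE_TIMES, np.zeros(len(NATIVE_TIMES)))

    def test_matches_brute_force_on_random_pmfs(self, rng):
        """Hazard transform equals direct f/(1-C) evaluation on 1,000 pmfs."""
        for _ in range(1000):
            mass = rng.dirichlet(np.ones(len(NATIVE_TIMES)) * rng.uniform(0.2, 3.0))
            if mass.min() < 1e-6:  # survival must stay above the cap threshold
                continue
            hz = hazard_from_pmf(Pmf(NATIVE_TIMES, mass))
            np.testing.assert_allclose(hz.values, brute_force_hazard(mass), atol=1e-10)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_full_support_final_raw_hazard_is_one(self, seed):
        """With full support the exclusive cumulative makes the last raw hazard 1."""
        mass = np.random.default_rng(seed).dirichlet(np.ones(len(NATIVE_TIMES)))
        if mass.min() <= 1e-12:
            return
        hz = hazard_from_pmf(Pmf(NATIVE_TIMES, mass))
        assert hz.values[-1] == pytest.approx(1.0)  # also the normalizing max


class TestInterpolation:
    def test_knots_reproduced_and_clipped(self, study_hazards):
        hz_u, _ = study_hazards
        fine = interpolate_hazard(hz_u, 250)
        assert fine.rate_hz == 250
        assert len(fine.values) == 401
        knot_idx = np.round((hz_u.times - 0.4) * 250).astype(int)
        np.testing.assert_allclose(fine.values[knot_idx], hz_u.values, atol=1e-12)
        assert fine.values.min() >= 0 and fine.values.max() <= 1

    def test_constant_series_stays_constant(self):
        hz = HazardSeries(NATIVE_TIMES, np.full(len(NATIVE_TIMES), 0.5), 10)
        fine = interpolate_hazard(hz)
        np.testing.assert_allclose(fine.values, 0.5, atol=1e-9)

    def test_matches_direct_spline_evaluation(self, study_hazards):
        from scipy.interpolate import CubicSpline
        hz_u, _ = study_hazards
        fine = interpolate_hazard(hz_u, 250)
        direct = np.clip(CubicSpline(hz_u.times, hz_u.values)(fine.times), 0, 1)
        np.testing.assert_allclose(fine.values, direct, atol=1e-9)

    def test_non_refining_rate_fails(self, study_hazards):
        hz_u, _ = study_hazards
        with pytest.raises(ValueError, match="multiple"):
            interpolate_hazard(hz_u, 37)


class TestBlur:
    def test_vanishing_phi_recovers_unblurred(self, study_hazards):
        hz_u, _ = study_hazards
        blurred = blur_hazard(hz_u, "temporal", phi=1e-4)
        assert np.max(np.abs(blurred.values - hz_u.values)) < 1e-6

    def test_probabilistic_blur_spreads_delta(self):
        mass = np.zeros(len(NATIVE_TIMES))
        mass[8] = 1.0  # delta at 1.2 s
        pmf = Pmf(NATIVE_TIMES, mass)
        hz = blur_hazard(pmf, "probabilistic", phi=0.25)
        # the blurred pmf is unimodal around the delta and keeps its mass
        d = np.abs(NATIVE_TIMES - 1.2)
        assert hz.values[np.argmin(d)] > 0
        assert (hz.values > 0).sum() > 1

    def test_probabilistic_blur_matches_kernel_sum_oracle(self):
        mass = np.zeros(len(NATIVE_TIMES))
        mass[8] = 1.0
        phi = 0.25
        # direct kernel-sum: one source point at t0 = 1.2 with SD phi * t0
        t0, sd = 1.2, 0.25 * 1.2
        k = np.exp(-0.5 * ((NATIVE_TIMES - t0) / sd) ** 2)
        k[np.abs(NATIVE_TIMES - t0) > 4 * sd] = 0
        expected_pmf = k / k.sum()
        hz = blur_hazard(Pmf(NATIVE_TIMES, mass), "probabilistic", phi=phi)
        oracle = hazard_from_pmf(Pmf(NATIVE_TIMES, expected_pmf))
        np.testing.assert_allclose(hz.values, oracle.values, atol=1e-10)

    def test_temporal_blur_preserves_peak_ordering(self):
        values = np.zeros(len(NATIVE_TIMES))
        values[2] = 1.0   # early, taller peak
        values[13] = 0.6  # late, smaller peak
        hz = HazardSeries(NATIVE_TIMES, values, 10)
        blurred = blur_hazard(hz, "temporal", phi=0.15)
        assert blurred.values[2] > blurred.values[13]

    def test_nonpositive_phi_fails(self, study_hazards):
        with pytest.raises(ValueError, match="phi"):
            blur_hazard(study_hazards[0], "temporal", 0.0)


class TestSegmentShuffle:
    def test_printed_order_example(self):
        """250 values with order 2-1-3-5-4 moves the 51st-100th block first."""
        values = np.arange(250)
        out = apply_segment_order(values, (2, 1, 3, 5, 4))
        expected = np.concatenate([
            values[50:100], values[0:50], values[100:150],
            values[200:250], values[150:200],
        ])
        np.testing.assert_array_equal(out, expected)

    def test_multiset_preserved_and_non_identity(self, study_hazards):
        hz_u, _ = study_hazards
        fine = interpolate_hazard(hz_u, 250)
        shuffled = segment_shuffle(fine, 5, seed=2)
        assert sorted(shuffled.values) == pytest.approx(sorted(fine.values))
        assert not np.array_equal(shuffled.values, fine.values)
        assert tuple(shuffled.provenance["shuffled_order"]) != (1, 2, 3, 4, 5)

    def test_constant_series_unchanged(self):
        hz = HazardSeries(np.arange(250) / 250, np.full(250, 0.3), 250)
        shuffled = segment_shuffle(hz, 5, seed=0)
        np.testing.assert_array_equal(shuffled.values, hz.values)

    def test_too_short_series_fails(self):
        hz = HazardSeries(np.arange(3) / 10, np.array([0.1, 0.2, 0.3]), 10)
        with pytest.raises(ValueError, match="segments"):
            segment_shuffle(hz, 5, seed=0)


def test_hazard_round_trip(tmp_path, study_hazards):
    hz_u, _ = study_hazards
    path = tmp_path / "hf_u.tsv"
    hazard.write_hazard(hz_u, path)
    back = hazard.read_hazard(path)
    np.testing.assert_allclose(back.values, hz_u.values, atol=1e-12)
    assert back.rate_hz == hz_u.rate_hz
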