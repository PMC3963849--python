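"""Unit and property tests for the switched stage-structured dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import firetree as ft
from firetree.model_core import (
    ConfigurationError,
    FireProbabilityModel,
    Recruitment,
    SimplexError,
    StagePair,
    UnstableDynamicsError,
    effective_cover,
    fire_probability,
    step,
)

UNIT = FireProbabilityModel(theta1=0.2, theta2=0.8, p_max=1.0, p_min=0.0)


class TestFireProbability:
    @pytest.mark.parametrize(
        "C, expected",
        [
            (0.2, 1.0),  # boundary of the flat high-fire region
            (0.5, 0.5),  # midpoint of the linear branch
            (0.9, 0.0),  # above the upper threshold
            (0.0, 1.0),
            (0.8, 0.0),
        ],
    )
    def test_piecewise_linear_values(self, C, expected):
        assert fire_probability(C, UNIT) == pytest.approx(expected, abs=1e-12)

    def test_step_function_when_thresholds_coincide(self):
        model = FireProbabilityModel(theta1=0.5, theta2=0.5, p_max=0.9, p_min=0.1)
        assert fire_probability(0.5, model) == 0.9
        assert fire_probability(0.5 + 1e-12, model) == 0.1

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        th=st.tuples(
            st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
        ),
        ps=st.tuples(
            st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
        ),
        covers=st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=8),
    )
    def test_monotone_feedback(self, th, ps, covers):
        """p(C) is non-increasing in C and bounded by [p_min, p_max]."""
        model = FireProbabilityModel(
            theta1=min(th), theta2=max(th), p_max=max(ps), p_min=min(ps)
        )
        vals = [fire_probability(c, model) for c in sorted(covers)]
        assert all(model.p_min <= v <= model.p_max for v in vals)
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            FireProbabilityModel(theta1=0.8, theta2=0.2)
        with pytest.raises(ConfigurationError):
            FireProbabilityModel(theta1=0.2, theta2=0.8, p_max=0.1, p_min=0.9)


class TestEffectiveCover:
    @pytest.mark.parametrize(
        "x, mask, expected",
        [
            ([0.1, 0.2, 0.3], (2, 3), 0.5),  # canopy classes only
            ([0.4], (1,), 0.4),
            ([0.0, 0.0, 0.0], (2, 3), 0.0),
            ([0.1, 0.2, 0.3], None, 0.6),
        ],
    )
    def test_mask_sums(self, x, mask, expected):
        model = FireProbabilityModel(theta1=0.2, theta2=0.8, cover_mask=mask)
        assert effective_cover(x, model) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_mask(self):
        model = FireProbabilityModel(theta1=0.2, theta2=0.8, cover_mask=(2, 3))
        with pytest.raises(ConfigurationError):
            effective_cover([0.5], model)


class TestStep:
    def test_survival_then_space_limited_recruitment(self):
        config = ft.scalar_config(0.9, 0.4, 0.1, 0.2, 0.8)
        # 0.9*0.5 = 0.45 surviving, then 0.1 * (1 - 0.45) recruited
        assert step([0.5], False, config)[0] == pytest.approx(0.505, abs=1e-14)

    def test_total_kill_without_recruitment(self):
        config = ft.scalar_config(0.9, 0.0, 0.0, 0.2, 0.8)
        assert step([0.5], True, config)[0] == 0.0

    def test_recruitment_fills_smallest_class_only(self):
        config = ft.three_class_reference_config()
        config = ft.ModelConfig(
            stages=config.stages,
            recruitment=Recruitment(a=0.2),
            fire=config.fire,
        )
        out = step([0.0, 0.0, 0.0], False, config)
        assert np.allclose(out, [0.2, 0.0, 0.0], atol=1e-14)

    def test_constant_recruitment_can_overflow(self):
        config = ft.scalar_config(1.0, 1.0, 0.3, 0.2, 0.8, space_limited=False)
        with pytest.raises(SimplexError):
            step([0.9], False, config)

    def test_invalid_column_sum_rejected_at_construction(self):
        with pytest.raises(ConfigurationError, match="column"):
            StagePair(A_nf=[[0.6, 0.0], [0.6, 0.5]], A_f=[[0.1, 0.0], [0.0, 0.1]])


class TestSteadyState:
    @pytest.mark.parametrize(
        "alpha, a, which, expected",
        [
            (0.9, 0.1, "no_fire", 0.1 / 0.19),  # a / (1 - (1-a) alpha)
            (0.4, 0.1, "fire", 0.1 / (1 - 0.9 * 0.4)),
            (0.0, 0.1, "fire", 0.1),  # memoryless map lands on recruitment
        ],
    )
    def test_scalar_closed_form(self, alpha, a, which, expected):
        config = ft.scalar_config(
            alpha if which == "no_fire" else 0.9,
            alpha if which == "fire" else 0.0,
            a,
            0.2,
            0.8,
        )
        assert ft.steady_state(config, which)[0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n", [1, 3])
    @pytest.mark.parametrize("which", ["no_fire", "fire"])
    def test_fixed_point_property(self, n, which, rng):
        """step(x*, which) = x* to 1e-12 for random stable configurations."""
        for _ in range(10):
            config = ft.random_valid_config(rng, n=n, max_col_sum=0.9)
            x_star = ft.steady_state(config, which)
            out = step(x_star, which == "fire", config)
            assert np.abs(out - x_star).sum() < 1e-12

    def test_unstable_dynamic_raises(self):
        config = ft.scalar_config(1.0, 0.5, 0.0, 0.2, 0.8)
        with pytest.raises(UnstableDynamicsError):
            ft.steady_state(config, "no_fire")

    def test_disturbed_cover_below_undisturbed(self, reference_config):
        ss = ft.steady_states(reference_config)
        assert ss.x_star_f.sum() < ss.x_star_nf.sum()
        assert ss.p_at_f >= ss.p_at_nf


class TestStability:
    def test_scalar_effective_norm(self):
        report = ft.stability_check(ft.scalar_config(0.9, 0.4, 0.1, 0.2, 0.8))
        assert report.stable_nf and report.stable_f
        assert report.one_norm_nf == pytest.approx(0.81, abs=1e-12)

    def test_identity_map_not_contractive(self):
        report = ft.stability_check(ft.scalar_config(1.0, 1.0, 0.0, 0.2, 0.8))
        assert not report.stable_nf and not report.stable_f

    def test_full_column_sums_stabilised_by_recruitment(self):
        # column sums 1.0 but recruitment scales the effective map by (1-a)
        pair = StagePair(
            A_nf=[[0.5, 0.3], [0.5, 0.7]], A_f=[[0.5, 0.3], [0.5, 0.7]]
        )
        config = ft.ModelConfig(
            stages=pair, recruitment=Recruitment(a=0.2), fire=UNIT
        )
        report = ft.stability_check(config)
        assert report.stable_nf
        assert report.one_norm_nf == pytest.approx(0.8, abs=1e-12)

    def test_scaled_max_norm_bounds_one_norm(self, rng):
        for _ in range(20):
            config = ft.random_valid_config(rng, n=3)
            r = ft.stability_check(config)
            assert r.scaled_max_norm_nf >= r.one_norm_nf - 1e-12
            assert r.scaled_max_norm_f >= r.one_norm_f - 1e-12


class TestInvertFireThresholds:
    def _config_with_covers(self):
        # steady covers 0.8 (no fire) and 0.2 (fire) with a = 0.2
        return ft.scalar_config(0.9375, 0.0, 0.2, 0.2, 0.8)

    def test_hand_solved_example(self):
        config = self._config_with_covers()
        ss = ft.steady_states(config)
        assert ss.x_star_nf[0] == pytest.approx(0.8, abs=1e-12)
        assert ss.x_star_f[0] == pytest.approx(0.2, abs=1e-12)
        th1, th2 = ft.invert_fire_thresholds(0.1, 0.9, config)
        assert th1 == pytest.approx(0.125, abs=1e-12)
        assert th2 == pytest.approx(0.875, abs=1e-12)

    def test_round_trip_consistency(self):
        config = self._config_with_covers()
        th1, th2 = ft.invert_fire_thresholds(0.1, 0.9, config)
        model = FireProbabilityModel(theta1=th1, theta2=th2)
        assert fire_probability(0.8, model) == pytest.approx(0.1, abs=1e-12)
        assert fire_probability(0.2, model) == pytest.approx(0.9, abs=1e-12)

    def test_degenerate_slope_rejected(self):
        with pytest.raises(ConfigurationError):
            ft.invert_fire_thresholds(0.5, 0.5, self._config_with_covers())

    def test_infeasible_targets_rejected(self):
        # tiny gap between targets pushes the thresholds far outside [0, 1]
        with pytest.raises(ConfigurationError):
            ft.invert_fire_thresholds(0.49, 0.51, self._config_with_covers())


class TestSimulate:
    def test_forced_no_fire_converges_to_steady_state(self, reference_config):
        r = ft.simulate(reference_config, [0.0], 2000, forced_fire=False)
        assert abs(r.states[-1, 0] - 0.1 / 0.19) < 1e-8

    def test_degenerate_bernoulli_gives_no_fires(self):
        config = ft.scalar_config(0.9, 0.4, 0.1, 0.2, 0.8, p_max=0.0, p_min=0.0)
        r = ft.simulate(config, [0.3], 500)
        assert not r.fires.any()

    @pytest.mark.parametrize("n", [1, 3])
    def test_determinism_given_seed(self, n, rng):
        config = ft.random_valid_config(rng, n=n).with_seed(42)
        r1 = ft.simulate(config, np.zeros(n), 500)
        r2 = ft.simulate(config, np.zeros(n), 500)
        assert np.array_equal(r1.states, r2.states)
        assert np.array_equal(r1.fires, r2.fires)

    def test_convergence_is_geometric_under_forced_dynamic(self, reference_config):
        r = ft.simulate(reference_config, [0.0], 200, forced_fire=False)
        errs = np.abs(r.states[:, 0] - 0.1 / 0.19)
        # contraction factor 0.81 per year
        assert np.all(errs[1:] <= 0.81 * errs[:-1] + 1e-15)

    def test_invalid_horizon(self, reference_config):
        with pytest.raises(ConfigurationError):
            ft.simulate(reference_config, [0.0], 0)

    def test_simplex_invariance_along_trajectories(self, rng):
        """Random valid configs never push the state off the cover simplex."""
        for _ in range(20):
            n = int(rng.integers(1, 4))
            config = ft.random_valid_config(rng, n=n)
            r = ft.simulate(config, np.zeros(n), 500, rng=rng)
            assert r.states.min() >= -1e-12
            assert r.total_cover.max() <= 1 + 1e-12
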