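import numpy as np
import pytest

from corticowalk import sim
from corticowalk.sim import (
    CellState,
    ModelParams,
    PopulationSpec,
    ResistanceField,
    VelocityProfile,
    classify_profile,
    effective_parameters,
    sample_generated_force,
    simulate,
    step_cell,
    velocity_profile,
)


def uniform_field(height=200.0, r=1.0):
    return ResistanceField(height=height, boundaries=(), magnitudes=(r,))


class TestModelParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelParams(rho=1.2, alpha=1.0)
        with pytest.raises(ValueError):
            ModelParams(rho=0.5, alpha=-1.0)
        with pytest.raises(ValueError):
            ModelParams(rho=0.5, alpha=1.0, k_spring=1.5)
        with pytest.raises(ValueError):
            ModelParams(rho=0.5, alpha=1.0, dt=0.0)

    def test_field_invariants(self):
        with pytest.raises(ValueError):
            ResistanceField(height=100, boundaries=(0.5, 0.4), magnitudes=(1, 2, 3))
        with pytest.raises(ValueError):
            ResistanceField(height=100, boundaries=(0.5,), magnitudes=(1, -2))
        ctrl = sim.control_field()
        assert len(ctrl.magnitudes) == 3
        r1, r2, r3 = ctrl.magnitudes
        assert r2 > r1 and r2 > r3
        assert max(r1, r3) / min(r1, r3) < 2.0  # R1 ~ R3
        ko = sim.ko_field()
        assert len(ko.magnitudes) == 1
        assert ko.magnitudes[0] == pytest.approx(r1, rel=0.5)


class TestSampleGeneratedForce:
    def test_fully_biased_radial(self):
        p = ModelParams(rho=1.0, alpha=1.0, step_force_jitter=0.0, theta_max=0.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            f = sample_generated_force(p, rng)
            np.testing.assert_allclose(f, [0.0, 1.0], atol=1e-12)

    def test_forced_sign_and_scale(self):
        p = ModelParams(rho=0.0, alpha=2.0, step_force_jitter=0.0, theta_max=0.0)
        rng = np.random.default_rng(0)
        f = sample_generated_force(p, rng, size=50)
        np.testing.assert_allclose(f[:, 1], -2.0, atol=1e-12)
        np.testing.assert_allclose(f[:, 0], 0.0, atol=1e-12)

    @pytest.mark.parametrize("rho", [0.5, 0.51, 0.65, 1.0])
    def test_bias_realization_binomial_ci(self, rho):
        p = ModelParams(rho=rho, alpha=1.0)
        rng = np.random.default_rng(42)
        f = sample_generated_force(p, rng, size=100_000)
        frac_up = float((f[:, 1] > 0).mean())
        sigma = np.sqrt(rho * (1 - rho) / 100_000)
        assert abs(frac_up - rho) <= max(3 * sigma, 1e-12)

    def test_magnitude_jitter_bounds(self):
        p = ModelParams(rho=0.5, alpha=2.0, step_force_jitter=0.1)
        rng = np.random.default_rng(1)
        f = sample_generated_force(p, rng, size=10_000)
        mags = np.hypot(f[:, 0], f[:, 1])
        assert mags.min() >= 2.0 * 0.9 - 1e-9
        assert mags.max() <= 2.0 * 1.1 + 1e-9


def spring_oracle(force, threshold, k_spring, n_max=10_000):
    """Scalar accumulation oracle: steps until a constant aligned force moves."""
    spring = 0.0
    for step in range(1, n_max + 1):
        total = force + spring
        if total > threshold:
            return step
        spring = k_spring * total
    return None


class TestStepCell:
    field = uniform_field(r=1.0)

    def _params(self, **kw):
        base = dict(
            rho=1.0, alpha=0.5, k_spring=1.0, step_force_jitter=0.0, theta_max=0.0
        )
        base.update(kw)
        return ModelParams(**base)

    def test_below_threshold_stall(self):
        p = self._params(alpha=0.5, k_spring=0.3)
        state = CellState(position=[0.0, 50.0])
        rng = np.random.default_rng(0)
        out = step_cell(state, p, self.field, rng)
        np.testing.assert_allclose(out.position, state.position)
        np.testing.assert_allclose(out.spring_force, [0.0, 0.3 * 0.5])

    @pytest.mark.parametrize("force", [0.3, 0.45, 0.26, 0.7])
    def test_first_move_matches_oracle(self, force):
        p = self._params(alpha=force, k_spring=1.0)
        state = CellState(position=[0.0, 50.0])
        rng = np.random.default_rng(0)
        expected = spring_oracle(force, 1.0, 1.0)
        for step in range(1, expected + 1):
            prev_y = state.position[1]
            state = step_cell(state, p, self.field, rng)
            moved = state.position[1] != prev_y
            assert moved == (step == expected)
        np.testing.assert_allclose(state.spring_force, 0.0)

    def test_spring_zero_after_move(self):
        p = self._params(alpha=5.0)
        state = CellState(position=[0.0, 50.0])
        out = step_cell(state, p, self.field, np.random.default_rng(0))
        assert out.position[1] > 50.0
        np.testing.assert_allclose(out.spring_force, 0.0)

    def test_monotone_rise_until_reflection(self):
        p = self._params(alpha=3.0)
        field = uniform_field(height=200.0, r=0.5)
        state = CellState(position=[0.0, 10.0])
        rng = np.random.default_rng(0)
        ys = [state.position[1]]
        for _ in range(3):
            state = step_cell(state, p, field, rng)
            ys.append(state.position[1])
        assert all(b > a for a, b in zip(ys, ys[1:]))

    def test_outside_field_signalled(self):
        state = CellState(position=[0.0, 500.0])
        with pytest.raises(ValueError):
            step_cell(state, self._params(), self.field, np.random.default_rng(0))

    def test_reflection_keeps_cell_inside(self):
        p = self._params(alpha=50.0)
        field = uniform_field(height=30.0, r=0.1)
        state = CellState(position=[0.0, 25.0])
        rng = np.random.default_rng(0)
        for _ in range(50):
            state = step_cell(state, p, field, rng)
            assert 0.0 <= state.position[1] <= 30.0


class TestEffectiveParameters:
    ctrl = ModelParams(rho=0.65, alpha=2.0, k_spring=0.65)
    ko = ModelParams(rho=0.51, alpha=0.5, k_spring=0.6)

    def test_beta_one_is_control(self):
        eff = effective_parameters(1.0, self.ctrl, self.ko)
        assert eff.rho == self.ctrl.rho and eff.alpha == self.ctrl.alpha

    def test_beta_zero_is_ko(self):
        eff = effective_parameters(0.0, self.ctrl, self.ko)
        assert eff.rho == self.ko.rho and eff.alpha == self.ko.alpha

    def test_linear_midpoint(self):
        c = ModelParams(rho=0.65, alpha=1.0)
        k = ModelParams(rho=0.51, alpha=1.0)
        eff = effective_parameters(0.5, c, k)
        assert eff.rho == pytest.approx(0.58)

    def test_other_fields_from_ko(self):
        eff = effective_parameters(0.5, self.ctrl, self.ko)
        assert eff.k_spring == self.ko.k_spring

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            effective_parameters(1.5, self.ctrl, self.ko)


class TestSimulate:
    def test_determinism(self, small_control_spec):
        r1 = simulate(small_control_spec, 50, seed=7)
        r2 = simulate(small_control_spec, 50, seed=7)
        np.testing.assert_array_equal(r1.positions, r2.positions)

    def test_rejects_bad_steps(self, small_control_spec):
        with pytest.raises(ValueError):
            simulate(small_control_spec, 0, seed=1)

    def test_times_strictly_increasing(self, small_control_spec):
        res = simulate(small_control_spec, 20, seed=3)
        assert np.all(np.diff(res.times) == small_control_spec.params_control.dt)

    def test_initial_positions_in_lowest_compartment(self, small_control_spec):
        res = simulate(small_control_spec, 5, seed=4)
        y0 = res.positions[0, :, 1]
        assert np.all(y0 <= 0.45 * 200.0)

    def test_monotone_alpha_vs_net_displacement(self):
        # tall uniform field keeps the population off the reflecting pia,
        # where net displacement would saturate
        field = uniform_field(height=5000.0, r=1.0)
        means = []
        for alpha in (1.2, 1.6, 2.0, 2.6):
            spec = PopulationSpec(
                n_control=40,
                n_mutant=0,
                params_control=sim.control_params(alpha=alpha),
                params_mutant_pure_ko=sim.ko_params(),
                field=field,
            )
            res = simulate(spec, 100, seed=11)
            net = res.positions[-1, :, 1] - res.positions[0, :, 1]
            means.append(net.mean())
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_coupling_limits(self):
        # n_mutant -> 0 surrogate: 1 mutant among many controls behaves like control
        base = dict(
            params_control=sim.control_params(),
            params_mutant_pure_ko=sim.ko_params(),
            field=sim.control_field(),
        )
        nearly_ctrl = PopulationSpec(n_control=999, n_mutant=1, **base)
        eff = effective_parameters(
            nearly_ctrl.beta, base["params_control"], base["params_mutant_pure_ko"]
        )
        assert eff.rho == pytest.approx(sim.control_params().rho, abs=1e-3)
        pure_ko = PopulationSpec(n_control=0, n_mutant=10, **base)
        res = simulate(pure_ko, 10, seed=0)
        assert (res.cell_class == "mutant").all()


class TestVelocityProfile:
    def test_constant_speed_flat(self):
        t = np.arange(0, 101, dtype=float)
        track = np.column_stack([t, np.zeros_like(t), 2.0 * t])
        prof = velocity_profile([track], n_bins=10, field_height=200.0)
        visited = ~np.isnan(prof.values)
        np.testing.assert_allclose(prof.values[visited], 1.0)

    def test_two_regime(self):
        tracks = []
        t = np.arange(0, 50, dtype=float)
        tracks.append(np.column_stack([t, 0 * t, np.minimum(2.0 * t, 99.0)]))
        t2 = np.arange(0, 100, dtype=float)
        tracks.append(np.column_stack([t2, 0 * t2, 100.0 + np.minimum(1.0 * t2, 99.0)]))
        prof = velocity_profile(tracks, n_bins=10, field_height=200.0)
        lower = prof.values[:5]
        upper = prof.values[5:]
        np.testing.assert_allclose(lower[~np.isnan(lower)][:4], 1.0, atol=0.05)
        np.testing.assert_allclose(upper[~np.isnan(upper)][1:4], 0.5, atol=0.05)

    def test_no_movement_signalled(self):
        t = np.arange(0, 10, dtype=float)
        track = np.column_stack([t, np.zeros_like(t), np.full_like(t, 50.0)])
        with pytest.raises(ValueError):
            velocity_profile([track], n_bins=10, field_height=200.0)

    def test_empty_bins_are_nan_not_zero(self):
        t = np.arange(0, 10, dtype=float)
        track = np.column_stack([t, np.zeros_like(t), 5.0 + t])
        prof = velocity_profile([track], n_bins=10, field_height=200.0)
        assert np.isnan(prof.values[-1])


class TestClassifyProfile:
    bins = (np.arange(10) + 0.5) / 10

    def _profile(self, values):
        v = np.asarray(values, dtype=float)
        return VelocityProfile(self.bins, v, np.ones(10, dtype=int))

    def test_identity_is_mosaic(self):
        ref_c = self._profile([1, 1, 1, 1, 0.2, 0.2, 0.8, 0.8, 0.8, 0.8])
        ref_k = self._profile([1] * 10)
        label, _ = classify_profile(ref_c, ref_c, ref_k)
        assert label == "mosaic_like"

    def test_flat_is_ko(self):
        ref_c = self._profile([1, 1, 1, 1, 0.2, 0.2, 0.8, 0.8, 0.8, 0.8])
        ref_k = self._profile([1] * 10)
        flat = self._profile([1.0] * 10)
        label, _ = classify_profile(flat, ref_c, ref_k)
        assert label == "ko_like"

    def test_two_regime_contrast(self):
        prof = self._profile([1, 1, 1, 1, 1, 0.5, 0.5, 0.5, 0.5, 0.5])
        _, contrast = classify_profile(prof, prof, self._profile([1] * 10))
        assert contrast == pytest.approx(0.5)

    def test_bin_mismatch(self):
        p = self._profile([1] * 10)
        other = VelocityProfile((np.arange(5) + 0.5) / 5, np.ones(5), np.ones(5, int))
        with pytest.raises(ValueError):
            classify_profile(p, other, other)

    def test_tie_goes_to_ko(self):
        a = self._profile([1.0] * 10)
        label, _ = classify_profile(a, a, a)
        assert label == "ko_like"


class TestProfileSignatures:
    def test_control_field_band_dip(self):
        spec = PopulationSpec(
            n_control=60,
            n_mutant=0,
            params_control=sim.control_params(),
            params_mutant_pure_ko=sim.ko_params(),
            field=sim.control_field(),
        )
        hits = 0
        for seed in range(10):
            res = simulate(spec, 300, seed=seed)
            prof = velocity_profile(res.tracks(), n_bins=20, field_height=200.0)
            band = np.nanmean(prof.values[9:11])  # R2 band bins
            r1 = np.nanmean(prof.values[2:8])
            hits += band < r1
        assert hits >= 10 * 0.95

    def test_uniform_field_flat(self):
        spec = PopulationSpec(
            n_control=0,
            n_mutant=150,
            params_control=sim.control_params(),
            params_mutant_pure_ko=sim.ko_params(),
            field=sim.ko_field(),
            coupling="none",
        )
        res = simulate(spec, 400, seed=2)
        prof = velocity_profile(res.tracks(), n_bins=10, field_height=200.0)
        vals = prof.values[~np.isnan(prof.values)]
        assert len(vals) >= 8
        assert np.nanstd(vals) / np.nanmean(vals) < 0.25


class TestFindTransition:
    def _template(self, n=80):
        # fast-crossing control parameters keep these contract tests cheap;
        # the shipped calibration is exercised in the acceptance suite
        return PopulationSpec(
            n_control=n,
            n_mutant=0,
            params_control=sim.control_params(alpha=2.6, k_spring=0.6),
            params_mutant_pure_ko=sim.ko_params(),
            field=sim.control_field(),
        )

    def test_all_mutant_is_ko_like(self):
        res = sim.find_transition(
            self._template(), [0.5, 1.0], reps=3, seed=0, n_steps=300, n_cells=80
        )
        assert res.labels[0.5] == "ko_like"
        assert res.labels[1.0] == "ko_like"

    def test_tiny_fraction_is_mosaic_no_transition(self):
        res = sim.find_transition(
            self._template(), [0.01], reps=3, seed=0, n_steps=300, n_cells=100
        )
        assert res.labels[0.01] == "mosaic_like"
        assert not res.found

    def test_unsorted_fractions_rejected(self):
        with pytest.raises(ValueError):
            sim.find_transition(self._template(), [0.1, 0.05], reps=1, seed=0)
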