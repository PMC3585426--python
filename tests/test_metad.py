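"""Well-tempered metadynamics: hills, walls, offset, Langevin, convergence."""

import numpy as np
import pytest

from bundlecv.metad import (KB, BiasState, DoubleWell, Harmonic, Hill,
                            MetadError, WTMetadParams, WallSpec,
                            accumulate_hills_on_grid, bias_offset_c_of_t,
                            bias_value_and_force, free_energy_from_bias,
                            langevin_propagate, next_hill_height,
                            reweight_frames, run_well_tempered_metadynamics,
                            wall_energy)
from conftest import DW_EDGES, run_doublewell


def one_hill_state(height=0.25, center=0.0, width=0.2, **kw):
    params = WTMetadParams(widths=(width,), initial_height=height, **kw)
    state = BiasState(params)
    state.add_hill(Hill(2.0, [center], [width], height))
    return state


class TestBiasValueAndForce:
    def test_empty_state(self):
        state = BiasState(WTMetadParams())
        v, f = bias_value_and_force(state, [0.3])
        assert v == 0.0 and np.all(f == 0.0)

    def test_at_hill_center(self):
        state = one_hill_state()
        v, f = bias_value_and_force(state, [0.0])
        assert v == pytest.approx(0.25)
        assert np.allclose(f, 0.0, atol=1e-15)

    def test_one_sigma_closed_form_and_force(self):
        state = one_hill_state()
        v, f = bias_value_and_force(state, [0.2])
        assert v == pytest.approx(0.25 * np.exp(-0.5), rel=1e-12)
        eps = 1e-7
        fd = -(bias_value_and_force(state, [0.2 + eps])[0]
               - bias_value_and_force(state, [0.2 - eps])[0]) / (2 * eps)
        assert f[0] == pytest.approx(fd, abs=1e-8)

    def test_hill_ordering_enforced(self):
        state = one_hill_state()
        with pytest.raises(MetadError):
            state.add_hill(Hill(1.0, [0.1], [0.2], 0.2))


class TestHillHeight:
    def test_initial_height_at_zero_bias(self):
        state = BiasState(WTMetadParams(initial_height=0.25))
        assert next_hill_height(state, [0.0]) == pytest.approx(0.25)

    def test_halved_at_ln2_bias(self):
        params = WTMetadParams(initial_height=0.25, bias_factor=10.0)
        state = BiasState(params)
        target_v = KB * params.delta_t * np.log(2.0)
        # place one hill whose peak equals the target bias
        state.add_hill(Hill(2.0, [0.0], [0.2], target_v))
        assert next_hill_height(state, [0.0]) == pytest.approx(0.125)

    def test_monotone_decreasing_in_bias(self):
        params = WTMetadParams(initial_height=0.25)
        heights = []
        state = BiasState(params)
        for k in range(6):
            heights.append(next_hill_height(state, [0.0]))
            state.add_hill(Hill(2.0 * (k + 1), [0.0], [0.2], heights[-1]))
        assert np.all(np.diff(heights) < 0)
        assert heights[-1] > 0


class TestWalls:
    UP = WallSpec(0, 1.2, "upper", kappa=500.0, rescale=0.1, exponent=4)

    def test_zero_inside_exactly(self):
        assert wall_energy(self.UP, 1.0) == 0.0
        assert wall_energy(self.UP, 1.2) == 0.0
        low = WallSpec(0, -1.4, "lower", kappa=500.0, rescale=0.1)
        assert wall_energy(low, -1.0) == 0.0

    def test_kappa_at_one_rescale_unit(self):
        assert wall_energy(self.UP, 1.3) == pytest.approx(500.0)

    def test_sixteen_kappa_at_two_rescale_units(self):
        assert wall_energy(self.UP, 1.4) == pytest.approx(16 * 500.0)

    def test_c1_continuity_at_bound(self):
        eps = 1e-7
        slope = (self.UP.energy(1.2 + eps) - self.UP.energy(1.2 - eps)) / (2 * eps)
        assert slope == pytest.approx(0.0, abs=1e-6)

    def test_force_matches_finite_difference(self):
        s = 1.35
        eps = 1e-7
        fd = -(self.UP.energy(s + eps) - self.UP.energy(s - eps)) / (2 * eps)
        assert self.UP.force(s) == pytest.approx(fd, rel=1e-6)

    def test_invalid_specs_rejected(self):
        with pytest.raises(MetadError):
            WallSpec(0, 1.0, "sideways")
        with pytest.raises(MetadError):
            WallSpec(0, 1.0, "upper", exponent=3)


class TestFreeEnergyFromBias:
    def test_scaling_identity(self):
        # gamma = 10: F = -(10/9) V before the minimum shift
        params = WTMetadParams(bias_factor=10.0, widths=(0.2,))
        hills = [Hill(2.0, [0.0], [0.2], 0.9)]
        # 102 edges -> bin centers at -1.00, -0.98, ..., 0, ..., 1.00
        edges = [np.linspace(-1.01, 1.01, 102)]
        surf = free_energy_from_bias(hills, edges, params)
        v = accumulate_hills_on_grid(hills, edges)
        expect = -(10.0 / 9.0) * v
        expect -= expect.min()
        assert np.allclose(np.asarray(surf.values), expect)
        # an inverted scaled Gaussian: maximum depth 10/9 * height
        # (up to the far tail of the hill at the grid edge)
        assert float(surf.values.max()) == pytest.approx(0.9 * 10 / 9, rel=1e-4)

    def test_empty_hills_rejected(self):
        with pytest.raises(MetadError):
            free_energy_from_bias([], [np.linspace(-1, 1, 11)],
                                  WTMetadParams())


class TestBiasOffset:
    def test_zero_before_first_hill(self):
        state = BiasState(WTMetadParams())
        assert state.current_c() == 0.0

    def test_constant_bias_limit(self):
        # a hill much wider than the grid is constant over it: c -> V
        params = WTMetadParams(widths=(1e4,), initial_height=0.3)
        edges = [np.linspace(-1.0, 1.0, 51)]
        hills = [Hill(2.0, [0.0], [1e4], 0.3)]
        _, c = bias_offset_c_of_t(hills, edges, params)
        assert c[-1] == pytest.approx(0.3, abs=1e-6)

    def test_narrow_grid_warns(self):
        # a narrow hill sitting on the grid edge: the bias there exceeds the
        # grid minimum by much more than kT, so the grid is too narrow
        params = WTMetadParams(widths=(0.05,))
        edges = [np.linspace(-0.1, 0.1, 11)]
        state = BiasState(params, grid_edges=edges)
        with pytest.warns(UserWarning, match="grid"):
            state.add_hill(Hill(2.0, [0.1], [0.05], 5.0))


class TestLangevin:
    def test_zero_temperature_zero_force_is_static(self):
        class Flat:
            def energy(self, x):
                return 0.0

            def force(self, x):
                return np.zeros_like(np.atleast_1d(x))

        _, xs, _ = langevin_propagate(Flat(), None, [0.7], 0.01, 5.0, 0.0,
                                      1000, seed=1)
        assert np.allclose(xs, 0.7)

    def test_harmonic_equipartition(self):
        _, xs, _ = langevin_propagate(Harmonic(1.0), None, [0.0], 0.01, 5.0,
                                      298.0, 1_000_000, seed=1,
                                      record_stride=5)
        assert np.mean(xs ** 2) == pytest.approx(KB * 298.0, rel=0.03)

    def test_fixed_seed_bit_identical(self):
        a = langevin_propagate(Harmonic(2.0), None, [0.5], 0.01, 5.0, 298.0,
                               2000, seed=42)
        b = langevin_propagate(Harmonic(2.0), None, [0.5], 0.01, 5.0, 298.0,
                               2000, seed=42)
        assert np.array_equal(a[1], b[1])

    def test_stability_guard(self):
        with pytest.raises(MetadError):
            langevin_propagate(Harmonic(), None, [0.0], 0.1, 5.0, 298.0, 10)


class TestEngine:
    def test_hill_height_non_increasing_at_fixed_points(self, doublewell_runs):
        # at any fixed CV point the accumulated bias only grows, so the
        # well-tempered height that would be deposited there never increases
        run = doublewell_runs[0]
        probes = ([-1.0], [0.0], [1.0])
        state = BiasState(run.state.params)
        prev = {k: np.inf for k in range(len(probes))}
        for hill in run.state.hills:
            state.add_hill(hill)
            for k, s in enumerate(probes):
                h = next_hill_height(state, s)
                assert h <= prev[k] + 1e-15
                prev[k] = h

    def test_replay_of_emitted_hills_is_bit_identical(self, doublewell_runs):
        run = doublewell_runs[0]
        replay = accumulate_hills_on_grid(run.state.hills,
                                          run.state.grid_edges)
        assert np.array_equal(replay, run.state.grid_bias)

    def test_rms_error_decreases_with_run_length(self, doublewell_runs):
        pot = DoubleWell(5.0)

        def rms_err(run):
            surf = free_energy_from_bias(run.state)
            c = surf.centers[0]
            f = np.asarray(surf.values)
            ana = np.array([pot.energy([x]) for x in c])
            sel = ana - ana.min() < 10.0
            diff = (f - f[sel].mean()) - (ana - ana[sel].mean())
            return float(np.sqrt(np.mean(diff[sel] ** 2)))

        short = np.mean([rms_err(run_doublewell(100_000, seed))
                         for seed in range(5)])
        long = np.mean([rms_err(run) for run in doublewell_runs])
        assert long < short

    def test_2d_separable_doublewell_marginal(self):
        # biasing both axes of U(x,y) = 5(x^2-1)^2 + 5(y^2-1)^2: the
        # marginal free energy along each axis matches the 1D analytic well
        class Separable2D:
            a = 5.0

            def energy(self, x):
                x = np.atleast_1d(x)
                return float(np.sum(self.a * (x ** 2 - 1.0) ** 2))

            def force(self, x):
                x = np.atleast_1d(x)
                return -4.0 * self.a * x * (x ** 2 - 1.0)

        params = WTMetadParams(298.0, 10.0, 2.0, 0.25, (0.2, 0.2))
        walls = [WallSpec(c, b, s, 20.0, 0.3)
                 for c in (0, 1) for b, s in ((1.8, "upper"), (-1.8, "lower"))]
        run = run_well_tempered_metadynamics(
            Separable2D(), params, walls, [-1.0, -1.0], 1_200_000, 0.01, 5.0,
            seed=8, grid_edges=[np.linspace(-2.6, 2.6, 131)] * 2,
            colvar_stride=50)
        surf = free_energy_from_bias(run.state)
        kt = KB * 298.0
        f = np.asarray(surf.values)
        for axis in (0, 1):
            c = surf.centers[axis]
            marg = -kt * np.log(np.exp(-f / kt).sum(axis=1 - axis))
            ana = 5.0 * (c ** 2 - 1.0) ** 2
            sel = ana < 8.0
            diff = (marg - marg[sel].mean()) - (ana - ana[sel].mean())
            assert np.abs(diff[sel]).max() < 1.0

    def test_well_tempered_limit_gamma_to_one(self):
        # a deep well and a vanishing CV temperature: the total deposited
        # bias stays bounded and the walker never escapes the start basin
        # (the 40 kJ/mol barrier is ~16 kT, far beyond spontaneous crossing)
        pot = DoubleWell(40.0)
        params = WTMetadParams(bias_factor=1.001, widths=(0.2,),
                               initial_height=0.25)
        run = run_well_tempered_metadynamics(
            pot, params, [], [-1.0], 50_000, 0.01, 5.0, seed=4,
            grid_edges=DW_EDGES, colvar_stride=50)
        total = sum(h.height for h in run.state.hills)
        assert total < 1.0
        assert run.colvar_values[:, 0].max() < 0.0

    def test_cv_count_validated(self):
        with pytest.raises(MetadError):
            run_well_tempered_metadynamics(
                Harmonic(), WTMetadParams(widths=(0.2,) * 5), [],
                [0.0] * 5, 10, 0.01, 5.0)


class TestReweighting:
    def test_zero_bias_gives_equal_weights(self):
        state = BiasState(WTMetadParams())
        w = reweight_frames(state, np.arange(10.0), np.zeros(10))
        assert np.allclose(w, 1.0)

    def test_biased_harmonic_recovers_equipartition(self):
        pot = Harmonic(1.0)
        params = WTMetadParams(298.0, 10.0, 2.0, 0.25, (0.3,))
        walls = [WallSpec(0, 6.0, "upper", 50.0, 0.5),
                 WallSpec(0, -6.0, "lower", 50.0, 0.5)]
        run = run_well_tempered_metadynamics(
            pot, params, walls, [0.0], 600_000, 0.01, 5.0, seed=11,
            grid_edges=[np.linspace(-8.5, 8.5, 341)], colvar_stride=10)
        w = reweight_frames(run.state, run.colvar_times, run.colvar_values)
        x = run.colvar_values[:, 0]
        est = np.sum(w * x ** 2) / np.sum(w)
        assert est == pytest.approx(KB * 298.0, rel=0.05)

    def test_misaligned_series_rejected(self):
        state = BiasState(WTMetadParams())
        with pytest.raises(MetadError):
            reweight_frames(state, np.arange(5.0), np.zeros(7))
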