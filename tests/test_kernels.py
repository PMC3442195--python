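"""Closed-form kernel behavior: values, symmetries, wall condition, mass."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import dblquad

from ctcflow import (EvalPoint, FlowSpec, GridSpec, Normalization, Source,
                     eval_field_grid, eval_kernel_2d, eval_kernel_3d,
                     evaluate_field, greens_2d, greens_3d, superpose)


class TestKernelValues:
    def test_2d_value_at_source_center(self):
        # Direct exponent vanishes; image exponent is -(2 y0)^2/(4 alpha t).
        s = Source(x0=0, y0=2, strength=1, alpha=1)
        c = eval_kernel_2d(s, EvalPoint(x=0, y=2, t=1))
        assert c == pytest.approx((1 + math.exp(-4)) / (4 * math.pi), rel=1e-14)

    def test_2d_even_in_streamwise_offset(self):
        s = Source(x0=3.0, y0=2.0, strength=2.0, alpha=1.5)
        for d in (0.5, 1.7, 10.0):
            left = eval_kernel_2d(s, EvalPoint(x=3.0 - d, y=4.0, t=2.0))
            right = eval_kernel_2d(s, EvalPoint(x=3.0 + d, y=4.0, t=2.0))
            assert left == right

    def test_3d_reference_point(self):
        # s=1, u=1, alpha=1 gives r=1; exponents 0, 0, -(2H)^2/4 = -1.
        s = Source(x0=0, y0=0, z0=1, strength=1, alpha=1)
        c = eval_kernel_3d(s, FlowSpec.constant(1.0),
                           EvalPoint(x=1, y=0, z=1, t=1))
        assert c == pytest.approx((1 + math.exp(-1)) / (8 * math.pi), rel=1e-14)

    def test_3d_upstream_is_zero(self):
        s = Source(x0=0, y0=0, z0=1, strength=1, alpha=1)
        flow = FlowSpec.constant(1.0)
        assert eval_kernel_3d(s, flow, EvalPoint(x=-1, y=0, z=1, t=1)) == 0.0
        assert eval_kernel_3d(s, flow, EvalPoint(x=0, y=0, z=1, t=1)) == 0.0

    def test_3d_wall_value_doubles_single_term(self):
        # At z=0 the direct and image exponentials coincide.
        s = Source(x0=0, y0=0, z0=7.0, strength=1.3, alpha=1.5)
        flow = FlowSpec.constant(2.0)
        c_wall = eval_kernel_3d(s, flow, EvalPoint(x=5, y=1, z=0, t=3))
        r = s.alpha * 5.0 / flow.u
        single = (s.strength / (8 * math.pi * r ** 1.5)
                  * math.exp(-((5 - 2 * 3) ** 2 + 1) / (4 * r))
                  * math.exp(-(0 - 7.0) ** 2 / (4 * r)))
        assert c_wall == pytest.approx(2 * single, rel=1e-12)

    def test_textbook_puff_defined_upstream_and_positive(self):
        s = Source(x0=0, y0=0, z0=1, strength=1, alpha=1)
        flow = FlowSpec.constant(1.0)
        c = eval_kernel_3d(s, flow, EvalPoint(x=-1, y=0, z=1, t=1),
                           Normalization.TEXTBOOK_PUFF)
        assert c > 0


class TestDomainErrors:
    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            EvalPoint(x=0, y=0, t=0.0)
        with pytest.raises(ValueError):
            greens_2d(0.0, 1.0, -1.0, x0=0, y0=1)

    def test_negative_wall_coordinate_rejected(self):
        s = Source(x0=0, y0=1, z0=1)
        with pytest.raises(ValueError):
            eval_kernel_2d(s, EvalPoint(x=0, y=-0.5, t=1))
        with pytest.raises(ValueError):
            eval_kernel_3d(s, FlowSpec.constant(1.0),
                           EvalPoint(x=1, y=0, z=-0.5, t=1))

    def test_invalid_source_parameters(self):
        with pytest.raises(ValueError):
            Source(x0=0, y0=0, strength=0.0)
        with pytest.raises(ValueError):
            Source(x0=0, y0=0, alpha=-1.0)

    def test_flow_mode_contracts(self):
        with pytest.raises(ValueError):
            FlowSpec.constant(0.0)  # r = alpha*s/u undefined at u = 0
        with pytest.raises(ValueError):
            FlowSpec(mode=FlowSpec.no_flow().mode, u=1.0)


class TestWallNoFlux:
    """Centered differences across the wall vanish identically (image symmetry)."""

    @pytest.mark.parametrize("delta", [1e-2, 1e-4, 1e-6])
    def test_2d_wall_normal_derivative_zero(self, rng, delta):
        for _ in range(20):
            x0, y0 = rng.uniform(-5, 5), rng.uniform(0, 5)
            x, t = rng.uniform(-5, 5), rng.uniform(0.1, 10)
            hi = greens_2d(x, delta, t, x0=x0, y0=y0, alpha=1.5)
            lo = greens_2d(x, -delta, t, x0=x0, y0=y0, alpha=1.5)
            wall = greens_2d(x, 0.0, t, x0=x0, y0=y0, alpha=1.5)
            assert abs(hi - lo) / (2 * delta) <= 1e-10 * wall

    @pytest.mark.parametrize("delta", [1e-2, 1e-4, 1e-6])
    def test_3d_wall_normal_derivative_zero(self, rng, delta):
        for _ in range(20):
            h = rng.uniform(0, 5)
            x, y, t = rng.uniform(0.5, 10), rng.uniform(-5, 5), rng.uniform(0.5, 5)
            hi = greens_3d(x, y, delta, t, x0=0, y0=0, z0=h, u=1.0, alpha=1.5)
            lo = greens_3d(x, y, -delta, t, x0=0, y0=0, z0=h, u=1.0, alpha=1.5)
            wall = greens_3d(x, y, 0.0, t, x0=0, y0=0, z0=h, u=1.0, alpha=1.5)
            assert abs(hi - lo) / (2 * delta) <= 1e-10 * max(wall, 1e-300)


class TestMassAndLimits:
    def test_half_plane_mass_equals_strength(self):
        # The direct + image pair restores exactly the emitted amount.
        f = lambda y, x: greens_2d(x, y, 1.0, x0=1.0, y0=2.0, strength=1.7,
                                   alpha=1.5)
        mass, err = dblquad(f, -np.inf, np.inf, 0, np.inf,
                            epsabs=1e-10, epsrel=1e-10)
        assert mass == pytest.approx(1.7, rel=1e-7)

    def test_image_contribution_decays_with_release_height(self):
        # image/direct ratio is exp(-y*y0/(alpha*t)); field tends to the
        # free-space kernel as the source recedes from the wall.
        x, y, t, alpha = 0.0, 3.0, 2.0, 1.5
        for y0 in (1.0, 5.0, 20.0):
            direct = math.exp(-((y - y0) ** 2) / (4 * alpha * t))
            image = math.exp(-((y + y0) ** 2) / (4 * alpha * t))
            assert image / direct == pytest.approx(
                math.exp(-y * y0 / (alpha * t)), rel=1e-12)
        far = greens_2d(x, y, t, x0=0.0, y0=40.0, alpha=alpha)
        free = (1 / (4 * math.pi * alpha * t)
                * math.exp(-(x ** 2 + (y - 40.0) ** 2) / (4 * alpha * t)))
        assert far == pytest.approx(free, rel=1e-9)

    def test_positivity_and_far_field_decay(self, small_sources_2d, flow2d):
        xs = np.linspace(-50, 150, 40)
        ys = np.linspace(0, 100, 40)
        vals = evaluate_field(list(small_sources_2d), flow2d, xs[:, None],
                              ys[None, :], None, 3.0)
        assert np.all(vals > 0)
        near = superpose(list(small_sources_2d), flow2d, EvalPoint(50, 10, 3.0))
        far = superpose(list(small_sources_2d), flow2d,
                        EvalPoint(50, 1e4, 3.0))
        assert far < 1e-12 * near


class TestSuperposition:
    def test_empty_source_list_is_zero_field(self, flow2d):
        assert superpose([], flow2d, EvalPoint(1.0, 1.0, 1.0)) == 0.0

    def test_colocated_pair_equals_double_strength(self, flow2d):
        a = Source(x0=1, y0=2, strength=0.7)
        d = Source(x0=1, y0=2, strength=1.4)
        p = EvalPoint(3.0, 1.0, 2.0)
        assert superpose([a, a], flow2d, p) == pytest.approx(
            superpose([d], flow2d, p), rel=1e-15)

    def test_term_by_term_oracle(self, small_sources_3d, flow3d, rng):
        # Superposed value equals the plain sum of single-source evaluations.
        for _ in range(10):
            p = EvalPoint(x=rng.uniform(0, 200), y=rng.uniform(0, 100),
                          z=rng.uniform(0, 30), t=rng.uniform(0.5, 20))
            total = superpose(list(small_sources_3d), flow3d, p)
            oracle = sum(eval_kernel_3d(s, flow3d, p) for s in small_sources_3d)
            assert total == pytest.approx(oracle, rel=1e-13)

    @given(k=st.floats(min_value=0.25, max_value=8.0),
           x=st.floats(min_value=-20, max_value=20),
           y=st.floats(min_value=0, max_value=20),
           t=st.floats(min_value=0.1, max_value=50))
    @settings(derandomize=True, deadline=None, max_examples=25)
    def test_homogeneity_in_strength(self, k, x, y, t):
        base = [Source(x0=-1.0, y0=2.0, strength=1.0),
                Source(x0=4.0, y0=0.5, strength=3.0)]
        scaled = [Source(x0=s.x0, y0=s.y0, strength=k * s.strength)
                  for s in base]
        p = EvalPoint(x, y, t)
        flow = FlowSpec.no_flow()
        assert superpose(scaled, flow, p) == pytest.approx(
            k * superpose(base, flow, p), rel=1e-12)

    def test_additivity_over_source_sets(self, small_sources_2d, flow2d):
        a = list(small_sources_2d)[:4]
        b = list(small_sources_2d)[4:]
        p = EvalPoint(40.0, 5.0, 2.5)
        assert superpose(a + b, flow2d, p) == pytest.approx(
            superpose(a, flow2d, p) + superpose(b, flow2d, p), rel=1e-13)


class TestFieldGrid:
    def test_degenerate_grid_matches_pointwise(self, small_sources_2d, flow2d):
        grid = GridSpec(x=np.array([12.0]), y=np.array([3.0]))
        fg = eval_field_grid(list(small_sources_2d), flow2d, grid, 2.0)
        assert fg.values.shape == (1, 1)
        assert fg.values[0, 0] == superpose(list(small_sources_2d), flow2d,
                                            EvalPoint(12.0, 3.0, 2.0))

    def test_grid_bit_identical_to_loop(self, small_sources_2d, flow2d):
        grid = GridSpec(x=np.linspace(0, 50, 7), y=np.linspace(0, 20, 5))
        fg = eval_field_grid(list(small_sources_2d), flow2d, grid, 1.5)
        for i, x in enumerate(grid.x):
            for j, y in enumerate(grid.y):
                assert fg.values[i, j] == superpose(
                    list(small_sources_2d), flow2d, EvalPoint(x, y, 1.5))

    def test_wall_slice_doubles_imageless_field(self, small_sources_3d, flow3d):
        grid = GridSpec(x=np.linspace(10, 120, 12), y=np.linspace(0, 100, 12),
                        z=np.array([0.0]))
        fg = eval_field_grid(list(small_sources_3d), flow3d, grid, 5.0)
        X, Y, Z = np.meshgrid(grid.x, grid.y, grid.z, indexing="ij")
        no_image = np.zeros_like(X)
        for s in small_sources_3d:
            mask = X > s.x0
            r = s.alpha * np.where(mask, X - s.x0, 1.0) / flow3d.u
            term = (s.strength / (8 * np.pi * r ** 1.5)
                    * np.exp(-((X - s.x0 - flow3d.u * 5.0) ** 2
                               + (Y - s.y0) ** 2) / (4 * r))
                    * np.exp(-((Z - s.z0) ** 2) / (4 * r)))
            no_image += np.where(mask, term, 0.0)
        np.testing.assert_allclose(fg.values, 2 * no_image, rtol=1e-10)

    def test_grid_crossing_wall_rejected(self, small_sources_2d, flow2d):
        grid = GridSpec(x=np.linspace(0, 10, 4), y=np.linspace(-1, 5, 4))
        with pytest.raises(ValueError, match="wall"):
            eval_field_grid(list(small_sources_2d), flow2d, grid, 1.0)

    def test_four_ctc_slices_finite_nonnegative(self, flow3d):
        from ctcflow import four_ctc_sources

        sources = list(four_ctc_sources())
        for z in (0.0, 45.0, 90.0):
            grid = GridSpec(x=np.linspace(0, 600, 48),
                            y=np.linspace(0, 600, 48), z=np.array([z]))
            for t in (1.0, 10.0, 40.0, 75.0):
                fg = eval_field_grid(sources, flow3d, grid, t)
                assert np.all(np.isfinite(fg.values))
                assert np.all(fg.values >= 0)
                assert np.max(fg.values) < np.inf
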