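"""Aggregation kernel values, matrices, identities and the staircase origin."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsgpbm import (
    build_kernel_matrix,
    circle_step,
    kernel_relative_difference,
    kernel_value,
    square_step,
    square_step_power,
    tanh_double_step,
    volume_of_diameter,
)
from tsgpbm.kernels import AggregationKernelSpec


class TestSquareStep:
    def test_step_one_is_product_kernel(self, grid35):
        spec = square_step(R=500.0, step=1.0, beta0=1.0)
        v = grid35.representative_volumes
        m = build_kernel_matrix(spec, grid35)
        assert m == pytest.approx((v[:, None] * v[None, :]) ** (1.0 / 3.0), rel=1e-15)

    def test_equal_thousand_volumes_below_step(self):
        spec = square_step(R=500.0, step=7.0, beta0=1.0)
        assert kernel_value(spec, 1000.0, 1000.0) == pytest.approx(100.0, rel=1e-12)

    def test_multiplier_applies_when_either_partner_exceeds_R(self):
        spec = square_step(R=100.0, step=5.0, beta0=1.0)
        small = volume_of_diameter(50.0)
        big = volume_of_diameter(200.0)
        assert kernel_value(spec, small, big) == pytest.approx(
            5.0 * (small * big) ** (1.0 / 3.0), rel=1e-12)
        assert kernel_value(spec, small, small) == pytest.approx(
            (small * small) ** (1.0 / 3.0), rel=1e-12)

    def test_R_below_grid_gives_stepped_product_matrix(self, grid35):
        spec = square_step(R=0.5, step=3.0, beta0=1.0)
        base = build_kernel_matrix(square_step(R=1e9, step=2.0, beta0=1.0), grid35)
        assert build_kernel_matrix(spec, grid35) == pytest.approx(3.0 * base, rel=1e-14)

    def test_R_above_grid_gives_plain_product_matrix(self, grid35):
        spec = square_step(R=6999.0, step=3.0, beta0=1.0)
        v = grid35.representative_volumes
        assert build_kernel_matrix(spec, grid35) == pytest.approx(
            (v[:, None] * v[None, :]) ** (1.0 / 3.0), rel=1e-14)


class TestKernelIdentities:
    def test_power_one_third_reduces_to_square_step(self, grid35):
        a = build_kernel_matrix(square_step(R=300.0, step=12.0, beta0=1.0), grid35)
        b = build_kernel_matrix(
            AggregationKernelSpec("square_step_power", beta0=1.0, R=300.0, step=12.0, p=1 / 3),
            grid35)
        assert b == pytest.approx(a, rel=1e-15)

    def test_sharp_tanh_converges_to_circle_step(self, grid35):
        step = 8.0
        R = 500.0
        circle = circle_step(R=R, step=step, beta0=1.0)
        tanh = tanh_double_step(top1=step, R2=R, beta0=1.0, top2=1.0,
                                delta1=1e-3, delta2=1e-3)
        v = grid35.representative_volumes
        x, e = np.meshgrid(v, v, indexing="ij")
        s = np.sqrt(x**2 + e**2)
        away = np.abs(s - R**3) > 1e3 * 1e-3  # off the step locus
        mc = build_kernel_matrix(circle, grid35)
        mt = build_kernel_matrix(tanh, grid35)
        # the tanh second step (at 7000 um equivalent) never acts inside the grid
        assert np.allclose(mt[away], mc[away], rtol=1e-6)

    def test_tanh_plateau_ratio_at_reference_conditions(self, grid35):
        spec = tanh_double_step(top1=10.0, R2=500.0, beta0=7e-12)
        v = grid35.representative_volumes
        mult = build_kernel_matrix(spec, grid35) / (
            (v[:, None] * v[None, :]) ** (1.0 / 3.0))
        assert mult.max() / mult.min() == pytest.approx(10.0, rel=1e-9)

    def test_tanh_low_plateau_below_R2_high_between(self):
        spec = tanh_double_step(top1=10.0, R2=500.0, beta0=1.0, delta1=1.0, delta2=1.0)
        tiny = 100.0  # volume well below R2^3
        mid = 1e9     # volume between R2^3 = 1.25e8 and R1^3 = 1.8e11
        assert kernel_value(spec, tiny, tiny) / (tiny * tiny) ** (1 / 3) == pytest.approx(1.0)
        assert kernel_value(spec, mid, tiny) / (mid * tiny) ** (1 / 3) == pytest.approx(10.0)


class TestKernelProperties:
    @settings(max_examples=60, deadline=None)
    @given(
        variant=st.sampled_from(["tanh_double_step", "circle_step", "square_step",
                                 "square_step_power"]),
        x=st.floats(1e-3, 1e10), e=st.floats(1e-3, 1e10),
        step=st.floats(0.1, 1e3), R=st.floats(1.0, 5000.0),
        p=st.floats(0.05, 1.0),
    )
    def test_symmetry(self, variant, x, e, step, R, p):
        if variant == "tanh_double_step":
            spec = tanh_double_step(top1=step, R2=R, beta0=1.0)
        elif variant == "circle_step":
            spec = circle_step(R=R, step=step, beta0=1.0)
        elif variant == "square_step":
            spec = square_step(R=R, step=step, beta0=1.0)
        else:
            spec = square_step_power(R=R, step=step, beta0=1.0, p=p)
        assert kernel_value(spec, x, e) == kernel_value(spec, e, x)

    @settings(max_examples=30, deadline=None)
    @given(step=st.floats(1.0, 1e3), R=st.floats(10.0, 3000.0))
    def test_square_step_monotone_in_each_argument(self, step, R):
        spec = square_step(R=R, step=step, beta0=1.0)
        sizes = np.geomspace(1.0, 1e10, 40)
        partner = 1e5
        values = kernel_value(spec, sizes, partner)
        assert np.all(np.diff(values) >= -1e-12 * values[:-1])

    def test_negative_sizes_rejected(self):
        spec = square_step(R=100.0, step=2.0, beta0=1.0)
        with pytest.raises(ValueError):
            kernel_value(spec, -1.0, 10.0)

    def test_invariants_enforced_on_spec(self):
        with pytest.raises(ValueError):
            square_step(R=-5.0, step=2.0, beta0=1.0)
        with pytest.raises(ValueError):
            tanh_double_step(top1=10.0, R2=800.0, beta0=1.0, R1=500.0)  # R1 <= R2
        with pytest.raises(ValueError):
            square_step_power(R=10.0, step=2.0, beta0=1.0, p=1.5)
        with pytest.raises(ValueError):
            AggregationKernelSpec("no_such_kernel")


class TestDiscretizationStaircase:
    def test_matrix_changes_only_at_representative_crossings(self, grid35):
        # sweep R continuously; distinct matrices = representatives spanned + 1
        lo, hi = 400.0, 600.0
        values = np.linspace(lo, hi, 401)
        seen = []
        for r in values:
            m = build_kernel_matrix(square_step(R=r, step=5.0, beta0=1.0), grid35)
            key = m.tobytes()
            if not seen or seen[-1] != key:
                if key not in seen:
                    seen.append(key)
        d = grid35.representative_diameters
        spanned = int(np.sum((d >= lo) & (d < hi)))
        assert len(seen) == spanned + 1


class TestRelativeDifference:
    def test_identical_matrices_fully_masked(self, grid6):
        m = build_kernel_matrix(square_step(R=100.0, step=2.0, beta0=1.0), grid6)
        rel = kernel_relative_difference(m, m)
        assert rel.mask.all()

    def test_doubled_matrix_gives_ones(self, grid6):
        m = build_kernel_matrix(square_step(R=100.0, step=2.0, beta0=1.0), grid6)
        rel = kernel_relative_difference(m, 2.0 * m)
        assert np.allclose(rel.compressed(), 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kernel_relative_difference(np.ones((3, 3)), np.ones((4, 4)))

    def test_sharp_tanh_vs_square_differs_only_across_step_loci(self, grid35):
        # the two kernels disagree exactly where their step indicators
        # classify a pair differently (circle in volume vs square in diameter)
        step = 10.0
        R = 500.0
        tanh = tanh_double_step(top1=step, R2=R, beta0=1.0, delta1=1e-3, delta2=1e-3)
        square = square_step(R=R, step=step, beta0=1.0)
        mt = build_kernel_matrix(tanh, grid35)
        ms = build_kernel_matrix(square, grid35)
        rel = np.abs(mt - ms) / ms
        v = grid35.representative_volumes
        d = grid35.representative_diameters
        x, e = np.meshgrid(v, v, indexing="ij")
        circle_fast = np.sqrt(x**2 + e**2) > R**3
        dx, de = np.meshgrid(d, d, indexing="ij")
        square_fast = (dx > R) | (de > R)
        disagreement = circle_fast != square_fast  # exhaustive pair scan
        assert np.all(rel[~disagreement] < 1e-6)
        assert np.all(rel[disagreement] > 0.1)
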