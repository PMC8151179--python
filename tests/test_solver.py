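"""Fixed-pivot aggregation, breakage RHS, compartment integration, chains.

The aggregation and breakage right-hand sides are checked element-wise
against independent brute-force implementations on small grids.
"""

import numpy as np
import pytest

from tsgpbm import (
    BreakageSpec,
    CompartmentSpec,
    GridMismatchError,
    ParticleSizeDistribution,
    aggregation_rhs,
    breakage_rhs,
    build_breakage_operator,
    build_kernel_matrix,
    generate_preblend,
    integrate_compartment,
    reference_kneading_compartment,
    reference_wetting_compartment,
    simulate_chain,
    square_step,
)


def brute_force_aggregation(numbers, beta, volumes, beta0):
    """Direct double sum over all ordered pairs with pivot splitting."""
    n = len(numbers)
    out = np.zeros(n)
    vmax = volumes[-1]
    for i in range(n):
        for j in range(n):
            v_new = volumes[i] + volumes[j]
            if v_new > vmax * (1 + 1e-12):
                continue  # pair does not react: no outflow over the grid top
            rate = 0.5 * beta0 * beta[i, j] * numbers[i] * numbers[j]
            k = int(np.searchsorted(volumes, v_new, side="right") - 1)
            if k >= n - 1:
                out[n - 1] += rate
            else:
                w_hi = (v_new - volumes[k]) / (volumes[k + 1] - volumes[k])
                out[k] += (1 - w_hi) * rate
                out[k + 1] += w_hi * rate
            # each of the two partners dies at the pair rate
            out[i] -= rate
            out[j] -= rate
    return out


class TestAggregationRHS:
    def test_matches_brute_force_on_random_states(self, grid6, rng):
        spec = square_step(R=200.0, step=5.0, beta0=1.0)
        beta = build_kernel_matrix(spec, grid6)
        v = grid6.representative_volumes
        for _ in range(100):
            numbers = rng.random(6) * rng.choice([1.0, 1e3, 1e6])
            psd = ParticleSizeDistribution(grid6, numbers)
            got = aggregation_rhs(psd, beta, beta0=2.5e-7)
            want = brute_force_aggregation(numbers, beta, v, 2.5e-7)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12 * np.abs(want).max())

    def test_zero_efficiency_gives_zero_derivative(self, grid6, rng):
        spec = square_step(R=200.0, step=5.0, beta0=1.0)
        beta = build_kernel_matrix(spec, grid6)
        psd = ParticleSizeDistribution(grid6, rng.random(6))
        assert np.all(aggregation_rhs(psd, beta, beta0=0.0) == 0.0)

    def test_volume_conserved_and_number_decreases(self, grid35, rng):
        spec = square_step(R=200.0, step=5.0, beta0=1.0)
        beta = build_kernel_matrix(spec, grid35)
        v = grid35.representative_volumes
        for _ in range(20):
            numbers = rng.random(35) * 1e4
            psd = ParticleSizeDistribution(grid35, numbers)
            dn = aggregation_rhs(psd, beta, beta0=1e-9)
            scale = np.abs(v * np.abs(dn)).sum()
            assert abs(v @ dn) <= 1e-12 * scale
            assert dn.sum() < 0.0

    def test_grid_mismatch_rejected(self, grid6, grid35, rng):
        spec = square_step(R=200.0, step=5.0, beta0=1.0)
        beta = build_kernel_matrix(spec, grid35)
        psd = ParticleSizeDistribution(grid6, rng.random(6))
        with pytest.raises(GridMismatchError):
            aggregation_rhs(psd, beta, beta0=1.0)


class TestBreakageRHS:
    @pytest.fixture()
    def operators(self, grid6):
        spec = BreakageSpec(S0=0.3, mu=100.0, sigma=30.0, fprim=0.4)
        return build_breakage_operator(spec, grid6)

    def test_matches_brute_force(self, grid6, operators, rng):
        selection, redistribution = operators
        for _ in range(100):
            numbers = rng.random(6) * 1e3
            psd = ParticleSizeDistribution(grid6, numbers)
            got = breakage_rhs(psd, selection, redistribution)
            want = np.zeros(6)
            for i in range(6):
                for j in range(6):
                    want[i] += redistribution[i, j] * selection[j] * numbers[j]
                want[i] -= selection[i] * numbers[i]
            assert got == pytest.approx(want, rel=1e-12)

    def test_mass_derivative_zero(self, grid6, operators, rng):
        selection, redistribution = operators
        v = grid6.representative_volumes
        for _ in range(20):
            psd = ParticleSizeDistribution(grid6, rng.random(6) * 1e3)
            dn = breakage_rhs(psd, selection, redistribution)
            assert abs(v @ dn) <= 1e-12 * (v * selection * psd.number_per_bin).sum()

    def test_single_mother_bin_number_derivative(self, grid6, operators):
        selection, redistribution = operators
        j = 4
        numbers = np.zeros(6)
        numbers[j] = 10.0
        psd = ParticleSizeDistribution(grid6, numbers)
        dn = breakage_rhs(psd, selection, redistribution)
        daughters = redistribution[:, j].sum()
        assert dn.sum() == pytest.approx((daughters - 1.0) * selection[j] * 10.0, rel=1e-12)


class TestIntegrateCompartment:
    def test_no_mechanisms_is_identity(self, grid35):
        pre = generate_preblend(grid35)
        comp = CompartmentSpec("C1", square_step(R=500.0, step=5.0, beta0=0.0))
        out = integrate_compartment(pre, comp)
        assert out.number_per_bin == pytest.approx(pre.number_per_bin, rel=1e-9)

    def test_pure_aggregation_decreases_number_conserves_mass(self, grid35):
        pre = generate_preblend(grid35)
        out = integrate_compartment(pre, reference_wetting_compartment(grid35))
        assert out.total_number < pre.total_number
        assert out.total_volume == pytest.approx(pre.total_volume, rel=1e-6)

    def test_unimodal_preblend_becomes_bimodal(self, grid35):
        # square step between the preblend mode and the grid top induces
        # the experimentally observed bimodal shape after the wetting zone
        pre = generate_preblend(grid35)
        out = integrate_compartment(pre, reference_wetting_compartment(grid35))
        f = out.volume_fractions()
        interior_maxima = [
            i for i in range(1, 34)
            if f[i] > f[i - 1] and f[i] >= f[i + 1] and f[i] > 1e-3
        ]
        assert len(interior_maxima) == 2

    def test_determinism(self, grid35):
        pre = generate_preblend(grid35)
        comp = reference_wetting_compartment(grid35)
        a = integrate_compartment(pre, comp)
        b = integrate_compartment(pre, comp)
        assert np.array_equal(a.number_per_bin, b.number_per_bin)

    def test_invalid_tolerances_rejected(self, grid35):
        pre = generate_preblend(grid35)
        with pytest.raises(ValueError):
            integrate_compartment(pre, reference_wetting_compartment(grid35), rel_tol=-1.0)


class TestSimulateChain:
    def test_single_compartment_equals_integrate(self, grid35):
        pre = generate_preblend(grid35)
        comp = reference_wetting_compartment(grid35)
        chain = simulate_chain(pre, [comp])
        direct = integrate_compartment(pre, comp)
        assert np.array_equal(chain.final.number_per_bin, direct.number_per_bin)

    def test_all_zero_rates_pass_preblend_through(self, grid35):
        pre = generate_preblend(grid35)
        comps = [
            CompartmentSpec("C1", square_step(R=500.0, step=5.0, beta0=0.0)),
            CompartmentSpec("C3", square_step(R=500.0, step=5.0, beta0=0.0),
                            breakage=BreakageSpec(S0=0.0, mu=100.0, sigma=30.0, fprim=0.4)),
        ]
        chain = simulate_chain(pre, comps)
        assert chain.final.number_per_bin == pytest.approx(pre.number_per_bin, rel=1e-9)

    def test_kneading_fine_fragment_mode_sits_at_mu(self, grid35):
        # erosion-dominated kneading rebuilds a fines mode at the erosion mean
        pre = generate_preblend(grid35)
        wet = reference_wetting_compartment(grid35, beta0=2e-11)
        mu = wet.kernel.R  # mu tied to the critical size
        knead = CompartmentSpec(
            "C3", square_step(R=wet.kernel.R, step=50.0, beta0=1e-13),
            breakage=BreakageSpec(S0=0.01, mu=mu, sigma=50.0, fprim=1.0))
        chain = simulate_chain(pre, [wet, knead])
        f = chain.final.volume_fractions()
        first_mode = next(
            i for i in range(35)
            if (i == 0 or f[i] > f[i - 1]) and (i == 34 or f[i] >= f[i + 1]) and f[i] > 1e-3
        )
        assert grid35.representative_diameters[first_mode] == pytest.approx(mu, rel=1e-9)

    def test_mass_conserved_through_mixed_chain(self, grid35):
        pre = generate_preblend(grid35)
        chain = simulate_chain(pre, [reference_wetting_compartment(grid35),
                                     reference_kneading_compartment(grid35)])
        assert chain.final.total_volume == pytest.approx(pre.total_volume, rel=1e-6)
        for diag in chain.diagnostics:
            assert diag.relative_mass_drift < 1e-6

    def test_outlet_lookup_by_name(self, grid35):
        pre = generate_preblend(grid35)
        chain = simulate_chain(pre, [reference_wetting_compartment(grid35)])
        assert chain.outlet("C1") is chain.outlets[0]
        with pytest.raises(KeyError):
            chain.outlet("C9")

    def test_empty_chain_rejected(self, grid35):
        with pytest.raises(ValueError):
            simulate_chain(generate_preblend(grid35), [])
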