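"""Synthetic study data: preblends, forward-simulated targets, noisy repeats.

No granulation PSD measurements are publicly deposited, so every input
the calibration and identifiability workflows need is generated here:

* preblend PSDs — lognormal in diameter, the usual shape of a milled
  pharmaceutical powder blend (a stand-in for measured preblends);
* compartment targets — forward simulations of a known compartment
  chain, optionally perturbed by measurement-like noise, with the
  generating parameters recorded for recovery tests;
* repeated measurements — multiplicative log-normal perturbations whose
  amplitude grows toward the large-particle bins, emulating the higher
  scatter image-analysis instruments show for coarse granules.

The module also fixes the reference study conditions used throughout
the identifiability analyses: a double-step kernel with R2 = 500 μm,
top1 = 10 and β₀ = 7×10⁻¹², and its square-step counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import lognorm

from .grid import SizeGrid, diameter_of_volume
from .kernels import AggregationKernelSpec, square_step, tanh_double_step
from .psd import ParticleSizeDistribution
from .solver import ChainResult, CompartmentSpec, simulate_chain

__all__ = [
    "NoiseSpec",
    "SyntheticTargets",
    "generate_preblend",
    "generate_repeated_measurements",
    "generate_compartment_targets",
    "reference_tanh_kernel",
    "reference_square_step_kernel",
    "reference_wetting_compartment",
    "reference_kneading_compartment",
    "DEFAULT_TOTAL_NUMBER",
]

#: Total particle number of the default preblend, per reference volume of
#: material.  Sized so that, at the reference efficiency β₀ = 7×10⁻¹²,
#: the wetting zone converts an O(1) fraction of the fines into granules
#: within one dimensionless residence time.
DEFAULT_TOTAL_NUMBER = 3e8


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative log-normal measurement noise.

    ``scale`` is the base log-standard-deviation; per-bin amplitude
    grows linearly from 0.5·scale at the finest bin to 1.5·scale at the
    coarsest, mirroring the size-dependent scatter of repeated PSD
    measurements.
    """

    scale: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("noise scale must be non-negative")

    def per_bin_sigma(self, n_bins: int) -> np.ndarray:
        return self.scale * (0.5 + np.linspace(0.0, 1.0, n_bins))


def generate_preblend(grid: SizeGrid, median_diameter: float = 50.0,
                      geometric_sd: float = 1.6,
                      total_number: float = DEFAULT_TOTAL_NUMBER,
                      seed: int | None = None) -> ParticleSizeDistribution:
    """Unimodal lognormal-in-diameter preblend evaluated on the grid.

    Number weights are the lognormal density at each representative
    diameter times the local bin width in diameter, scaled to
    ``total_number``.  Deterministic: the ``seed`` argument is accepted
    for interface uniformity but no sampling takes place.
    """
    del seed  # deterministic by construction
    if geometric_sd <= 1.0:
        raise ValueError("geometric standard deviation must exceed 1")
    d = grid.representative_diameters
    if not d[0] < median_diameter < d[-1]:
        raise ValueError(
            f"median diameter {median_diameter} μm lies outside the grid span "
            f"[{d[0]:.3g}, {d[-1]:.3g}] μm"
        )
    sigma = np.log(geometric_sd)
    density = lognorm.pdf(d, s=sigma, scale=median_diameter)
    edge_d = diameter_of_volume(grid.bin_edges)
    widths = np.diff(edge_d)
    weights = density * widths
    numbers = weights * (total_number / weights.sum())
    return ParticleSizeDistribution(grid, numbers)


def generate_repeated_measurements(psd: ParticleSizeDistribution, noise: NoiseSpec,
                                   k: int) -> list[ParticleSizeDistribution]:
    """k independent noisy replicates of one PSD (total volume preserved)."""
    if k < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(noise.seed)
    return [_perturb(psd, noise, rng) for _ in range(k)]


def _perturb(psd: ParticleSizeDistribution, noise: NoiseSpec,
             rng: np.random.Generator) -> ParticleSizeDistribution:
    if noise.scale == 0:
        return psd
    sigma = noise.per_bin_sigma(psd.grid.n_bins)
    factors = np.exp(sigma * rng.standard_normal(psd.grid.n_bins))
    numbers = psd.number_per_bin * factors
    total = numbers @ psd.grid.representative_volumes
    if total > 0 and psd.total_volume > 0:
        numbers *= psd.total_volume / total
    return ParticleSizeDistribution(psd.grid, numbers)


@dataclass(frozen=True)
class SyntheticTargets:
    """Forward-simulated calibration targets plus their generating truth."""

    truth: ChainResult
    noisy: tuple[tuple[ParticleSizeDistribution, ...], ...]  # per compartment
    compartments: tuple[CompartmentSpec, ...]
    noise: NoiseSpec


def generate_compartment_targets(preblend: ParticleSizeDistribution,
                                 chain: list[CompartmentSpec] | tuple[CompartmentSpec, ...],
                                 noise: NoiseSpec,
                                 replicates: int = 1) -> SyntheticTargets:
    """Simulate a chain and emit noisy per-compartment target PSDs.

    The noise-free truth and the generating compartment specs are
    retained so that calibration can be scored as parameter recovery.
    """
    truth = simulate_chain(preblend, list(chain))
    rng = np.random.default_rng(noise.seed)
    noisy = tuple(
        tuple(_perturb(outlet, noise, rng) for _ in range(replicates))
        for outlet in truth.outlets
    )
    return SyntheticTargets(truth=truth, noisy=noisy,
                            compartments=tuple(chain), noise=noise)


# ---------------------------------------------------------------------------
# Reference study conditions


def reference_tanh_kernel(beta0: float = 7e-12) -> AggregationKernelSpec:
    """Double-step kernel at the reference conditions used in the
    staircase analyses: R2 = 500 μm, top1 = 10, top2 = 1, sharp smoothers."""
    return tanh_double_step(top1=10.0, R2=500.0, beta0=beta0)


def reference_square_step_kernel(grid: SizeGrid, R: float | None = None,
                                 step: float = 50.0,
                                 beta0: float = 7e-12) -> AggregationKernelSpec:
    """Square-step kernel with R snapped to a representative diameter.

    Defaults to the representative size nearest 500 μm so that the step
    sits where the reference double-step kernel places it.
    """
    target = 500.0 if R is None else R
    return square_step(R=grid.nearest_representative(target), step=step, beta0=beta0)


def reference_wetting_compartment(grid: SizeGrid, R: float | None = None,
                                  step: float = 50.0,
                                  beta0: float = 7e-12) -> CompartmentSpec:
    """Wetting zone (pure aggregation) with the square-step kernel."""
    return CompartmentSpec(name="C1",
                           kernel=reference_square_step_kernel(grid, R, step, beta0))


def reference_kneading_compartment(grid: SizeGrid, R: float | None = None,
                                   step: float = 50.0, beta0: float = 2e-12,
                                   S0: float = 2e-3, fprim: float = 0.3,
                                   name: str = "C3") -> CompartmentSpec:
    """Kneading zone (aggregation + breakage) with μ tied to R and σ = 50 μm."""
    from .breakage import BreakageSpec

    kernel = reference_square_step_kernel(grid, R, step, beta0)
    breakage = BreakageSpec(S0=S0, mu=kernel.R, sigma=50.0, fprim=fprim)
    return CompartmentSpec(name=name, kernel=kernel, breakage=breakage)
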