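"""Breakage: linear selection function and erosion + binary daughter law.

A mother granule of volume m is selected to break at rate S(m) = S₀·m^⅓.
When it breaks, a fraction ``fprim`` of its mass erodes into small
fragments whose *diameters* follow a Gaussian N(μ, σ²) (μ, σ in μm),
while the remaining fraction splits uniformly in daughter volume —
binary breakage contributing two daughters on average.

The discretized operator integrates the daughter density over each
daughter bin (the erosion term in closed form via the normal CDF in
equivalent-diameter space) and then rescales every mother column so that discrete
daughter mass equals the mother's representative volume exactly: the
continuous law is only approximately mass-conserving because the
Gaussian is truncated at both ends, and a leaking operator would poison
every downstream conservation test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr

from .grid import SizeGrid, diameter_of_volume, volume_of_diameter

__all__ = [
    "BreakageSpec",
    "selection_rate",
    "daughter_density",
    "build_breakage_operator",
]


@dataclass(frozen=True)
class BreakageSpec:
    """Parameters of the selection and daughter-size laws.

    S0 : breakage rate constant (1/time per μm of d^⅓ scale), ≥ 0
    mu : mean erosion-fragment diameter (μm), > 0
    sigma : standard deviation of the erosion Gaussian (μm), > 0
    fprim : mass fraction routed to erosion fragments, in [0, 1]
    """

    S0: float
    mu: float
    sigma: float
    fprim: float

    def __post_init__(self) -> None:
        if self.S0 < 0:
            raise ValueError("S0 must be non-negative")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.fprim <= 1.0:
            raise ValueError("fprim must lie in [0, 1]")

    def with_params(self, **changes) -> "BreakageSpec":
        return replace(self, **changes)


def selection_rate(spec: BreakageSpec, m):
    """Rate S₀·m^⅓ at which a granule of volume m is selected to break."""
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mother volume must be positive")
    r = spec.S0 * m ** (1.0 / 3.0)
    return float(r) if r.ndim == 0 else r


def daughter_density(spec: BreakageSpec, m: float, d):
    """Daughter-volume density b(m, d) for mother volume m (μm³).

    Erosion term: Gaussian in the daughter *equivalent diameter* (μm),
    so that μ and σ carry the same units and meaning as the critical
    size R of the aggregation kernels; the m/v(μ) factor makes its mass
    integral ≈ fprim·m.  Binary term: uniform 2/m in daughter volume,
    whose mass integral is exactly (1−fprim)·m.
    """
    d = np.asarray(d, dtype=float)
    if m <= 0:
        raise ValueError("mother volume must be positive")
    if np.any(d <= 0) or np.any(d > m * (1 + 1e-12)):
        raise ValueError("daughter volume must satisfy 0 < d <= m")
    u = diameter_of_volume(d)
    gauss = np.exp(-((u - spec.mu) ** 2) / (2.0 * spec.sigma**2)) / (
        np.sqrt(2.0 * np.pi) * spec.sigma
    )
    # du/dd for the equivalent-diameter substitution
    jacobian = u / (3.0 * d)
    erosion = spec.fprim * gauss * (m / volume_of_diameter(spec.mu)) * jacobian
    binary = (1.0 - spec.fprim) * 2.0 / m
    value = erosion + binary
    return float(value) if value.ndim == 0 else value


def build_breakage_operator(spec: BreakageSpec, grid: SizeGrid) -> tuple[np.ndarray, np.ndarray]:
    """Discretize breakage on the grid.

    Returns ``(selection, redistribution)``: ``selection[j]`` is S(v_j)
    and ``redistribution[i, j]`` the expected number of daughters landing
    in bin i per breakage of a mother at pivot v_j.  Each column is
    rescaled so Σ_i M_ij·v_i = v_j exactly; daughters only occupy bins
    with v_i ≤ v_j.  A mother whose daughter law has no representable
    mass (erosion mean far above the mother size with fprim = 1) gets an
    identity column, making its breakage a no-op.
    """
    v = grid.representative_volumes
    edges = grid.bin_edges
    n = grid.n_bins
    selection = selection_rate(spec, v) if spec.S0 > 0 else np.zeros(n)

    redistribution = np.zeros((n, n))
    for j in range(n):
        m = v[j]
        for i in range(j + 1):
            lo = 0.0 if i == 0 else edges[i]
            hi = min(edges[i + 1], m)
            if hi <= lo:
                continue
            redistribution[i, j] = _bin_daughter_number(spec, m, lo, hi)
        mass = redistribution[:, j] @ v
        if mass > 1e-12 * m:
            redistribution[:, j] *= m / mass
        else:
            redistribution[:, j] = 0.0
            redistribution[j, j] = 1.0
    return selection, redistribution


def _bin_daughter_number(spec: BreakageSpec, m: float, lo: float, hi: float) -> float:
    """∫ b(m, d) dd over [lo, hi] in closed form.

    Substituting the equivalent diameter for d turns the erosion
    integral into a Gaussian CDF difference; the binary term is uniform
    in d.
    """
    erosion = 0.0
    if spec.fprim > 0:
        u_lo = diameter_of_volume(lo) if lo > 0 else 0.0
        u_hi = diameter_of_volume(hi)
        phi = ndtr((u_hi - spec.mu) / spec.sigma) - ndtr((u_lo - spec.mu) / spec.sigma)
        erosion = spec.fprim * (m / volume_of_diameter(spec.mu)) * phi
    binary = (1.0 - spec.fprim) * 2.0 * (hi - lo) / m
    return erosion + binary
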