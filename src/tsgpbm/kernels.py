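"""Aggregation kernels with step-like size dependence.

Classical kernels (sum, product) cannot turn a unimodal feed into a
bimodal granule population; all variants here superimpose a step on a
product-type collision frequency so that particle combinations beyond a
critical size aggregate faster.  The collision frequency β(x, ε) excludes
the aggregation efficiency β₀, which the solver applies separately so
kernel shape and rate can be varied independently.

Variants
--------
``tanh_double_step``
    The original double smooth step: a low plateau ``top2`` for small
    particle combinations, a high plateau ``top1`` beyond ``R2``, and a
    second step to zero beyond ``R1``, each smoothed by a hyperbolic
    tangent of width δ.  The distance from the origin in the (x, ε)
    volume plane, s = (x² + ε²)^½, is compared against R³ with R in μm.
``circle_step``
    Sharp single step on the same circular locus: rate multiplied by
    ``step`` once s exceeds R³.
``square_step``
    Sharp single step on a square locus in equivalent-diameter space:
    the multiplier applies as soon as either partner exceeds the critical
    diameter R (μm).  Power 1/3 on each volume.
``square_step_power``
    Same square locus with a tunable power p on each volume (default
    2/5), which decouples the spacing of the two modes from the feed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import SizeGrid, diameter_of_volume, volume_of_diameter

__all__ = [
    "AggregationKernelSpec",
    "tanh_double_step",
    "circle_step",
    "square_step",
    "square_step_power",
    "kernel_value",
    "build_kernel_matrix",
    "kernel_relative_difference",
]

_VARIANTS = ("tanh_double_step", "circle_step", "square_step", "square_step_power")


@dataclass(frozen=True)
class AggregationKernelSpec:
    """Variant plus the parameters that variant actually uses.

    Lengths (R, R1, R2) are in μm; δ smoothers act in the volume-space
    argument of the tanh; β₀ has units 1/time and is assumed constant in
    time and size-independent.
    """

    variant: str
    beta0: float = 0.0
    # tanh_double_step
    top1: float | None = None
    top2: float | None = None
    R1: float | None = None
    R2: float | None = None
    delta1: float | None = None
    delta2: float | None = None
    # circle_step / square_step / square_step_power
    R: float | None = None
    step: float | None = None
    # square_step_power
    p: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown kernel variant {self.variant!r}")
        if self.beta0 < 0:
            raise ValueError("beta0 must be non-negative")
        required = {
            "tanh_double_step": ("top1", "top2", "R1", "R2", "delta1", "delta2"),
            "circle_step": ("R", "step"),
            "square_step": ("R", "step"),
            "square_step_power": ("R", "step", "p"),
        }[self.variant]
        for name in required:
            if getattr(self, name) is None:
                raise ValueError(f"{self.variant} kernel requires parameter {name!r}")
        if self.variant == "tanh_double_step":
            if not self.R1 > self.R2 > 0:
                raise ValueError("tanh_double_step requires R1 > R2 > 0")
            if self.delta1 <= 0 or self.delta2 <= 0:
                raise ValueError("tanh smoother widths must be positive")
        else:
            if self.R <= 0:
                raise ValueError("critical size R must be positive")
            if self.step <= 0:
                raise ValueError("step multiplier must be positive")
        if self.variant == "square_step_power" and not (0 < self.p <= 1):
            raise ValueError("power p must lie in (0, 1]")

    @property
    def power(self) -> float:
        """Exponent applied to each partner volume."""
        return self.p if self.variant == "square_step_power" else 1.0 / 3.0

    def with_params(self, **changes) -> "AggregationKernelSpec":
        return replace(self, **changes)


def tanh_double_step(top1: float, R2: float, beta0: float, *, top2: float = 1.0,
                     R1: float | None = None, delta1: float = 10.0,
                     delta2: float = 10.0) -> AggregationKernelSpec:
    """Double smooth step kernel; by default the second step (to zero)
    sits at 7000 μm equivalent diameter, outside any admissible grid."""
    if R1 is None:
        R1 = volume_of_diameter(7000.0) ** (1.0 / 3.0)
    return AggregationKernelSpec("tanh_double_step", beta0=beta0, top1=top1, top2=top2,
                                 R1=R1, R2=R2, delta1=delta1, delta2=delta2)


def circle_step(R: float, step: float, beta0: float) -> AggregationKernelSpec:
    return AggregationKernelSpec("circle_step", beta0=beta0, R=R, step=step)


def square_step(R: float, step: float, beta0: float) -> AggregationKernelSpec:
    return AggregationKernelSpec("square_step", beta0=beta0, R=R, step=step)


def square_step_power(R: float, step: float, beta0: float,
                      p: float = 0.4) -> AggregationKernelSpec:
    return AggregationKernelSpec("square_step_power", beta0=beta0, R=R, step=step, p=p)


def kernel_value(spec: AggregationKernelSpec, x, eps):
    """Collision frequency β(x, ε) for volumes x, ε (μm³), excluding β₀.

    Symmetric in its two size arguments; accepts scalars or broadcastable
    arrays.
    """
    x = np.asarray(x, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if np.any(x <= 0) or np.any(eps <= 0):
        raise ValueError("particle volumes must be positive")
    if spec.variant == "tanh_double_step":
        s = np.sqrt(x * x + eps * eps)
        high = 0.5 * spec.top1 * (1.0 + np.tanh((spec.R1**3 - s) / spec.delta1))
        drop = 0.5 * (spec.top1 - spec.top2) * (1.0 + np.tanh((spec.R2**3 - s) / spec.delta2))
        value = (high - drop) * (x * eps) ** (1.0 / 3.0)
    elif spec.variant == "circle_step":
        s = np.sqrt(x * x + eps * eps)
        mult = np.where(s <= spec.R**3, 1.0, spec.step)
        value = mult * (x * eps) ** (1.0 / 3.0)
    else:  # square_step, square_step_power
        below = (diameter_of_volume(x) <= spec.R) & (diameter_of_volume(eps) <= spec.R)
        mult = np.where(below, 1.0, spec.step)
        value = mult * (x * eps) ** spec.power
    return float(value) if value.ndim == 0 else value


def build_kernel_matrix(spec: AggregationKernelSpec, grid: SizeGrid) -> np.ndarray:
    """β(v_i, v_j) over all representative-volume pairs; symmetric, ≥ 0."""
    v = grid.representative_volumes
    return kernel_value(spec, v[:, None], v[None, :])


def kernel_relative_difference(matrix_a: np.ndarray, matrix_b: np.ndarray) -> np.ma.MaskedArray:
    """|a−b|/a per entry with exact-zero differences masked out."""
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    equal = a == b
    if np.any((a <= 0) & ~equal):
        raise ValueError("reference matrix must be positive where entries differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(a - b) / a
    return np.ma.MaskedArray(rel, mask=equal)
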