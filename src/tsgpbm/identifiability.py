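"""Practical identifiability: parameter sweeps, plateaus, uniqueness.

A parameter is practically identifiable when the distance between the
simulated and target PSD, viewed as a function of that parameter, dips
below the measurement-error threshold at exactly one swept value.  Two
artefacts of the sectional discretization drive the analysis:

* *staircase profiles* — the kernel matrix only changes when a step
  location crosses a representative size, so smoothly swept location
  parameters produce piecewise-constant distance profiles (plateaus);
* *intermediate levels* — on the simulation grid a smooth tanh step is
  sampled at only a handful of sizes, so for any step location at most
  a couple of grid sizes fall inside the smoothed transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import energy_distance
from .errors import SolverError
from .grid import SizeGrid
from .kernels import AggregationKernelSpec, kernel_value
from .psd import ParticleSizeDistribution
from .solver import CompartmentSpec, integrate_compartment

__all__ = [
    "SweepResult",
    "sweep_parameter",
    "detect_plateaus",
    "uniqueness_below_threshold",
    "discretized_step_levels",
]


@dataclass(frozen=True)
class SweepResult:
    """Distance profile over one swept parameter."""

    parameter: str
    values: np.ndarray
    distances: np.ndarray           # NaN where the simulation failed
    normalized: np.ndarray          # min-max scaled to [0, 1]
    plateaus: tuple[tuple[int, int], ...]  # inclusive index ranges
    threshold: float | None = None
    below_threshold: tuple[int, ...] = ()

    @property
    def n_below_threshold(self) -> int:
        return len(self.below_threshold)

    @property
    def identifiable(self) -> bool | None:
        """True iff exactly one swept value falls below the threshold."""
        if self.threshold is None:
            return None
        return self.n_below_threshold == 1

    def plateau_point_fraction(self) -> float:
        """Fraction of swept points that belong to multi-point plateaus."""
        covered = sum(hi - lo + 1 for lo, hi in self.plateaus if hi > lo)
        return covered / self.values.size

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "values": self.values.tolist(),
            "distances": self.distances.tolist(),
            "normalized": self.normalized.tolist(),
            "plateaus": [list(p) for p in self.plateaus],
            "threshold": self.threshold,
            "below_threshold": list(self.below_threshold),
            "identifiable": self.identifiable,
        }


def sweep_parameter(model_template: CompartmentSpec,
                    inlet: ParticleSizeDistribution,
                    target_psd: ParticleSizeDistribution,
                    param_name: str,
                    values,
                    threshold: float | None = None,
                    flat_tol: float = 1e-3) -> SweepResult:
    """One forward simulation + energy distance per swept value.

    Kernel parameter names (R, R2, step, beta0, ...) and breakage names
    (S0, fprim, ...) resolve against the compartment template.  A failed
    simulation is recorded as NaN rather than aborting the sweep; only an
    all-failed sweep raises.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or not np.all(np.isfinite(values)):
        raise ValueError("need at least 2 finite sweep values")
    distances = np.full(values.size, np.nan)
    for k, value in enumerate(values):
        try:
            comp = _set_parameter(model_template, param_name, float(value))
            outlet = integrate_compartment(inlet, comp)
            distances[k] = energy_distance(outlet, target_psd).value
        except (SolverError, ValueError):
            continue
    ok = np.isfinite(distances)
    if not ok.any():
        raise SolverError(f"sweep over {param_name!r}: every simulation failed")
    normalized = _min_max(distances)
    plateaus = detect_plateaus(normalized, flat_tol)
    below: tuple[int, ...] = ()
    if threshold is not None:
        below = tuple(int(i) for i in np.flatnonzero(ok & (distances < threshold)))
    return SweepResult(parameter=param_name, values=values, distances=distances,
                       normalized=normalized, plateaus=plateaus,
                       threshold=threshold, below_threshold=below)


def _set_parameter(comp: CompartmentSpec, name: str, value: float) -> CompartmentSpec:
    from .calibration import _BREAKAGE_PARAMS, _KERNEL_PARAMS

    if name in _KERNEL_PARAMS:
        return comp.with_kernel_params(**{name: value})
    if name in _BREAKAGE_PARAMS:
        return comp.with_breakage_params(**{name: value})
    raise ValueError(f"parameter {name!r} does not resolve in the compartment template")


def _min_max(distances: np.ndarray) -> np.ndarray:
    ok = np.isfinite(distances)
    lo = distances[ok].min()
    hi = distances[ok].max()
    if hi == lo:
        out = np.where(ok, 0.0, np.nan)
        return out
    return (distances - lo) / (hi - lo)


def detect_plateaus(sweep, flat_tol: float) -> tuple[tuple[int, int], ...]:
    """Maximal runs of consecutive points varying by less than ``flat_tol``.

    Operates on the normalized profile of a :class:`SweepResult` (or a
    raw array); run boundaries are the step locations of a staircase
    profile.  NaN points terminate runs.
    """
    if flat_tol <= 0:
        raise ValueError("flat_tol must be positive")
    profile = sweep.normalized if isinstance(sweep, SweepResult) else np.asarray(sweep, float)
    runs: list[tuple[int, int]] = []
    start = 0
    lo = hi = profile[0] if profile.size else np.nan
    for i in range(1, profile.size + 1):
        extend = False
        if i < profile.size and np.isfinite(profile[i]) and np.isfinite(lo):
            new_lo = min(lo, profile[i])
            new_hi = max(hi, profile[i])
            extend = (new_hi - new_lo) < flat_tol
        if extend:
            lo, hi = new_lo, new_hi
            continue
        runs.append((start, i - 1))
        if i < profile.size:
            start = i
            lo = hi = profile[i]
    return tuple(runs)


def uniqueness_below_threshold(sweep: SweepResult, threshold: float) -> SweepResult:
    """Re-evaluate a sweep against a measurement-error threshold.

    Returns a new :class:`SweepResult` whose ``below_threshold`` indices
    and ``identifiable`` verdict reflect the given threshold: the swept
    parameter is identifiable at this error level iff exactly one value
    lies below it; zero values below flags a non-attainable target.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ok = np.isfinite(sweep.distances)
    below = tuple(int(i) for i in np.flatnonzero(ok & (sweep.distances < threshold)))
    return SweepResult(parameter=sweep.parameter, values=sweep.values,
                       distances=sweep.distances, normalized=sweep.normalized,
                       plateaus=sweep.plateaus, threshold=threshold,
                       below_threshold=below)


def discretized_step_levels(kernel_spec: AggregationKernelSpec, grid: SizeGrid,
                            fixed_size: float, sweep_values_for_R2) -> int:
    """Maximum number of intermediate step levels visible on the grid.

    For each swept R2, the tanh kernel's step multiplier (kernel value
    divided by the product factor) is evaluated at every representative
    size with the partner fixed at ``fixed_size`` (a volume); values
    strictly between the plateaus — more than 1% of the plateau gap away
    from both — count as intermediate.  Returns the maximum count over
    the sweep: on a coarse grid a smooth step is sampled by at most a
    couple of sizes, which is why sweeping R2 produces a staircase.
    """
    if kernel_spec.variant != "tanh_double_step":
        raise ValueError("intermediate-level analysis applies to the tanh kernel only")
    v = grid.representative_volumes
    product = (v * fixed_size) ** (1.0 / 3.0)
    low = min(kernel_spec.top1, kernel_spec.top2)
    high = max(kernel_spec.top1, kernel_spec.top2)
    tol = 0.01 * (high - low)
    worst = 0
    for r2 in np.asarray(sweep_values_for_R2, dtype=float):
        spec = kernel_spec.with_params(R2=float(r2))
        mult = kernel_value(spec, v, fixed_size) / product
        count = int(np.sum((mult > low + tol) & (mult < high - tol)))
        worst = max(worst, count)
    return worst
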