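"""Per-compartment calibration: parameter reduction and PSO fitting.

The full model carries more parameters than the data can pin down, so
calibration proceeds in two stages:

1. *Parameter reduction* — the critical size R of the square-step
   kernel is read directly off the wetting-zone measurements as the
   depletion point of the fines peak (majority vote across liquid-to-
   solid ratio conditions, ties toward the smaller size).  The erosion
   mean μ of the breakage law is tied to the same size (the fines that
   survive the kneading zones sit where the un-granulated fines sat) and
   σ is fixed at 50 μm, neither a tight nor a broad erosion mode.  This
   leaves two free parameters in the wetting zone (step, β₀) and three
   in each kneading zone (β₀, S₀, fprim).

2. *Particle swarm optimization* — a seeded global-best PSO minimizes
   the energy distance between the simulated compartment outlet and the
   target PSD.  Rate-like parameters (β₀) are searched on a log₁₀
   scale.  PSO is preferred over local optimizers because the objective
   has plateaus and is not differentiable in the step-kernel parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .distances import energy_distance
from .errors import SolverError
from .psd import ParticleSizeDistribution, estimate_depletion_size
from .solver import CompartmentSpec, integrate_compartment

__all__ = [
    "PSOSettings",
    "CalibrationProblem",
    "CalibrationResult",
    "ReducedParameters",
    "reduce_parameters",
    "calibrate_wetting",
    "calibrate_kneading",
    "minimize_pso",
]

_KERNEL_PARAMS = {"beta0", "step", "R", "top1", "top2", "R1", "R2", "delta1", "delta2", "p"}
_BREAKAGE_PARAMS = {"S0", "mu", "sigma", "fprim"}

#: Default search bounds.  β₀ spans ten decades around the reference
#: efficiency 7×10⁻¹² and, like the breakage rate constant S₀, is
#: searched on a log₁₀ scale: both are rate constants whose plausible
#: range spans decades, and a linear search concentrates the swarm in
#: the extreme-rate regime where a compensating aggregation/breakage
#: balance traps the optimizer away from the true basin.
DEFAULT_BOUNDS = {
    "step": (1.0, 1e4),
    "beta0": (1e-16, 1e-6),
    "S0": (1e-5, 1e2),
    "fprim": (0.0, 1.0),
}
DEFAULT_LOG_SCALE = frozenset({"beta0", "S0"})


@dataclass(frozen=True)
class PSOSettings:
    """Global-best PSO hyperparameters (constriction-type defaults)."""

    swarm_size: int = 30
    iterations: int = 150
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    seed: int = 0
    ftol: float = 1e-12       # stop once the best objective falls below this
    patience: int | None = 40  # stop after this many stalled iterations


@dataclass(frozen=True)
class CalibrationProblem:
    """One compartment's fitting problem.

    ``free_parameters`` maps parameter names to (lower, upper) bounds;
    names in ``log_scale`` are searched in log₁₀ space (bounds must then
    be positive).
    """

    compartment: CompartmentSpec
    inlet: ParticleSizeDistribution
    target: ParticleSizeDistribution
    free_parameters: dict[str, tuple[float, float]]
    log_scale: frozenset[str] = DEFAULT_LOG_SCALE
    settings: PSOSettings = field(default_factory=PSOSettings)

    def __post_init__(self) -> None:
        if not self.free_parameters:
            raise ValueError("need at least one free parameter")
        for name, (lo, hi) in self.free_parameters.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"parameter {name!r} needs finite bounds with lo < hi")
            if name in self.log_scale and lo <= 0:
                raise ValueError(f"log-scaled parameter {name!r} needs positive bounds")
            if name not in _KERNEL_PARAMS | _BREAKAGE_PARAMS:
                raise ValueError(f"unknown parameter {name!r}")


@dataclass(frozen=True)
class CalibrationResult:
    best_parameters: dict[str, float]
    best_objective: float
    trace: np.ndarray  # best objective after each iteration
    seed: int

    def __post_init__(self) -> None:
        if self.trace.size and not np.isclose(self.best_objective, self.trace.min()):
            raise ValueError("best objective must equal the minimum of the trace")


@dataclass(frozen=True)
class ReducedParameters:
    """Sizes fixed by the parameter-reduction protocol (all in μm)."""

    R: float
    mu: float
    sigma: float = 50.0


#: Size classes between the detected depletion category and the critical
#: size R.  With a sharp square step, the fines peak collapses in the
#: first class *strictly above* R (those particles gain the stepped
#: aggregation channel against the entire fines population), and the
#: width-3 smoothing of the valley detector shifts the minimum one
#: further class up while its window still contains the fines tail.
#: Both offsets are structural, not scenario-dependent.
DEPLETION_TO_R_OFFSET = 2


def reduce_parameters(wetting_psd_measurements: list[ParticleSizeDistribution],
                      formulation_label: str | None = None) -> ReducedParameters:
    """Fix R, μ and σ from wetting-zone measurements.

    The depletion point of the fines peak sits in the same size class
    regardless of process conditions, so it is detected per measurement
    and combined by majority vote (ties toward the smaller size); R is
    the representative size :data:`DEPLETION_TO_R_OFFSET` classes below
    the voted depletion category, μ is set equal to R and σ to 50 μm.
    Raises when no measurement exhibits a depletion point, in which case
    R must be calibrated instead.
    """
    if not wetting_psd_measurements:
        raise ValueError("need at least one wetting-zone PSD")
    votes: dict[float, int] = {}
    for psd in wetting_psd_measurements:
        r = estimate_depletion_size(psd)
        if r is not None:
            votes[r] = votes.get(r, 0) + 1
    if not votes:
        label = f" for {formulation_label}" if formulation_label else ""
        raise ValueError(
            f"no depletion point found in any wetting-zone measurement{label}; "
            "R cannot be read off the data and must be calibrated"
        )
    best_count = max(votes.values())
    depletion = min(size for size, count in votes.items() if count == best_count)
    grid = wetting_psd_measurements[0].grid
    diameters = grid.representative_diameters
    idx = int(np.argmin(np.abs(diameters - depletion)))
    r = float(diameters[max(idx - DEPLETION_TO_R_OFFSET, 0)])
    return ReducedParameters(R=r, mu=r, sigma=50.0)


# ---------------------------------------------------------------------------
# PSO


def minimize_pso(objective, bounds: np.ndarray, settings: PSOSettings):
    """Seeded global-best PSO with reflecting bound handling.

    ``objective`` maps a position matrix (swarm_size × n_dim) to a vector
    of objective values (non-finite values are treated as +inf).
    Returns ``(best_position, best_value, trace)``.
    """
    rng = np.random.default_rng(settings.seed)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    n_dim = bounds.shape[0]
    pos = lo + span * rng.random((settings.swarm_size, n_dim))
    vel = 0.1 * span * (2.0 * rng.random((settings.swarm_size, n_dim)) - 1.0)

    values = _evaluate(objective, pos)
    if np.sum(~np.isfinite(values)) > 0.5 * settings.swarm_size:
        raise ValueError("objective non-finite at more than half of the initial swarm; "
                         "check the parameter bounds")
    values = np.where(np.isfinite(values), values, np.inf)
    pbest_pos = pos.copy()
    pbest_val = values.copy()
    g = int(np.argmin(pbest_val))
    gbest_pos = pbest_pos[g].copy()
    gbest_val = float(pbest_val[g])

    trace = [gbest_val]
    stalled = 0
    for _ in range(settings.iterations):
        r1 = rng.random((settings.swarm_size, n_dim))
        r2 = rng.random((settings.swarm_size, n_dim))
        vel = (settings.inertia * vel
               + settings.cognitive * r1 * (pbest_pos - pos)
               + settings.social * r2 * (gbest_pos - pos))
        pos = pos + vel
        # reflect at the bounds, damping the velocity component
        low_mask = pos < lo
        high_mask = pos > hi
        pos = np.where(low_mask, 2.0 * lo - pos, pos)
        pos = np.where(high_mask, 2.0 * hi - pos, pos)
        pos = np.clip(pos, lo, hi)  # guard against double overshoot
        vel = np.where(low_mask | high_mask, -0.5 * vel, vel)

        values = _evaluate(objective, pos)
        values = np.where(np.isfinite(values), values, np.inf)
        improved = values < pbest_val
        pbest_pos[improved] = pos[improved]
        pbest_val[improved] = values[improved]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest_val = float(pbest_val[g])
            gbest_pos = pbest_pos[g].copy()
            stalled = 0
        else:
            stalled += 1
        trace.append(gbest_val)
        if gbest_val < settings.ftol:
            break
        if settings.patience is not None and stalled >= settings.patience:
            break
    return gbest_pos, gbest_val, np.asarray(trace)


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    values = np.asarray(objective(positions), dtype=float)
    if values.shape != (positions.shape[0],):
        raise ValueError("objective must return one value per swarm member")
    return values


# ---------------------------------------------------------------------------
# Compartment calibration


def _apply_parameters(compartment: CompartmentSpec, params: dict[str, float]) -> CompartmentSpec:
    kernel_changes = {k: v for k, v in params.items() if k in _KERNEL_PARAMS}
    breakage_changes = {k: v for k, v in params.items() if k in _BREAKAGE_PARAMS}
    out = compartment
    if kernel_changes:
        out = out.with_kernel_params(**kernel_changes)
    if breakage_changes:
        out = out.with_breakage_params(**breakage_changes)
    return out


def _calibrate(problem: CalibrationProblem) -> CalibrationResult:
    names = list(problem.free_parameters)
    bounds = np.array([
        (np.log10(lo), np.log10(hi)) if name in problem.log_scale else (lo, hi)
        for name, (lo, hi) in problem.free_parameters.items()
    ])

    def decode(position: np.ndarray) -> dict[str, float]:
        return {
            name: float(10.0 ** position[k] if name in problem.log_scale else position[k])
            for k, name in enumerate(names)
        }

    def objective(positions: np.ndarray) -> np.ndarray:
        out = np.empty(positions.shape[0])
        for k in range(positions.shape[0]):
            params = decode(positions[k])
            try:
                comp = _apply_parameters(problem.compartment, params)
                outlet = integrate_compartment(problem.inlet, comp)
                out[k] = energy_distance(outlet, problem.target).value
            except (SolverError, ValueError):
                out[k] = np.inf
        return out

    best_pos, best_val, trace = minimize_pso(objective, bounds, problem.settings)
    return CalibrationResult(best_parameters=decode(best_pos), best_objective=best_val,
                             trace=trace, seed=problem.settings.seed)


def calibrate_wetting(problem: CalibrationProblem) -> CalibrationResult:
    """Calibrate the wetting zone; free parameters ⊆ {step, beta0}.

    R is fixed beforehand by :func:`reduce_parameters`, leaving the step
    height and the aggregation efficiency as the only free parameters.
    """
    extra = set(problem.free_parameters) - {"step", "beta0"}
    if extra:
        raise ValueError(f"wetting calibration only frees step and beta0, got {sorted(extra)}")
    if problem.compartment.breakage is not None:
        raise ValueError("wetting zone carries no breakage mechanism")
    return _calibrate(problem)


def calibrate_kneading(problem: CalibrationProblem) -> CalibrationResult:
    """Calibrate a kneading zone; free parameters ⊆ {beta0, S0, fprim}.

    μ and σ are fixed beforehand by :func:`reduce_parameters`.
    """
    extra = set(problem.free_parameters) - {"beta0", "S0", "fprim"}
    if extra:
        raise ValueError(
            f"kneading calibration only frees beta0, S0 and fprim, got {sorted(extra)}"
        )
    return _calibrate(problem)
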