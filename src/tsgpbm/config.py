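"""Run configuration: YAML parsing, validation and model building.

A run configuration is a YAML mapping with a ``grid`` section, an
ordered ``compartments`` list (each with a kernel and optionally a
breakage section), optional ``calibration`` settings and a ``seed``.
Unknown keys are rejected and validation reports every violation with
its key path, not just the first.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .breakage import BreakageSpec
from .errors import ConfigError
from .grid import SizeGrid, build_geometric_grid
from .kernels import AggregationKernelSpec
from .solver import CompartmentSpec

__all__ = ["RunConfig", "load_config", "dump_config", "config_sha256"]

_VARIANT_KEYS = {
    "tanh_double_step": {"top1", "top2", "R1", "R2", "delta1", "delta2"},
    "circle_step": {"R", "step"},
    "square_step": {"R", "step"},
    "square_step_power": {"R", "step", "p"},
}


class GridSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_bins: int = 35
    d_min_um: float = 1.0
    d_max_um: float = 4000.0


class KernelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    variant: str
    beta0: float = 0.0
    top1: float | None = None
    top2: float | None = None
    R1: float | None = None
    R2: float | None = None
    delta1: float | None = None
    delta2: float | None = None
    R: float | None = None
    step: float | None = None
    p: float | None = None

    @model_validator(mode="after")
    def _only_variant_keys(self) -> "KernelSection":
        if self.variant not in _VARIANT_KEYS:
            raise ValueError(
                f"unknown kernel variant {self.variant!r}; "
                f"expected one of {sorted(_VARIANT_KEYS)}"
            )
        allowed = _VARIANT_KEYS[self.variant]
        stray = [
            name
            for name in ("top1", "top2", "R1", "R2", "delta1", "delta2", "R", "step", "p")
            if getattr(self, name) is not None and name not in allowed
        ]
        if stray:
            raise ValueError(
                f"keys {stray} do not belong to kernel variant {self.variant!r}"
            )
        return self

    def to_spec(self) -> AggregationKernelSpec:
        fields = {k: getattr(self, k) for k in _VARIANT_KEYS[self.variant]}
        return AggregationKernelSpec(variant=self.variant, beta0=self.beta0, **fields)


class BreakageSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    S0: float
    mu_um: float
    sigma_um: float = 50.0
    fprim: float = Field(ge=0.0, le=1.0)

    def to_spec(self) -> BreakageSpec:
        return BreakageSpec(S0=self.S0, mu=self.mu_um, sigma=self.sigma_um, fprim=self.fprim)


class CompartmentSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    kernel: KernelSection
    breakage: BreakageSection | None = None
    integration_time: float = 1.0

    def to_spec(self) -> CompartmentSpec:
        return CompartmentSpec(
            name=self.name,
            kernel=self.kernel.to_spec(),
            breakage=None if self.breakage is None else self.breakage.to_spec(),
            integration_time=self.integration_time,
        )


class CalibrationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    swarm_size: int = 30
    iterations: int = 150
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49


class SweepSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    parameter: str = "R2"
    start: float = 400.0
    stop: float = 600.0
    num: int = 201
    flat_tol: float = 1e-3


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    grid: GridSection = Field(default_factory=GridSection)
    compartments: list[CompartmentSection] = Field(default_factory=list)
    calibration: CalibrationSection = Field(default_factory=CalibrationSection)
    sweep: SweepSection = Field(default_factory=SweepSection)
    seed: int = 0

    def build_grid(self) -> SizeGrid:
        g = self.grid
        return build_geometric_grid(g.n_bins, g.d_min_um, g.d_max_um)

    def build_compartments(self) -> list[CompartmentSpec]:
        return [section.to_spec() for section in self.compartments]


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    Raises :class:`~tsgpbm.errors.ConfigError` listing *all* schema
    violations with their key paths.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(part) for part in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(f"{path}: {len(lines)} validation error(s):\n" + "\n".join(lines)) from exc


def dump_config(config: RunConfig, path) -> None:
    """Write a configuration back to YAML (round-trips through load_config)."""
    data = config.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def config_sha256(path) -> str:
    """Hash of the raw configuration text, recorded in provenance files."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
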