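"""Particle size distributions on a :class:`~tsgpbm.grid.SizeGrid`.

A PSD stores particle *numbers* per bin (per a fixed reference volume of
material); the volume-fraction view — what a laser diffraction or image
analysis instrument reports — is derived from it.  Tables are plain CSV
with a ``diameter_um`` column plus either ``number`` or
``volume_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, GridMismatchError
from .grid import SizeGrid, build_geometric_grid

__all__ = [
    "ParticleSizeDistribution",
    "to_volume_fraction",
    "read_psd_table",
    "write_psd_table",
    "estimate_depletion_size",
]


@dataclass(frozen=True)
class ParticleSizeDistribution:
    """Number of particles per size bin on a fixed grid."""

    grid: SizeGrid
    number_per_bin: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.number_per_bin, dtype=float)
        object.__setattr__(self, "number_per_bin", n)
        if n.shape != (self.grid.n_bins,):
            raise GridMismatchError(
                f"number_per_bin has {n.size} entries for a {self.grid.n_bins}-bin grid"
            )
        if np.any(n < 0):
            raise ValueError("particle numbers must be non-negative")
        if not np.all(np.isfinite(n)):
            raise ValueError("particle numbers must be finite")

    @property
    def total_number(self) -> float:
        return float(self.number_per_bin.sum())

    @property
    def total_volume(self) -> float:
        return float(self.number_per_bin @ self.grid.representative_volumes)

    def volume_fractions(self) -> np.ndarray:
        return to_volume_fraction(self)

    def with_numbers(self, numbers: np.ndarray) -> "ParticleSizeDistribution":
        return ParticleSizeDistribution(self.grid, np.asarray(numbers, dtype=float))


def to_volume_fraction(psd: ParticleSizeDistribution) -> np.ndarray:
    """Volume fraction per bin: n_i·v_i / Σ_j n_j·v_j (sums to 1)."""
    w = psd.number_per_bin * psd.grid.representative_volumes
    total = w.sum()
    if total <= 0:
        raise DegenerateInputError("PSD carries no volume; volume fractions undefined")
    return w / total


def from_volume_fraction(grid: SizeGrid, fractions: np.ndarray,
                         total_volume: float = 1.0) -> ParticleSizeDistribution:
    """Inverse of :func:`to_volume_fraction` up to the overall scale."""
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0):
        raise ValueError("volume fractions must be non-negative")
    s = f.sum()
    if s <= 0:
        raise DegenerateInputError("volume fractions sum to zero")
    numbers = (f / s) * total_volume / grid.representative_volumes
    return ParticleSizeDistribution(grid, numbers)


def write_psd_table(psd: ParticleSizeDistribution, path) -> None:
    """Write a PSD as CSV with diameter, number and volume-fraction columns."""
    frame = pd.DataFrame(
        {
            "diameter_um": psd.grid.representative_diameters,
            "number": psd.number_per_bin,
            "volume_fraction": _safe_volume_fractions(psd),
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def _safe_volume_fractions(psd: ParticleSizeDistribution) -> np.ndarray:
    if psd.total_volume > 0:
        return to_volume_fraction(psd)
    return np.zeros(psd.grid.n_bins)


def read_psd_table(path, grid: SizeGrid | None = None) -> ParticleSizeDistribution:
    """Read a PSD table written by :func:`write_psd_table` or by hand.

    Requires a ``diameter_um`` column plus ``number`` and/or
    ``volume_fraction``; ``number`` wins when both are present.  When no
    grid is supplied, one is reconstructed from the diameters, which must
    form a geometric progression.
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse PSD table {path}: {exc}") from exc
    if "diameter_um" not in frame.columns:
        raise FormatError(f"{path}: missing required column 'diameter_um'")
    diameters = frame["diameter_um"].to_numpy(dtype=float)
    for row, d in enumerate(diameters):
        if not np.isfinite(d) or d <= 0:
            raise FormatError(f"{path}: row {row}: non-positive diameter {d}")
    if np.any(np.diff(diameters) <= 0):
        row = int(np.flatnonzero(np.diff(diameters) <= 0)[0]) + 1
        raise FormatError(f"{path}: row {row}: diameters must increase strictly")
    if grid is None:
        grid = build_geometric_grid(diameters.size, diameters[0], diameters[-1])
    if not np.allclose(grid.representative_diameters, diameters, rtol=1e-9):
        raise FormatError(f"{path}: diameters do not match the target grid")

    if "number" in frame.columns:
        column = "number"
        numbers = frame["number"].to_numpy(dtype=float)
    elif "volume_fraction" in frame.columns:
        column = "volume_fraction"
        fractions = frame["volume_fraction"].to_numpy(dtype=float)
        _check_non_negative(fractions, column, path)
        return from_volume_fraction(grid, fractions)
    else:
        raise FormatError(f"{path}: need a 'number' or 'volume_fraction' column")
    _check_non_negative(numbers, column, path)
    return ParticleSizeDistribution(grid, numbers)


def _check_non_negative(values: np.ndarray, column: str, path) -> None:
    bad = np.flatnonzero(~np.isfinite(values) | (values < 0))
    if bad.size:
        row = int(bad[0])
        raise FormatError(f"{path}: row {row}: negative or non-finite {column} {values[row]}")


def estimate_depletion_size(psd: ParticleSizeDistribution,
                            smoothing_window: int = 3) -> float | None:
    """Locate the depletion point of a bimodal PSD, in μm.

    The depletion point is the size at which the first (fines) peak of the
    volume-fraction curve dies out towards larger sizes: the first local
    minimum after the first local maximum, detected on a centred
    moving-average smoothing of the curve.  The returned value is snapped
    to the representative diameter of the valley bin, which can then be
    used directly as the critical size R of the step aggregation kernels.

    Returns ``None`` when the PSD has no interior valley (e.g. a strictly
    unimodal curve), signalling that R cannot be read off the data.
    """
    f = to_volume_fraction(psd)
    s = _moving_average(f, smoothing_window)
    n = s.size
    # first local maximum: a strict rise into the peak (or a strict fall
    # from the very first bin), so a flat leading baseline never counts
    peak = None
    for i in range(n - 1):
        left_rise = s[i] > s[i - 1] if i > 0 else s[0] > s[1]
        if left_rise and s[i] >= s[i + 1]:
            peak = i
            break
    if peak is None:
        return None
    for i in range(peak + 1, n - 1):
        if s[i] < s[i - 1] and s[i] <= s[i + 1]:
            return float(psd.grid.representative_diameters[i])
    return None


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.copy()
    half = window // 2
    out = np.empty_like(values)
    for i in range(values.size):
        lo = max(0, i - half)
        hi = min(values.size, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out
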