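"""Geometric size grid over particle volume.

The internal coordinate of the population balance is particle volume
(μm³); sizes are reported to users as equivalent-sphere diameters (μm).
The grid is geometric in volume: representative volumes form a geometric
progression and bin edges sit at the geometric midpoints, with the outer
edges extended by half a ratio step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SizeGrid",
    "build_geometric_grid",
    "volume_of_diameter",
    "diameter_of_volume",
    "MAX_REPRESENTATIVE_DIAMETER_UM",
]

#: Largest admissible representative diameter (μm).  Keeping every
#: representative size below this bound guarantees that the second step of
#: the double-step aggregation kernel (which sends the rate to zero for
#: very large aggregates) never acts inside the grid, i.e. particles
#: cannot aggregate out of the system.
MAX_REPRESENTATIVE_DIAMETER_UM = 7000.0

_GEOMETRIC_RTOL = 1e-12


def volume_of_diameter(d: float | np.ndarray) -> float | np.ndarray:
    """Equivalent-sphere volume (μm³) of a diameter ``d`` (μm): v = (π/6)·d³."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    v = (np.pi / 6.0) * d**3
    return float(v) if v.ndim == 0 else v


def diameter_of_volume(v: float | np.ndarray) -> float | np.ndarray:
    """Equivalent-sphere diameter (μm) of a volume ``v`` (μm³)."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be positive")
    d = (6.0 * v / np.pi) ** (1.0 / 3.0)
    return float(d) if d.ndim == 0 else d


@dataclass(frozen=True)
class SizeGrid:
    """Geometric discretization of particle volume.

    Parameters
    ----------
    representative_volumes
        Strictly increasing pivot volumes (μm³), geometric to 1e-12
        relative tolerance.
    bin_edges
        ``n_bins + 1`` strictly increasing edge volumes (μm³) interleaving
        the representatives.
    """

    representative_volumes: np.ndarray
    bin_edges: np.ndarray
    representative_diameters: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.representative_volumes, dtype=float)
        e = np.asarray(self.bin_edges, dtype=float)
        object.__setattr__(self, "representative_volumes", v)
        object.__setattr__(self, "bin_edges", e)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least 2 representative volumes")
        if e.shape != (v.size + 1,):
            raise ValueError("bin_edges must have n_bins + 1 entries")
        if np.any(v <= 0) or np.any(np.diff(v) <= 0):
            raise ValueError("representative volumes must be positive and strictly increasing")
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(v <= e[:-1]) or np.any(v >= e[1:]):
            raise ValueError("each representative volume must lie strictly inside its bin")
        ratios = v[1:] / v[:-1]
        if not np.allclose(ratios, ratios[0], rtol=_GEOMETRIC_RTOL, atol=0.0):
            raise ValueError("representative volumes must be geometric to 1e-12")
        d = diameter_of_volume(v)
        if d[-1] >= MAX_REPRESENTATIVE_DIAMETER_UM:
            raise ValueError(
                f"largest representative diameter {d[-1]:.1f} μm must stay below "
                f"{MAX_REPRESENTATIVE_DIAMETER_UM:.0f} μm"
            )
        object.__setattr__(self, "representative_diameters", d)

    @property
    def n_bins(self) -> int:
        return self.representative_volumes.size

    @property
    def ratio(self) -> float:
        """Common ratio of the geometric volume progression."""
        v = self.representative_volumes
        return float((v[-1] / v[0]) ** (1.0 / (v.size - 1)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SizeGrid):
            return NotImplemented
        return self.representative_volumes.shape == other.representative_volumes.shape and bool(
            np.array_equal(self.representative_volumes, other.representative_volumes)
            and np.array_equal(self.bin_edges, other.bin_edges)
        )

    def __hash__(self) -> int:
        return hash((self.representative_volumes.tobytes(), self.bin_edges.tobytes()))

    def nearest_representative(self, diameter_um: float) -> float:
        """Representative diameter closest to ``diameter_um`` (μm)."""
        d = self.representative_diameters
        return float(d[np.argmin(np.abs(d - diameter_um))])


def build_geometric_grid(n_bins: int, d_min: float, d_max: float) -> SizeGrid:
    """Build a volume-geometric grid between two diameters.

    Representative volumes run geometrically from v(d_min) to v(d_max);
    edges sit at geometric midpoints, outer edges half a ratio step
    outside the extreme representatives.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if not (0 < d_min < d_max):
        raise ValueError("diameter bounds must satisfy 0 < d_min < d_max")
    v_min = volume_of_diameter(d_min)
    v_max = volume_of_diameter(d_max)
    v = np.geomspace(v_min, v_max, n_bins)
    sqrt_r = (v_max / v_min) ** (0.5 / (n_bins - 1))
    edges = np.empty(n_bins + 1)
    edges[1:-1] = np.sqrt(v[:-1] * v[1:])
    edges[0] = v[0] / sqrt_r
    edges[-1] = v[-1] * sqrt_r
    return SizeGrid(representative_volumes=v, bin_edges=edges)


#: The grid used throughout the reference analyses: 35 bins, 1–4000 μm.
def default_grid() -> SizeGrid:
    """35-bin volume-geometric grid spanning diameters 1–4000 μm."""
    return build_geometric_grid(35, 1.0, 4000.0)
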