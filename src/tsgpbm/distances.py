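"""Energy distance between PSDs and the measurement-error noise floor.

The calibration objective is the energy distance — equivalently a
maximum mean discrepancy — between the volume-fraction views of two
PSDs, with the representative diameters (μm) as support points:

    D(u, v) = (2·E|X−Y| − E|X−X′| − E|Y−Y′|)^½

where X, X′ ~ u and Y, Y′ ~ v independently.  The measurement-error
threshold is the median of all pairwise distances among repeated
measurements; a parameter value is practically indistinguishable from
the optimum when its distance falls below this floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import energy_distance as _scipy_energy_distance

from .errors import DegenerateInputError, GridMismatchError
from .psd import ParticleSizeDistribution, to_volume_fraction

__all__ = ["DistanceResult", "energy_distance", "measurement_error_threshold"]


@dataclass(frozen=True)
class DistanceResult:
    """Energy distance value and the support convention it was computed on."""

    value: float
    support: str  # "diameter" or "log_diameter"

    def __float__(self) -> float:
        return self.value


def energy_distance(u: ParticleSizeDistribution, v: ParticleSizeDistribution,
                    log_diameter: bool = False) -> DistanceResult:
    """Energy distance between the volume-fraction views of two PSDs.

    Distributions are compared on representative diameters in μm
    (optionally log-diameters); both PSDs must live on the same grid and
    carry positive total volume.
    """
    if u.grid != v.grid:
        raise GridMismatchError("PSDs live on different grids")
    if u.total_volume <= 0 or v.total_volume <= 0:
        raise DegenerateInputError("cannot compare a zero-mass PSD")
    support = u.grid.representative_diameters
    if log_diameter:
        support = np.log(support)
    value = _scipy_energy_distance(support, support,
                                   to_volume_fraction(u), to_volume_fraction(v))
    return DistanceResult(value=float(value),
                          support="log_diameter" if log_diameter else "diameter")


def measurement_error_threshold(repeats: list[ParticleSizeDistribution],
                                log_diameter: bool = False) -> float:
    """Median pairwise energy distance among repeated measurements.

    The median (rather than the mean) keeps the threshold robust to an
    occasional outlying repeat.  Requires at least two PSDs.
    """
    if len(repeats) < 2:
        raise ValueError("need at least 2 repeated measurements")
    distances = [
        energy_distance(a, b, log_diameter=log_diameter).value
        for a, b in combinations(repeats, 2)
    ]
    return float(np.median(distances))
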