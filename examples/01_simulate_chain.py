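"""Simulate a preblend through the wetting and kneading zones.

Builds the default 35-bin grid (1–4000 μm), a lognormal preblend, and a
two-compartment chain: a wetting zone with the square-step aggregation
kernel and a kneading zone that adds breakage.  Prints per-compartment
diagnostics and the location of the granule modes.
"""

import numpy as np

from tsgpbm import (
    default_grid,
    generate_preblend,
    reference_kneading_compartment,
    reference_wetting_compartment,
    simulate_chain,
)

grid = default_grid()
preblend = generate_preblend(grid)
chain = simulate_chain(preblend, [
    reference_wetting_compartment(grid),
    reference_kneading_compartment(grid),
])

print(f"preblend: {preblend.total_number:.3e} particles, "
      f"{preblend.total_volume:.3e} um^3 total volume")
for psd, diag in zip(chain.outlets, chain.diagnostics):
    f = psd.volume_fractions()
    modes = [i for i in range(grid.n_bins)
             if (i == 0 or f[i] > f[i - 1])
             and (i == grid.n_bins - 1 or f[i] >= f[i + 1]) and f[i] > 1e-3]
    mode_d = ", ".join(f"{grid.representative_diameters[i]:.0f}" for i in modes)
    print(f"{diag.name}: number change {diag.number_change:+.3e}, "
          f"mass drift {diag.relative_mass_drift:.1e}, modes at {mode_d} um")

# The wetting zone turns the unimodal preblend bimodal: un-granulated
# fines survive below the critical size R while granules grow above it.
# The kneading zone then shifts and reshapes both peaks through the
# combined action of aggregation and breakage; mass is conserved
# throughout (drift ~ 1e-15).
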