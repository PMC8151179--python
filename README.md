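# tsgpbm

Compartmental one-dimensional population balance modelling of
twin-screw wet granulation: step-type aggregation kernels, a
mass-conserving aggregation–breakage solver, energy-distance
calibration with particle swarm optimization, and practical
identifiability analysis of the kernel parameters.

## The problem

Continuous twin-screw wet granulation turns a fine powder preblend into
granules as it passes a wetting zone and successive kneading zones.
The granule size distribution (PSD) is the critical quality attribute;
a low liquid-to-solid ratio leaves part of the feed un-granulated, so
the wetting-zone PSD is typically *bimodal*: a surviving fines peak and
a granule peak.  Classical aggregation kernels (sum, product) cannot
produce bimodality from a unimodal feed, so the compartmental model
used here gives the collision frequency a step: particle combinations
beyond a critical size R aggregate `step` times faster,

    β(x, ε) = β₀ · (x·ε)^p · [1 if d(x) ≤ R and d(ε) ≤ R else step],

with breakage in the kneading zones from a linear selection function
S(m) = S₀·m^⅓ and an erosion-plus-binary daughter law b(m, d).

Two practical-identifiability artefacts drive the package's analyses:

* on the discrete simulation grid, the original *smooth* (tanh) step
  kernel changes only when its step location crosses a representative
  size, so the calibration objective is a staircase in that parameter —
  whole intervals fit equally well;
* judged against a measurement-error floor (the median pairwise energy
  distance among repeated measurements), only the sharp square-step
  kernel with R restricted to the grid's representative sizes leaves a
  *single* admissible parameter value.

The package implements the resulting calibration protocol: read R off
the depletion point of the fines peak, tie the erosion mean μ = R, fix
σ = 50 μm, and calibrate the remaining two wetting parameters
(step, β₀) and three kneading parameters (β₀, S₀, fprim) by PSO against
the energy distance.  It is written for process modellers in
pharmaceutical development; all experimental inputs are emulated by a
first-class synthetic-data module.

## Worked example

```python
import numpy as np
from tsgpbm import (default_grid, generate_preblend, simulate_chain,
                    reference_wetting_compartment, reference_kneading_compartment,
                    energy_distance, estimate_depletion_size)

grid = default_grid()                      # 35 bins, 1-4000 um, geometric in volume
preblend = generate_preblend(grid)         # lognormal powder blend, median 50 um
chain = simulate_chain(preblend, [
    reference_wetting_compartment(grid),   # square-step kernel, R ~ 445 um
    reference_kneading_compartment(grid),  # + breakage, mu = R, sigma = 50 um
])
wetting = chain.outlet("C1")
print(round(estimate_depletion_size(wetting), 1))
print(round(energy_distance(preblend, wetting).value, 4))
print(f"{chain.diagnostics[0].relative_mass_drift:.1e}")
```

prints

```
725.2
10.3529
4.4e-16
```

— the wetting outlet is bimodal with its fines-depletion point in the
725 μm size class (two classes above the kernel's critical size, a
structural offset the calibration protocol inverts), it sits an energy
distance of 10.35 (μm^½ scale) from the preblend, and the solver
conserved mass to machine precision.  The `examples/` directory holds
one narrative script per capability (chain simulation, noise floor,
staircase identifiability, parameter reduction + PSO calibration, and
a shell workflow for the CLI).

A thin command-line interface mirrors the library:

```sh
tsgpbm simulate --config run.yaml --preblend preblend.csv --out-dir results/
tsgpbm distance a.csv b.csv
tsgpbm noise-floor repeats/*.csv
tsgpbm sweep --config run.yaml --target C1.csv --inlet preblend.csv \
       --param R --from 150 --to 1200 --num 9 --out sweep.json
```

PSD tables are plain CSV (`diameter_um` plus `number` or
`volume_fraction`); configurations are YAML with strict validation.

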