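"""Directional variography and coregionalization-model fitting.

Simulates unconditional Gaussian cofields from the reference model, pools
their directional experimental variograms and refits the nugget + spherical
model with free ranges — a self-consistency check of the whole variography
stack (the fit should recover 84 m along-shore and 27 m cross-shore).
"""

import numpy as np

from littersim import (
    GridSpec,
    beach_litter_lmc,
    fit_lmc,
    grid_variogram_set,
    pool_variograms,
    turning_bands_unconditional,
)

model = beach_litter_lmc()
grid = GridSpec()
n_fields = 8

sets = []
for seed in range(n_fields):
    z = turning_bands_unconditional(model, grid.node_coords(), n_lines=600,
                                    rng=seed)
    sets.append(
        grid_variogram_set(grid, z, azimuths=(0.0,), lag_centres=np.arange(1.0, 91.0))
        + grid_variogram_set(grid, z, azimuths=(90.0,), lag_centres=np.arange(1.0, 46.0))
    )
fitted, info = fit_lmc(pool_variograms(sets))

print(f"pooled variograms of {n_fields} simulated cofields on the 50x150 grid")
print(f"fitted ranges : {info.ranges[0]:.1f} m (azimuth 0), "
      f"{info.ranges[1]:.1f} m (azimuth 90)")
print("reference     : 84.0 m, 27.0 m")
for s in fitted.structures:
    print(f"{s.kind:10s} sill matrix:\n{np.round(s.sill, 3)}")
print(
    "\nSingle-field fits scatter widely (the range is comparable to the\n"
    "domain); pooling replicates recovers the generating model."
)
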