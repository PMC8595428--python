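"""Simulate a coupled marmoset pair and recover the inter-brain synchrony map.

Two brains on identical grids share a band-limited latent signal (0.01-0.1 Hz)
at rho = 0.4 inside a central region.  Four 400-volume runs per subject are
detrended, normalized per run, concatenated (n = 1600), correlated voxel-wise,
and Fisher-Z transformed; voxels with z >= 3.1 are flagged as synchronous.
"""

import numpy as np

from hyperbold.preprocess import detrend_poly
from hyperbold.synchrony import synchrony_pipeline
from hyperbold.synthgen import CouplingSpec, NoiseSpec, simulate_pair
from hyperbold.volio import Mask3D

shape = (12, 12, 10)
mask = Mask3D(np.ones(shape, dtype=bool))
roi_arr = np.zeros(shape, dtype=bool)
roi_arr[3:9, 3:9, 3:7] = True
roi = Mask3D(roi_arr)

runs_a, runs_b, truth = simulate_pair(
    mask,
    coupling=CouplingSpec(roi=roi, rho=0.4),
    noise=NoiseSpec(),  # baseline 100, AR(1) noise (SD 2.2), mild drift
    n_runs=4,
    n_volumes=400,
    seed=7,
)

runs_a = [detrend_poly(r, 5) for r in runs_a]
runs_b = [detrend_poly(r, 5) for r in runs_b]
result = synchrony_pipeline(runs_a, runs_b, mask, threshold=3.1)

in_roi = result.r_map[roi.data]
outside = result.r_map[mask.data & ~roi.data]
print(f"concatenated timepoints:      {result.n_timepoints}")
print(f"median r inside coupled ROI:  {np.median(in_roi):.3f}  (target 0.400)")
print(f"median r outside the ROI:     {np.median(outside):+.3f}  (should be ~0)")
print(f"median z inside ROI:          {np.median(result.z_map[roi.data]):.1f}")
print(f"supra-threshold voxels:       {result.supra_mask.sum()} "
      f"({roi.n_voxels} truly coupled)")
# The median ROI r matches the simulated coupling strength; at n = 1600 a
# coupling of 0.4 gives z ~ 17, so every coupled voxel clears the 3.1 cut
# while the uncoupled background stays near the ~0.1% false-positive rate.
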