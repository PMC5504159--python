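"""Simulate a joint-NUS relaxation experiment and reconstruct the rate cube.

Builds a small protein-like peak table, samples 256 of 2560 joint
(t1, t_relax) grid points (10%), inverts them through the joint
Fourier-Laplace dictionary, and reads each peak's longitudinal decay
rate off the rate axis.
"""

import numpy as np

from ftilt import (
    AcquisitionGeometry,
    NoiseModel,
    SolverConfig,
    generate_schedule,
    protein_fixture,
    reconstruct_cube,
    simulate_joint_fid,
)
from ftilt.analysis import PeakList, rates_from_cube

geometry = AcquisitionGeometry(
    n_t1=32, sw_indirect=500.0, trelax_min=0.01, trelax_max=0.8,
    trelax_mesh=0.01, n_f1_recon=64, n_r_recon=64, r_min=0.5, r_max=5.0,
)
# four peaks tiled over two direct-dimension columns, as in a real HSQC
# where an amide 1H column carries only a couple of 15N peaks
peaks = protein_fixture(4, geometry, seed=1, n_columns=2)
sigma = min(p.amplitude for p in peaks) / 50.0      # SNR 50 for the weakest peak
schedule = generate_schedule(geometry, 256, seed=2)
samples = np.stack([
    simulate_joint_fid(
        [p for p in peaks if int(p.freq_direct) == c],
        geometry, schedule, NoiseModel(sigma, seed=3 + c),
    )
    for c in range(2)
])

cube = reconstruct_cube(
    samples, schedule, geometry,
    SolverConfig(tau=0.0005, tau_mode="relative", n_iter=8000),
)
estimates = rates_from_cube(cube, PeakList.from_models(peaks))

print(f"sampled {schedule.n_points} of "
      f"{geometry.n_t1 * geometry.delay_universe.size} joint grid points")
print("peak   f1 (Hz)   R true (1/s)   R joint (1/s)   status")
for p, e in zip(peaks, estimates):
    print(f"{e.peak_id}  {p.freq_indirect:8.1f}   {p.rate:12.3f}   "
          f"{e.rate:13.3f}   {e.status}")
# R joint should match R true to within a rate-grid bin (~0.07 1/s here):
# the decay rate is read directly off the cube's third axis, no
# exponential fitting involved.
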