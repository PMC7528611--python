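"""Population phase statistics: 6-h binning, chi-square uniformity, Rayleigh vector.

Draws night-clustered peak phases (as cells receiving inhibitory SCN input
show) and a uniform control population, and compares their statistics.
"""

import numpy as np

from circuitclock import phase_distribution, smoothed_phase_histogram

rng = np.random.default_rng(0)
night = np.mod(18.0 + 12 / np.pi * rng.vonmises(0.0, 2.0, 45), 24.0)
uniform = rng.uniform(0.0, 24.0, 45)

for name, phases in (("night-clustered", night), ("uniform", uniform)):
    d = phase_distribution(phases)
    print(f"{name:16s} 6-h bin counts {d.bin_counts.tolist()}  "
          f"chi2={d.chi2:5.1f} p={d.p:.4f}  R={d.rayleigh_R:.2f} "
          f"mean={d.circ_mean:5.1f} h")

grid, dens = smoothed_phase_histogram(night)
print(f"smoothed histogram: mass {dens.sum()*(grid[1]-grid[0]):.6f} "
      f"(= n cells), mode at ZT {grid[np.argmax(dens)]:.1f} h")
print("A large chi2 with small p rejects uniformity of peak times over the "
      "four 6-h bins; R near 1 means tight phase clustering, near 0 dispersion.")
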