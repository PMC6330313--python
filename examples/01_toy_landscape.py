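"""Sample a toy torsion landscape and check Boltzmann consistency.

Builds a 1D double well (2 kT and 4 kT deep), runs overdamped Langevin
dynamics, and compares the sampled angle histogram with the exact
quadrature free energy. The printed total-variation distance says how
close the sampler is to the true equilibrium ensemble (0 = perfect).
"""

import numpy as np

import loopflex as lf

spec = lf.ToySystemSpec(
    n_torsions=1,
    wells=[lf.Well((-np.pi / 2,), 2.0, 0.5), lf.Well((np.pi / 2,), 4.0, 0.5)],
    seed=42)

traj = lf.langevin_trajectory(spec, x0=[np.pi / 2], n_steps=500_000,
                              save_stride=10)
print(f"sampled {traj.n_frames} frames, frame interval "
      f"{traj.frame_interval} reduced time units")

edges = np.linspace(-np.pi, np.pi, 37)
ref = lf.reference_free_energy(spec, lf.RawTorsionCV(0), edges,
                               pts_per_dim=2000)
hist, _ = np.histogram(traj.angles[:, 0], bins=edges)
p_sim = hist / hist.sum()
tv = 0.5 * np.abs(p_sim - ref.probabilities).sum()

print(f"total-variation distance to Boltzmann quadrature: {tv:.4f}")
print(f"free-energy difference between basins (quadrature): "
      f"{ref.free_energy[:18].min() - ref.free_energy[18:].min():+.3f} kT")
print("the deeper (4 kT) well should carry most probability; TV << 0.05 "
      "means the sampler reproduces the exact ensemble")
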