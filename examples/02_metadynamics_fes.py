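"""Well-tempered metadynamics on a double well, validated by quadrature.

Deposits tempered Gaussians along a raw-torsion collective variable
(height 1.2 kT, stride 500 steps, biasfactor 10 — the biasfactor the
antibody protocol used) and reconstructs the free-energy surface from
the final bias. The RMS deviation from the exact quadrature reference
quantifies convergence.
"""

import numpy as np

import loopflex as lf

spec = lf.ToySystemSpec(
    n_torsions=1,
    wells=[lf.Well((-np.pi / 2,), 2.0, 0.5), lf.Well((np.pi / 2,), 4.0, 0.5)],
    seed=7)
cv = lf.RawTorsionCV(0, label="psi")
params = lf.MetadParams(height=1.2, sigmas=(0.3,), stride=500,
                        biasfactor=10.0)

traj, hills = lf.run_wt_metad(spec, cv, params, x0=[np.pi / 2],
                              n_steps=300_000, save_stride=50)
print(f"deposited {hills.n_hills} hills; first height "
      f"{hills.heights[0]:.3f} kT (= w0), last height "
      f"{hills.heights[-1]:.3f} kT (tempered down)")

grid = np.linspace(-np.pi, np.pi, 73)
fes = lf.fes_from_hills(hills, grid)
ref = lf.reference_free_energy(spec, cv, grid, pts_per_dim=2000)
low = ref.free_energy < 4.0
rms = np.sqrt(np.mean((fes.free_energy[low] - ref.free_energy[low]) ** 2))
print(f"FES RMS deviation from quadrature (bins within 4 kT of the "
      f"minimum): {rms:.3f} kT")
print("decaying hill heights and a sub-0.3 kT deviation indicate a "
      "converged well-tempered estimate")
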