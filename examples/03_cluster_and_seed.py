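"""Cluster a biased exploration ensemble and plan seeded runs.

Embeds a metadynamics torsion ensemble as an idealized Ca trace,
computes the pairwise Kabsch RMSD matrix, clusters it by average linkage
at a 1 A cutoff, and balances unbiased follow-up runs across the cluster
representatives so every system reaches a comparable sampling total.
"""

import numpy as np

import loopflex as lf

spec = lf.ToySystemSpec(
    n_torsions=2,
    wells=[lf.Well((-1.8, 0.0), 2.5, 0.55), lf.Well((0.0, 1.8), 2.5, 0.55),
           lf.Well((1.8, 0.0), 2.5, 0.55)],
    seed=3)
cvs = list(lf.default_loop_cvs(1, 1))
params = lf.MetadParams(height=1.2, stride=500, biasfactor=10.0)

traj, _ = lf.run_wt_metad(spec, cvs, params, x0=[-1.8, 0.0],
                          n_steps=30_000, save_stride=20)
coords = lf.embed_ca_trace(traj)
D = lf.pairwise_rmsd_matrix(coords, stride=10)
model = lf.average_linkage_cluster(D, cutoff=1.0)

print(f"{traj.n_frames} biased frames -> {D.shape[0]} strided frames -> "
      f"{model.n_clusters} clusters at 1.0 A cutoff")
print("cluster sizes:", model.sizes.tolist())
print("medoid representative frames:", model.representatives.tolist())

runs = lf.balance_seeded_runs(model.n_clusters, run_length=100,
                              total_target=8400)
print(f"balancing toward 8400 time units with 100-unit runs: "
      f"{runs} seeded runs per representative")
print("each representative is a real ensemble frame, so it can seed an "
      "unbiased run directly")
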