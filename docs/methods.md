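# Methods

This note records the models, estimators, default parameters and design
choices behind loopflex, and what the synthetic benchmarks do and do not
demonstrate about real loop dynamics.

## Units and conventions

Reduced units throughout: energies in kT (kT = 1 by default), time
dimensionless, one reduced time unit labelled "ns" in report tables to
match the field's reporting style. Published Gaussian heights in
kcal/mol translate via 1 kT = 0.5922 kcal/mol at 300 K
(`toy_dynamics.KCAL_PER_KT_300K`). All torsions live on (-pi, pi]; the
wrap maps -pi to +pi. Dihedral signs follow the standard convention of
structural-biology toolkits (trans = pi, cis = 0; verified against both
a brute-force rotation construction and biotite): for the quadruple
(0,0,0),(1,0,0),(1,1,0),(1,1,1) the dihedral is +pi/2.

## Synthetic torsion dynamics

The landscape is a log-sum-exp mixture of periodic Gaussian wells,

    U(x) = -kT ln sum_k exp(depth_k - sum_j d_ang(x_j, c_kj)^2 / (2 s_k^2)),

smooth and 2 pi-periodic, with directly interpretable well depths (kT)
and widths (rad). Two caveats worth knowing when designing systems:
the *effective* barrier out of a well is roughly
min(depth, d^2 / (2 s^2)) where d is the distance to the saddle — wide
wells cap the barrier well below the nominal depth; and with several
overlapping wells the depths shift slightly from the nominal values.

Dynamics is overdamped (position) Langevin,

    x <- x - (dt/friction) grad(U + V_bias) + sqrt(2 kT dt / friction) xi,

wrapped each step. Velocity-resolved integrators and thermostats are
deliberately out of scope: the artifact tests analysis machinery, not
force fields, and the overdamped chain has the correct equilibrium
ensemble and a well-defined kinetic structure. Defaults dt = 0.01 and
friction = 1 keep the per-step drift below the well widths for depths
up to ~10 kT at width >= 0.35. Noise is pre-generated from a numpy
Generator, so determinism is a seeding contract independent of the
numba-compiled inner loops. The saved-frame interval (save_stride) is a
free choice; the packaged configurations save every 20 steps (0.2 time
units).

Two oracles close the loop: dense midpoint-rule Boltzmann quadrature
over the torus (exact marginal free energies for up to 3 torsions;
midpoint sampling keeps bin occupancies exactly balanced and symmetric)
and exact discrete Markov-chain sampling for kinetic-estimator tests.

## Collective variables and metadynamics

CVs are linear combinations `sum_j a_j sin(x_ij) + b_j cos(x_ij)`. The
published protocol does not print the combination coefficients, so the
default is unit sin and cos weights per loop torsion, overridable in
config; with two loop blocks the pipeline biases two CVs (one per
block). Sin/cos CVs are bounded and therefore *non-periodic* in CV
space (hills use plain distance); raw single-torsion CVs are periodic
(wrapped distance).

Well-tempered metadynamics deposits a Gaussian every `stride` steps at
the current CV value with height `w0 exp(-V(s)/((gamma-1) kT))`. Bias
and bias forces are evaluated by direct summation over hills — adequate
at desk-scale hill counts (hundreds to thousands) and free of grid
interpolation error. Hill widths are not published either; the default
is 0.1 x the CV's reachable range. The free-energy estimator is the
standard `F(s) = -(gamma/(gamma-1)) V_final(s)`, min-shifted; the
min-shift makes it invariant under constant shifts of U. The packaged
defaults (w0 = 1.2 kT, stride 500, gamma = 10) converge a 1D double
well (2/4 kT) to ~0.16 kT RMS against quadrature in 6e5 steps — the
documented convergence benchmark (seed 7).

## Geometry

Toy torsions acquire Cartesian form through an idealized Ca-trace
embedding: virtual bond 3.8 A, virtual bond angle 120 deg, the k-th
torsion as the k-th pseudo-dihedral, first three points gauge-fixed
(origin / +x / xy-plane). Measuring the pseudo-dihedrals of the
embedded chain recovers the inputs to 1e-9, so coordinate-based stages
(RMSD, PCA) are exactly consistent with torsion-space dynamics. The
original protocol aligns trajectories to the whole Fv before measuring
loop RMSD; toy chains have no Fv, so superposition is on the loop
points themselves — flagged here because absolute RMSD values are not
comparable between the two alignment choices.

RMSD is the Kabsch minimum over proper rotations (reflections
corrected), computed via scipy's rotation alignment with the residual
evaluated explicitly (the library's reported residual loses precision
near zero). PDB input goes through biotite (first model, first altloc,
ATOM records, wwPDB v3.3 columns); missing backbone atoms fail loudly
with the residue named.

## Clustering

Average-linkage agglomeration on the RMSD matrix stops when the
smallest inter-cluster average distance exceeds the cutoff
(scipy linkage + fcluster distance criterion; scipy's deterministic
tie-breaking applies). Labels are renumbered by first frame appearance;
representatives are medoids so that every representative is a real
frame usable as a seeding structure. Cutoff choice is a manual config
knob (default 1.0 A, the published value): no auto-optimization is
attempted because the published "broad cluster distribution" criterion
is not an algorithm. Microstates use k-means (k-means++ init, fixed
seed, <= 500 iterations) in tICA space.

## Projections

PCA is a covariance eigendecomposition with explained-variance
fractions relative to the total variance. tICA solves
`C(tau) v = lambda C(0) v` with the time-lagged covariance symmetrized
(real eigenvalues for reversible data) and C(0) ridge-regularized
(eps = 1e-10 default); covariances are pooled per trajectory so no
cross-trajectory time pairs form. Components follow a deterministic
sign convention (largest-|loading| entry positive). Free-energy
surfaces are histogram-based, normalized over occupied bins, empty bins
at infinite F. Basin counting smooths the probability field with a
Gaussian (default 2.5 bins on 60-bin grids — chosen so that the
packaged landscapes' constructed well counts are recovered exactly;
narrower smoothing counts sampling-noise minima) and counts local
minima below min + 2 kT.

## Markov-state models

Counts are sliding-window (maximal data use; no Bayesian error bars —
out of scope). Connectivity is *reversible*: states are linked only by
transitions observed in both directions, and the largest such component
is retained, with the retained fraction reported. The transition matrix
is the detailed-balance-constrained MLE via the standard fixed-point
iteration on symmetric edge weights, converged to 1e-10 maximum
relative change; detailed balance, row-stochasticity and stationarity
are asserted on every estimate. Implied timescales skip non-positive
eigenvalues with a warning; eigenvalues at 1 report infinity.

PCCA+ takes the first m pi-orthonormal right eigenvectors, finds
simplex vertices by the most-distant-row construction, clips negative
memberships and renormalizes rows (variants differ here; this is the
documented choice). Crisp states are argmax rows; macrostate
probability sums pi over crisp members. The macrostate count is a
config input per system (the published analysis chose 3-5 per antibody
without a stated criterion); the spectral gap is reported as the
timescale ratio t_m / t_{m+1} to inform — not automate — the choice.
Macrostate transition timescales are *directed mean-first-passage
times* (the published figures do not say whether their timescales are
MFPTs or relaxation times; MFPTs are reported and labelled as such),
computed from the linear system `m_i = 1 + sum_j T_ij m_j` with the
target set absorbing, averaged over the source macrostate with the
restricted stationary weights.

## The packaged study pair

The default configuration is a two-torsion pair of systems:

* flexible — four wells of 2.5 kT (width 0.55 rad) spread over the
  torus; barriers ~2 kT, so all wells interconvert within a seeded run;
* rigid — one dominant 6.5 kT well plus a minor 5.0 kT well (width
  0.45 rad); barriers ~4.2 kT out of the deep well.

The ~2 kT barrier difference (rate factor ~e^2) is the construction
behind every directional comparison: more clusters at the shared 1 A
cutoff, more occupied combined-PCA basins, and a several-fold longer
slowest implied timescale for the rigid system. Desk-scale problem
sizes: 2 metadynamics starts x 4e4 steps per system, seeded runs of
2e4 steps balanced toward 4.8e5 total steps per system, 150 k-means
microstates, tICA/MSM lag 25 frames (5 time units, the published lag
under the 1 unit = 1 ns labelling). The full pipeline runs in ~20 s;
per-stage seeds derive from the master seed through
`SeedSequence(master, spawn_key=(stage, index))`, making reruns
bit-reproducible.

## What the synthetic benchmarks do and do not show

They verify the *analysis machinery*: estimator correctness against
closed forms and brute force, Boltzmann consistency of the sampler,
metadynamics convergence against quadrature, and the qualitative
flexible-vs-rigid contrast under a known ground truth. They do not
emulate solvent, atomistic force fields, velocity correlations,
multi-body couplings beyond the well mixture, or the dimensionality of
a real loop (hundreds of coordinates); quantitative numbers (cluster
counts, timescales) therefore characterize the toy landscapes, not any
antibody. Known limitations: bias evaluation is O(hills) per step
(fine at desk scale, slow for millions of hills); quadrature references
stop at 3 torsions; no Bayesian/HMM estimation or transition-path
fluxes beyond MFPT.
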