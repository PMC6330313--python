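"""Synthetic loop-torsion dynamics.

This module is the data-generating stand-in for microsecond molecular
dynamics of an antibody loop. It provides

* a configurable multi-well potential on a torus of psi-like torsions
  (``ToySystemSpec``) — a smooth Gaussian-mixture landscape whose well
  depths play the role of conformational free-energy barriers,
* an overdamped Langevin integrator on that landscape
  (:func:`langevin_trajectory`), optionally under an external bias
  potential (used by the metadynamics engine),
* exact discrete Markov-chain sampling (:func:`sample_markov_chain`) used
  as an oracle generator for kinetic-model tests, and
* a dense-quadrature reference free energy (:func:`reference_free_energy`)
  against which biased-sampling estimates can be validated.

Reduced units are used throughout: energies in kT (kT = 1 by default),
time dimensionless. ``TIME_UNIT_LABEL`` maps one reduced time unit to the
"ns" labels used in report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernels
from .angles import angular_difference, wrap_angle
from .errors import (CapabilityError, DimensionError, NumericalError,
                     ValidationError)

#: label attached to one reduced time unit in report tables
TIME_UNIT_LABEL = "ns"

#: kcal/mol per kT at 300 K, for translating published Gaussian heights
KCAL_PER_KT_300K = 0.5922


@dataclass(frozen=True)
class Well:
    """One Gaussian well: a metastable loop conformation.

    depth is in kT (larger = more stable), width in radians.
    """

    center: np.ndarray
    depth: float
    width: float

    def __post_init__(self):
        center = wrap_angle(np.atleast_1d(np.asarray(self.center, float)))
        object.__setattr__(self, "center", center)
        if not self.depth > 0:
            raise ValidationError(f"well depth must be > 0, got {self.depth}")
        if not self.width > 0:
            raise ValidationError(f"well width must be > 0, got {self.width}")


@dataclass(frozen=True)
class ToySystemSpec:
    """A synthetic 'loop' defined on a torus of torsion angles."""

    n_torsions: int
    wells: Sequence[Well]
    kT: float = 1.0
    friction: float = 1.0
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_torsions < 1:
            raise ValidationError("n_torsions must be >= 1")
        if not self.dt > 0:
            raise ValidationError("dt must be > 0")
        if self.kT < 0:
            raise ValidationError("kT must be >= 0")
        if not self.friction > 0:
            raise ValidationError("friction must be > 0")
        if len(self.wells) == 0:
            raise ValidationError("at least one well is required")
        for w in self.wells:
            if w.center.shape != (self.n_torsions,):
                raise DimensionError(
                    f"well center has shape {w.center.shape}, "
                    f"expected ({self.n_torsions},)")

    def _well_arrays(self):
        centers = np.stack([w.center for w in self.wells])
        depths = np.array([w.depth for w in self.wells], float)
        widths = np.array([w.width for w in self.wells], float)
        return centers, depths, widths


@dataclass
class TorsionTrajectory:
    """Frames x n_torsions matrix of torsions, wrapped to (-pi, pi]."""

    angles: np.ndarray
    frame_interval: float
    origin_label: str = ""

    def __post_init__(self):
        self.angles = np.atleast_2d(np.asarray(self.angles, float))
        if not self.frame_interval > 0:
            raise ValidationError("frame_interval must be > 0")
        if not np.all(np.isfinite(self.angles)):
            raise ValidationError("trajectory contains non-finite angles")
        self.angles = wrap_angle(self.angles)

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_torsions(self) -> int:
        return self.angles.shape[1]


@dataclass
class DiscreteTrajectory:
    """Microstate index sequence with a fixed time per step."""

    states: np.ndarray
    n_states: int
    frame_interval: float = 1.0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64).ravel()
        if self.n_states < 1:
            raise ValidationError("n_states must be >= 1")
        if self.states.size and (
                self.states.min() < 0 or self.states.max() >= self.n_states):
            raise ValidationError("state indices out of range")


# ---------------------------------------------------------------------------
# potential and dynamics


def potential_energy(spec: ToySystemSpec, x) -> float:
    """Potential energy U(x) of the well mixture, in kT units.

    U(x) = -kT * ln sum_k exp(depth_k - sum_j d_ang(x_j, c_kj)^2/(2 s_k^2)),
    smooth and 2*pi-periodic in every torsion. With kT = 0 the landscape is
    identically flat (zero force).
    """
    x = np.atleast_1d(np.asarray(x, float))
    if x.shape != (spec.n_torsions,):
        raise DimensionError(
            f"x has shape {x.shape}, expected ({spec.n_torsions},)")
    if spec.kT == 0.0:
        return 0.0
    centers, depths, widths = spec._well_arrays()
    return float(_kernels.well_energy(centers, depths, widths, spec.kT, x))


def potential_gradient(spec: ToySystemSpec, x) -> np.ndarray:
    """dU/dx at x (kT per radian)."""
    x = np.atleast_1d(np.asarray(x, float))
    if x.shape != (spec.n_torsions,):
        raise DimensionError(
            f"x has shape {x.shape}, expected ({spec.n_torsions},)")
    out = np.zeros(spec.n_torsions)
    if spec.kT == 0.0:
        return out
    centers, depths, widths = spec._well_arrays()
    _kernels.well_gradient(centers, depths, widths, spec.kT, x, out)
    return out


def langevin_trajectory(spec: ToySystemSpec, x0, n_steps: int,
                        save_stride: int = 1,
                        bias: Optional[Callable] = None,
                        seed: Optional[int] = None) -> TorsionTrajectory:
    """Overdamped Langevin dynamics on the toy landscape.

    Parameters
    ----------
    bias : callable, optional
        ``bias(x) -> (V, dV_dx)`` adding an external potential; when given,
        the integration runs in a (slower) generic loop.
    seed : int, optional
        Overrides ``spec.seed``; identical spec + seed gives bitwise
        identical trajectories.

    The initial frame is always saved; thereafter every ``save_stride``-th
    step is kept, so the result has ``n_steps // save_stride + 1`` frames.
    """
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    if save_stride < 1:
        raise ValidationError("save_stride must be >= 1")
    x0 = wrap_angle(np.atleast_1d(np.asarray(x0, float)))
    if x0.shape != (spec.n_torsions,):
        raise DimensionError(
            f"x0 has shape {x0.shape}, expected ({spec.n_torsions},)")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    noise = rng.standard_normal((n_steps, spec.n_torsions))
    label = f"langevin-seed{spec.seed if seed is None else seed}"

    if bias is None:
        centers, depths, widths = spec._well_arrays()
        if spec.kT == 0.0:
            # flat landscape, no noise: use zero-depth gradient via kT=0 path
            frames = np.tile(x0, (n_steps // save_stride + 1, 1))
            return TorsionTrajectory(frames, spec.dt * save_stride, label)
        frames, fail = _kernels.langevin_run(
            centers, depths, widths, spec.kT, spec.friction, spec.dt,
            x0, n_steps, save_stride, noise)
        if fail >= 0:
            raise NumericalError(f"non-finite force at step {fail}")
        return TorsionTrajectory(frames, spec.dt * save_stride, label)

    # generic path with an arbitrary bias callable
    mob = spec.dt / spec.friction
    amp = np.sqrt(2.0 * spec.kT * spec.dt / spec.friction)
    x = x0.copy()
    frames = [x.copy()]
    for step in range(1, n_steps + 1):
        g = potential_gradient(spec, x)
        _, db = bias(x)
        force = g + np.asarray(db, float)
        if not np.all(np.isfinite(force)):
            raise NumericalError(f"non-finite force at step {step}")
        x = wrap_angle(x - mob * force + amp * noise[step - 1])
        if step % save_stride == 0:
            frames.append(x.copy())
    return TorsionTrajectory(np.array(frames), spec.dt * save_stride, label)


def sample_markov_chain(T, n_steps: int, start: int,
                        seed: int) -> DiscreteTrajectory:
    """Exact realization of a discrete Markov chain.

    ``T`` must be row-stochastic to 1e-12. The returned trajectory has
    ``n_steps + 1`` states, beginning at ``start``.
    """
    T = np.asarray(T, float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValidationError("T must be square")
    n = T.shape[0]
    if np.any(T < 0) or np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-12:
        raise ValidationError("T rows must be non-negative and sum to 1")
    if not (0 <= start < n):
        raise ValidationError(f"start state {start} out of range")
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    uniforms = rng.random(n_steps)
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0  # guard against round-off at the right edge
    states = _kernels.markov_chain_run(cum, start, uniforms)
    return DiscreteTrajectory(states, n_states=n)


def reference_free_energy(spec: ToySystemSpec, cv, grid,
                          pts_per_dim: int = 301):
    """Quadrature reference free energy along a collective variable.

    Computes F(s) = -kT ln p(s) with p from dense Boltzmann integration of
    exp(-U/kT) over the torsion torus, binned by cv value onto ``grid``
    (bin edges). Min-shifted to zero. Only feasible for <= 3 torsions.
    """
    from .projections import FreeEnergySurface  # local: avoid cycle at import

    if spec.n_torsions > 3:
        raise CapabilityError(
            "dense quadrature supported for at most 3 torsions")
    grid = np.asarray(grid, float)
    # midpoint rule: symmetric about 0, no double-counted endpoint
    step = 2 * np.pi / pts_per_dim
    axes = [-np.pi + (np.arange(pts_per_dim) + 0.5) * step
            for _ in range(spec.n_torsions)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    centers, depths, widths = spec._well_arrays()
    # vectorized well-mixture energy over the grid
    expo = np.full(pts.shape[0], -np.inf)
    es = np.empty((len(spec.wells), pts.shape[0]))
    for k in range(len(spec.wells)):
        d = angular_difference(pts, centers[k][None, :])
        es[k] = depths[k] - (d ** 2).sum(axis=1) / (2.0 * widths[k] ** 2)
    m = es.max(axis=0)
    U = -spec.kT * (m + np.log(np.exp(es - m).sum(axis=0)))
    w = np.exp(-(U - U.min()) / max(spec.kT, 1e-300))
    s = np.array([cv.value(p) for p in pts]) if hasattr(cv, "value") \
        else np.apply_along_axis(cv, 1, pts)
    if s.min() < grid[0] or s.max() > grid[-1]:
        raise ValidationError("grid does not cover the CV range")
    hist, edges = np.histogram(s, bins=grid, weights=w)
    p = hist / hist.sum()
    with np.errstate(divide="ignore"):
        F = -spec.kT * np.log(p)
    F -= F[np.isfinite(F)].min()
    return FreeEnergySurface(edges=[edges], probabilities=p,
                             free_energy=F, kT=spec.kT)


# ---------------------------------------------------------------------------
# trajectory text I/O (round-trip exact via 17-significant-digit floats)


def write_trajectory(traj: TorsionTrajectory, path) -> None:
    path = Path(path)
    header = (f"loopflex torsion trajectory v1\n"
              f"n_torsions={traj.n_torsions} "
              f"frame_interval={traj.frame_interval!r} "
              f"origin_label={traj.origin_label}")
    np.savetxt(path, traj.angles, fmt="%.17g", header=header)


def read_trajectory(path) -> TorsionTrajectory:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if "loopflex torsion trajectory" not in first:
            raise ValidationError(f"{path} is not a loopflex trajectory file")
        meta = fh.readline().lstrip("# ").strip()
    fields = dict(kv.split("=", 1) for kv in meta.split(" ", 2))
    angles = np.loadtxt(path, ndmin=2)
    return TorsionTrajectory(angles,
                             frame_interval=float(fields["frame_interval"]),
                             origin_label=fields.get("origin_label", ""))
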