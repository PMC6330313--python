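"""Well-tempered metadynamics over 1-2 collective variables.

A history-dependent bias V(s) is built from Gaussians deposited along the
CVs at a fixed stride. In the well-tempered variant the deposited height
decays with the bias already accumulated at the deposition point,

    h = w0 * exp( -V(s) / ((gamma - 1) * kT) ),

with biasfactor gamma > 1, so that the final bias converges to
-(gamma - 1)/gamma * F(s) and the free energy is recovered as

    F(s) = -(gamma / (gamma - 1)) * V(s) + const.

Published parameters for the antibody systems (heights 10.0 or
2.0 kcal/mol, deposition every 1000 steps, biasfactor 10) translate to the
toy engine via KCAL_PER_KT_300K; the toy defaults express heights in kT.

Hills logs round-trip through a HILLS-style delimited text file with one
deposited Gaussian per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .angles import angular_difference, wrap_angle
from .collective_variables import CVDefinition, RawTorsionCV
from .errors import DimensionError, NumericalError, ValidationError
from .toy_dynamics import TorsionTrajectory, ToySystemSpec

__all__ = ["MetadParams", "HillsLog", "bias_value", "bias_gradient",
           "run_wt_metad", "fes_from_hills", "write_hills", "read_hills"]

#: default hill width as a fraction of the CV's reachable range
DEFAULT_SIGMA_FRACTION = 0.1


@dataclass(frozen=True)
class MetadParams:
    """Well-tempered metadynamics parameters (energies in kT)."""

    height: float = 1.2                  # initial Gaussian height w0, kT
    sigmas: Optional[Tuple[float, ...]] = None  # per-CV width; None -> auto
    stride: int = 1000                   # deposition interval in steps
    biasfactor: float = 10.0             # gamma, dimensionless > 1
    kT: float = 1.0

    def __post_init__(self):
        if not self.height > 0:
            raise ValidationError("height must be > 0")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")
        if not self.biasfactor > 1:
            raise ValidationError("biasfactor must be > 1")
        if not self.kT > 0:
            raise ValidationError("kT must be > 0")
        if self.sigmas is not None:
            sig = tuple(float(s) for s in self.sigmas)
            object.__setattr__(self, "sigmas", sig)
            if any(s <= 0 for s in sig):
                raise ValidationError("all sigmas must be > 0")

    def resolve_sigmas(self, cvs: Sequence) -> np.ndarray:
        if self.sigmas is not None:
            if len(self.sigmas) != len(cvs):
                raise DimensionError(
                    f"{len(self.sigmas)} sigmas for {len(cvs)} CVs")
            return np.array(self.sigmas, float)
        return np.array([DEFAULT_SIGMA_FRACTION * cv.value_range
                         for cv in cvs], float)


@dataclass
class HillsLog:
    """Deposited metadynamics Gaussians.

    times are integration-step indices (strictly increasing), centers and
    widths are per-CV, heights are the *actual* (tempered) heights in kT.
    """

    times: np.ndarray
    centers: np.ndarray          # n_hills x n_cv
    widths: np.ndarray           # n_hills x n_cv
    heights: np.ndarray          # n_hills, kT
    biasfactor: float
    cv_labels: Tuple[str, ...] = ()
    periodic: Tuple[bool, ...] = ()

    def __post_init__(self):
        self.times = np.asarray(self.times, float).ravel()
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        self.widths = np.atleast_2d(np.asarray(self.widths, float))
        self.heights = np.asarray(self.heights, float).ravel()
        n = self.times.size
        if not (self.centers.shape[0] == self.widths.shape[0]
                == self.heights.size == n):
            raise ValidationError("inconsistent hills log lengths")
        if n and np.any(np.diff(self.times) <= 0):
            raise ValidationError("hill times must be strictly increasing")
        if np.any(self.heights <= 0):
            raise ValidationError("hill heights must be > 0")
        if not self.periodic:
            self.periodic = (False,) * self.n_cv

    @property
    def n_hills(self) -> int:
        return self.times.size

    @property
    def n_cv(self) -> int:
        return self.centers.shape[1] if self.n_hills else len(self.periodic)


def _hill_terms(hills: HillsLog, s: np.ndarray) -> np.ndarray:
    """Gaussian contribution of every hill at CV point(s) s."""
    diff = s[None, :] - hills.centers            # n_hills x n_cv
    for d, per in enumerate(hills.periodic):
        if per:
            diff[:, d] = angular_difference(diff[:, d], 0.0)
    arg = (diff ** 2 / (2.0 * hills.widths ** 2)).sum(axis=1)
    return hills.heights * np.exp(-arg), diff


def bias_value(hills: HillsLog, s) -> float:
    """Accumulated bias V(s) in kT; 0 for an empty log."""
    s = np.atleast_1d(np.asarray(s, float))
    if hills.n_hills == 0:
        return 0.0
    if s.shape != (hills.n_cv,):
        raise DimensionError(
            f"s has shape {s.shape}, expected ({hills.n_cv},)")
    terms, _ = _hill_terms(hills, s)
    return float(terms.sum())


def bias_gradient(hills: HillsLog, s) -> np.ndarray:
    """dV/ds at a CV point."""
    s = np.atleast_1d(np.asarray(s, float))
    if hills.n_hills == 0:
        return np.zeros_like(s)
    if s.shape != (hills.n_cv,):
        raise DimensionError(
            f"s has shape {s.shape}, expected ({hills.n_cv},)")
    terms, diff = _hill_terms(hills, s)
    return -(terms[:, None] * diff / hills.widths ** 2).sum(axis=0)


def _cv_arrays(cvs: Sequence):
    """Flatten a CV list into the array layout the kernel consumes."""
    kinds, ptr, idx, a, b, periodic = [], [0], [], [], [], []
    for cv in cvs:
        if isinstance(cv, RawTorsionCV):
            kinds.append(1)
            idx.append(cv.index)
            a.append(0.0)
            b.append(0.0)
        elif isinstance(cv, CVDefinition):
            kinds.append(0)
            idx.extend(cv.torsion_indices)
            a.extend(cv.sin_weights)
            b.extend(cv.cos_weights)
        else:
            raise ValidationError(f"unsupported CV type {type(cv)!r}")
        periodic.append(cv.periodic)
        ptr.append(len(idx))
    return (np.array(kinds, np.int64), np.array(ptr, np.int64),
            np.array(idx, np.int64), np.array(a, float), np.array(b, float),
            np.array(periodic, np.bool_))


def run_wt_metad(spec: ToySystemSpec, cvs, params: MetadParams, x0,
                 n_steps: int, save_stride: int = 1,
                 seed: Optional[int] = None
                 ) -> Tuple[TorsionTrajectory, HillsLog]:
    """Run well-tempered metadynamics on the toy landscape.

    Every ``params.stride`` steps a Gaussian of tempered height is
    deposited at the current CV value; between depositions the dynamics is
    the overdamped Langevin integrator with the extra bias force
    -dV/dx = -(dV/ds) (ds/dx). Deterministic for a fixed seed.
    """
    if not isinstance(cvs, (list, tuple)):
        cvs = [cvs]
    if len(cvs) == 0 or len(cvs) > 2:
        raise ValidationError("run_wt_metad supports 1 or 2 CVs")
    if n_steps < params.stride:
        raise ValidationError("n_steps must be >= deposition stride")
    if save_stride < 1:
        raise ValidationError("save_stride must be >= 1")
    x0 = wrap_angle(np.atleast_1d(np.asarray(x0, float)))
    if x0.shape != (spec.n_torsions,):
        raise DimensionError(
            f"x0 has shape {x0.shape}, expected ({spec.n_torsions},)")

    sigmas = params.resolve_sigmas(cvs)
    kinds, ptr, idx, a, b, periodic = _cv_arrays(cvs)
    if idx.size and idx.max() >= spec.n_torsions:
        raise ValidationError("CV indexes torsion beyond the system size")
    centers, depths, widths = spec._well_arrays()
    used_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    noise = rng.standard_normal((n_steps, spec.n_torsions))

    (frames, hill_times, hill_centers, hill_heights, n_hills,
     fail) = _kernels.wtmetad_run(
        centers, depths, widths, spec.kT, spec.friction, spec.dt,
        kinds, ptr, idx, a, b,
        sigmas, periodic, params.height, params.stride, params.biasfactor,
        x0, n_steps, save_stride, noise)
    if fail >= 0:
        raise NumericalError(f"non-finite force at step {fail}")

    traj = TorsionTrajectory(frames, spec.dt * save_stride,
                             origin_label=f"wtmetad-seed{used_seed}")
    hills = HillsLog(times=hill_times,
                     centers=hill_centers,
                     widths=np.tile(sigmas, (n_hills, 1)),
                     heights=hill_heights,
                     biasfactor=params.biasfactor,
                     cv_labels=tuple(getattr(cv, "label", "cv")
                                     for cv in cvs),
                     periodic=tuple(bool(p) for p in periodic))
    return traj, hills


def fes_from_hills(hills: HillsLog, grid, kT: float = 1.0):
    """Free energy on a grid from the final bias.

    Standard well-tempered estimator
    F(s) = -(gamma/(gamma-1)) V_final(s) + const, min-shifted to 0.
    ``grid`` is a 1D array of bin edges (1 CV) or a list of such arrays
    (2 CVs); F is evaluated at bin centers.
    """
    if hills.n_hills == 0:
        raise ValidationError("empty hills log")
    if isinstance(grid, (list, tuple)):
        edges = [np.asarray(g, float) for g in grid]
    else:
        edges = [np.asarray(grid, float)]
    if len(edges) != hills.n_cv:
        raise DimensionError(
            f"{len(edges)} grid dimensions for {hills.n_cv} CVs")
    from .projections import FreeEnergySurface

    centers = [0.5 * (e[:-1] + e[1:]) for e in edges]
    mesh = np.meshgrid(*centers, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    V = np.array([bias_value(hills, p) for p in pts]).reshape(mesh[0].shape)
    scale = hills.biasfactor / (hills.biasfactor - 1.0)
    F = -scale * V
    F -= F.min()
    with np.errstate(over="ignore"):
        p = np.exp(-F / kT)
    p /= p.sum()
    return FreeEnergySurface(edges=edges, probabilities=p, free_energy=F,
                             kT=kT)


# ---------------------------------------------------------------------------
# HILLS-style text I/O


def write_hills(hills: HillsLog, path) -> None:
    path = Path(path)
    n_cv = hills.n_cv
    labels = hills.cv_labels or tuple(f"cv{i}" for i in range(n_cv))
    cols = (["time"] + [f"center_{l}" for l in labels]
            + [f"sigma_{l}" for l in labels] + ["height", "biasfactor"])
    per = " ".join("1" if p else "0" for p in hills.periodic)
    with open(path, "w") as fh:
        fh.write(f"#! FIELDS {' '.join(cols)}\n")
        fh.write(f"#! SET periodic {per}\n")
        for i in range(hills.n_hills):
            row = ([hills.times[i]] + list(hills.centers[i])
                   + list(hills.widths[i]) + [hills.heights[i],
                                              hills.biasfactor])
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_hills(path) -> HillsLog:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#! FIELDS"):
            raise ValidationError(f"{path} is not a hills file")
        fields = header.split()[2:]
        pline = fh.readline()
        periodic = tuple(tok == "1" for tok in pline.split()[3:])
    n_cv = sum(1 for f in fields if f.startswith("center_"))
    labels = tuple(f[len("center_"):] for f in fields
                   if f.startswith("center_"))
    data = np.loadtxt(path, ndmin=2)
    return HillsLog(times=data[:, 0],
                    centers=data[:, 1:1 + n_cv],
                    widths=data[:, 1 + n_cv:1 + 2 * n_cv],
                    heights=data[:, 1 + 2 * n_cv],
                    biasfactor=float(data[0, 2 + 2 * n_cv]),
                    cv_labels=labels,
                    periodic=periodic)
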