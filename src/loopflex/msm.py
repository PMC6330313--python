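"""Markov-state-model estimation and spectral coarse-graining.

From discretized (microstate) trajectories this module estimates, at a
chosen lag time tau:

* sliding-window transition counts,
* the largest set of microstates mutually connected by observed
  transitions in both directions (reversible connectivity),
* the detailed-balance-constrained maximum-likelihood transition matrix
  via the standard fixed-point iteration on unnormalized edge weights,
* implied relaxation timescales t_i = -tau / ln lambda_{i+1} and their
  lag dependence (Markovianity plateau diagnostic),
* a Chapman-Kolmogorov self-consistency test,
* PCCA+ fuzzy coarse-graining into metastable macrostates, with
  stationary macrostate probabilities, directed mean-first-passage
  transition times, and representative frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import NumericalError, ValidationError
from .toy_dynamics import DiscreteTrajectory

__all__ = ["MSMModel", "MacrostateModel", "count_matrix",
           "largest_connected_set", "reversible_mle", "implied_timescales",
           "its_scan", "ck_test", "estimate_msm", "pcca_plus",
           "macrostate_mfpt", "macrostate_representatives"]


@dataclass
class MSMModel:
    """A reversible MSM on the largest connected microstate set."""

    lag: int                       # frames
    frame_interval: float          # physical time per frame
    counts: np.ndarray             # full count matrix
    active_set: np.ndarray         # indices into the full state space
    connected_fraction: float
    T: np.ndarray                  # transition matrix on active set
    pi: np.ndarray                 # stationary distribution
    eigenvalues: np.ndarray        # sorted descending, lambda_1 = 1
    right_eigvecs: np.ndarray
    left_eigvecs: np.ndarray

    @property
    def lag_time(self) -> float:
        return self.lag * self.frame_interval

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def timescales(self, k: Optional[int] = None) -> np.ndarray:
        """Implied timescales in physical time units."""
        ts = implied_timescales(self.T, self.lag, k,
                                eigenvalues=self.eigenvalues)
        return ts * self.frame_interval


@dataclass
class MacrostateModel:
    """PCCA+ macrostates of an MSM."""

    n_macrostates: int
    memberships: np.ndarray        # microstates x macrostates, rows sum 1
    assignment: np.ndarray         # crisp argmax per microstate
    probabilities: np.ndarray      # stationary macrostate probabilities
    spectral_gap: float            # lambda_m / lambda_{m+1}
    mfpt: Optional[np.ndarray] = None          # directed, physical time
    representatives: Optional[np.ndarray] = None  # frame index per macrostate


def _as_state_arrays(dtrajs) -> List[np.ndarray]:
    if isinstance(dtrajs, (DiscreteTrajectory, np.ndarray, list, tuple)) \
            and not isinstance(dtrajs, (list, tuple)):
        dtrajs = [dtrajs]
    elif isinstance(dtrajs, (list, tuple)) and dtrajs and np.isscalar(
            dtrajs[0]):
        dtrajs = [np.asarray(dtrajs)]
    out = []
    for d in dtrajs:
        if isinstance(d, DiscreteTrajectory):
            out.append(d.states)
        else:
            out.append(np.asarray(d, dtype=np.int64).ravel())
    return out


def count_matrix(dtrajs, lag: int,
                 n_states: Optional[int] = None) -> np.ndarray:
    """Sliding-window transition counts C_ij = #{t: s_t=i, s_{t+lag}=j}.

    Counts are summed over trajectories; no cross-trajectory pairs are
    formed. Trajectories shorter than lag + 1 are skipped with a warning.
    """
    if lag < 1:
        raise ValidationError("lag must be >= 1")
    arrays = _as_state_arrays(dtrajs)
    if n_states is None:
        n_states = max((int(a.max()) + 1 for a in arrays if a.size),
                       default=0)
        for d in (dtrajs if isinstance(dtrajs, (list, tuple)) else [dtrajs]):
            if isinstance(d, DiscreteTrajectory):
                n_states = max(n_states, d.n_states)
    C = np.zeros((n_states, n_states))
    used = 0
    for a in arrays:
        if a.size < lag + 1:
            warnings.warn(
                f"trajectory of length {a.size} shorter than lag+1, skipped")
            continue
        np.add.at(C, (a[:-lag], a[lag:]), 1.0)
        used += 1
    if used == 0:
        raise ValidationError("no trajectory long enough for this lag")
    return C


def largest_connected_set(C: np.ndarray) -> Tuple[np.ndarray, float]:
    """Largest set of states mutually connected by reversible transitions.

    States i, j are linked iff C_ij > 0 and C_ji > 0; the returned
    fraction is |set| / n_states.
    """
    C = np.asarray(C, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("count matrix must be square")
    if np.any(C < 0):
        raise ValidationError("count matrix must be non-negative")
    n = C.shape[0]
    mutual = (C > 0) & (C.T > 0)
    np.fill_diagonal(mutual, True)
    _, labels = connected_components(csr_matrix(mutual), directed=False)
    sizes = np.bincount(labels)
    best = int(np.argmax(sizes))
    members = np.flatnonzero(labels == best)
    return members, members.size / n


def reversible_mle(C: np.ndarray, tol: float = 1e-10,
                   max_iter: int = 1_000_000
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Detailed-balance-constrained maximum-likelihood transition matrix.

    Fixed-point iteration on unnormalized symmetric edge weights x_ij:

        x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j),

    with c_i row sums of C and x_i = sum_j x_ij, iterated until the
    maximum relative change of x drops below ``tol``. Returns
    (T, pi) with T_ij = x_ij / x_i and pi proportional to x_i.
    """
    C = np.asarray(C, float)
    n = C.shape[0]
    if n == 0:
        raise ValidationError("empty count matrix")
    Csym = C + C.T
    if np.any((Csym.sum(axis=1) == 0)):
        raise ValidationError("count matrix has an unvisited state")
    c_row = C.sum(axis=1)
    x = Csym / Csym.sum()
    mask = Csym > 0
    for _ in range(max_iter):
        xi = x.sum(axis=1)
        q = c_row / xi
        denom = q[:, None] + q[None, :]
        x_new = np.where(mask, Csym / np.where(denom > 0, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        delta = np.max(np.abs(x_new - x)[mask] / x_new[mask])
        x = x_new
        if delta < tol:
            break
    else:
        raise NumericalError(
            f"reversible MLE did not converge: residual {delta:.3e}")
    xi = x.sum(axis=1)
    T = x / xi[:, None]
    pi = xi / xi.sum()
    # tidy round-off so typed invariants hold exactly-ish
    T = T / T.sum(axis=1, keepdims=True)
    return T, pi


def _reversible_eigensystem(T: np.ndarray, pi: np.ndarray):
    """Real sorted eigen-system via the symmetrized similarity transform."""
    sqrt_pi = np.sqrt(pi)
    S = T * (sqrt_pi[:, None] / sqrt_pi[None, :])
    S = 0.5 * (S + S.T)
    evals, U = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    U = U[:, order]
    right = U / sqrt_pi[:, None]
    left = U * sqrt_pi[:, None]
    # normalize: right[:,0] == 1, left[:,0] == pi
    for j in range(evals.size):
        ref = right[np.argmax(np.abs(right[:, j])), j]
        if ref < 0:
            right[:, j] = -right[:, j]
            left[:, j] = -left[:, j]
    scale = right[0, 0]
    if scale != 0:
        right[:, 0] /= scale
        left[:, 0] *= scale
    return evals, right, left


def implied_timescales(T: np.ndarray, lag: int,
                       k: Optional[int] = None,
                       eigenvalues: Optional[np.ndarray] = None
                       ) -> np.ndarray:
    """Relaxation timescales t_i = -lag / ln lambda_{i+1} (frame units).

    Eigenvalues at (numerically) 1 give infinite timescales; negative or
    complex eigenvalues are skipped with a warning.
    """
    if eigenvalues is None:
        evals = np.linalg.eigvals(np.asarray(T, float))
        real = np.abs(evals.imag) < 1e-10
        if not real.all():
            warnings.warn("complex eigenvalues skipped")
        evals = np.sort(evals[real].real)[::-1]
    else:
        evals = np.asarray(eigenvalues, float)
    sub = evals[1:]
    keep = sub > 0
    if not keep.all():
        warnings.warn("non-positive eigenvalues skipped")
    sub = sub[keep]
    with np.errstate(divide="ignore"):
        ts = np.where(sub >= 1.0, np.inf, -lag / np.log(sub))
    if k is not None:
        ts = ts[:k]
    return ts


def estimate_msm(dtrajs, lag: int, frame_interval: float = 1.0,
                 n_states: Optional[int] = None) -> MSMModel:
    """Full estimation chain: counts -> connectivity -> reversible MLE."""
    C = count_matrix(dtrajs, lag, n_states=n_states)
    active, fraction = largest_connected_set(C)
    if active.size == 0:
        raise ValidationError("no connected states")
    Csub = C[np.ix_(active, active)]
    T, pi = reversible_mle(Csub)
    evals, right, left = _reversible_eigensystem(T, pi)
    return MSMModel(lag=lag, frame_interval=frame_interval, counts=C,
                    active_set=active, connected_fraction=fraction,
                    T=T, pi=pi, eigenvalues=evals,
                    right_eigvecs=right, left_eigvecs=left)


def its_scan(dtrajs, lags: Sequence[int], n_timescales: int = 3,
             frame_interval: float = 1.0) -> pd.DataFrame:
    """Implied timescales as a function of lag (plateau diagnostic)."""
    rows = []
    for lag in lags:
        model = estimate_msm(dtrajs, lag, frame_interval)
        ts = model.timescales(n_timescales)
        row = {"lag": lag, "lag_time": lag * frame_interval}
        for i in range(n_timescales):
            row[f"t{i + 2}"] = ts[i] if i < ts.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def ck_test(dtrajs, lag: int, factors: Sequence[int] = (2, 3, 4, 5)
            ) -> pd.DataFrame:
    """Chapman-Kolmogorov: compare T(k*lag) with T(lag)^k elementwise.

    Both matrices are restricted to the active set of the base-lag model;
    the reported number per k is the maximum absolute element deviation.
    """
    base = estimate_msm(dtrajs, lag)
    rows = []
    for k in factors:
        if k == 1:
            rows.append({"factor": 1, "max_deviation": 0.0})
            continue
        Ck = count_matrix(dtrajs, k * lag, n_states=base.counts.shape[0])
        sub = Ck[np.ix_(base.active_set, base.active_set)]
        Tk, _ = reversible_mle(sub)
        Tpow = np.linalg.matrix_power(base.T, k)
        rows.append({"factor": k,
                     "max_deviation": float(np.max(np.abs(Tk - Tpow)))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCCA+ coarse-graining


def _pi_normalized_eigvecs(T, pi, m):
    evals, right, _ = _reversible_eigensystem(np.asarray(T, float),
                                              np.asarray(pi, float))
    psi = right[:, :m].copy()
    # pi-orthonormality: sum_i pi_i psi_ik psi_il = delta_kl
    for j in range(m):
        norm = np.sqrt(np.sum(pi * psi[:, j] ** 2))
        psi[:, j] /= norm
    psi[:, 0] = 1.0
    return evals, psi


def pcca_plus(T: np.ndarray, pi: np.ndarray,
              n_macrostates: int) -> MacrostateModel:
    """PCCA+ fuzzy assignment of microstates to metastable macrostates.

    The dominant pi-orthonormal right eigenvectors span a simplex whose
    vertices correspond to pure macrostates; the inner-simplex vertex
    construction (most-distant-row initialization) gives the linear map A
    with memberships chi = Psi A, followed by clipping of small negative
    memberships and row renormalization. Crisp states are argmax rows;
    macrostate probabilities sum pi over crisp members.
    """
    T = np.asarray(T, float)
    pi = np.asarray(pi, float)
    n = T.shape[0]
    m = n_macrostates
    if not (2 <= m <= n):
        raise ValidationError(
            f"n_macrostates must be in [2, {n}], got {m}")
    evals, psi = _pi_normalized_eigvecs(T, pi, m)
    if m < n and 0 < evals[m] < 1 and 0 < evals[m - 1] < 1:
        # ratio of relaxation timescales t_m / t_{m+1}: how much slower the
        # slowest resolved process is than the fastest discarded one
        gap = float(np.log(evals[m]) / np.log(evals[m - 1]))
        if gap < 2.0:
            warnings.warn(
                f"weak spectral gap: timescale ratio t_{m}/t_{m + 1} = "
                f"{gap:.3f} (eigenvalues {evals[m - 1]:.4f}, "
                f"{evals[m]:.4f}); macrostate count may be ill-determined")
    else:
        gap = np.inf

    # inner-simplex vertex search (most-distant rows of psi)
    X = psi.copy()
    vertices = np.empty(m, dtype=np.int64)
    vertices[0] = int(np.argmax(np.linalg.norm(X, axis=1)))
    X = X - X[vertices[0]]
    for j in range(1, m):
        c = X[vertices[j - 1]].copy()
        nc = np.linalg.norm(c)
        if nc > 0:
            c /= nc
            X = X - np.outer(X @ c, c)
        vertices[j] = int(np.argmax(np.linalg.norm(X, axis=1)))
    A = np.linalg.inv(psi[vertices])
    chi = psi @ A
    chi = np.clip(chi, 0.0, None)
    rowsum = chi.sum(axis=1)
    dead = rowsum <= 0
    if dead.any():  # pathological: every membership clipped
        chi[dead] = 1.0 / m
        rowsum = chi.sum(axis=1)
    chi /= rowsum[:, None]

    assignment = np.argmax(chi, axis=1).astype(np.int64)
    present = np.unique(assignment)
    if present.size < m:
        warnings.warn("some macrostates received no crisp member")
    probs = np.array([pi[assignment == k].sum() for k in range(m)])
    return MacrostateModel(n_macrostates=m, memberships=chi,
                           assignment=assignment, probabilities=probs,
                           spectral_gap=gap)


def mfpt_to_set(T: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Microstate mean first-passage times (frames) to a target set.

    Solves m_i = 0 for i in the target and m_i = 1 + sum_j T_ij m_j
    otherwise; unreachable targets yield infinite MFPT.
    """
    T = np.asarray(T, float)
    n = T.shape[0]
    target = np.asarray(target, dtype=np.int64)
    m = np.zeros(n)
    others = np.setdiff1d(np.arange(n), target)
    if others.size == 0:
        return m
    A = np.eye(others.size) - T[np.ix_(others, others)]
    b = np.ones(others.size)
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        sol = np.full(others.size, np.inf)
    if np.any(sol < 0):
        sol = np.full(others.size, np.inf)
    m[others] = sol
    return m


def macrostate_mfpt(T: np.ndarray, pi: np.ndarray, assignment: np.ndarray,
                    frame_interval: float = 1.0) -> np.ndarray:
    """Directed macrostate-to-macrostate mean first-passage times.

    MFPT(M -> N) averages the microstate MFPTs to set N over the source
    macrostate, weighted by the stationary distribution restricted to M.
    Diagonal is 0 by definition; physical time units.
    """
    T = np.asarray(T, float)
    pi = np.asarray(pi, float)
    assignment = np.asarray(assignment, dtype=np.int64)
    macros = np.unique(assignment)
    k = int(assignment.max()) + 1
    out = np.zeros((k, k))
    for N in macros:
        target = np.flatnonzero(assignment == N)
        m = mfpt_to_set(T, target)
        for M in macros:
            if M == N:
                continue
            src = np.flatnonzero(assignment == M)
            w = pi[src] / pi[src].sum()
            out[M, N] = float(np.sum(w * m[src])) * frame_interval
    return out


def macrostate_representatives(macro: MacrostateModel,
                               microstate_centers: np.ndarray,
                               frames: np.ndarray,
                               pi: Optional[np.ndarray] = None,
                               frame_microstates: Optional[np.ndarray] = None
                               ) -> np.ndarray:
    """Representative frame per macrostate.

    The representative is the frame closest (in the clustered feature
    space) to the pi-weighted centroid of the macrostate's member
    microstate centers; ties break to the lowest frame index. If
    ``frame_microstates`` is given, candidates are restricted to frames
    assigned to the macrostate's own microstates.
    """
    centers = np.asarray(microstate_centers, float)
    frames = np.atleast_2d(np.asarray(frames, float))
    if pi is None:
        pi = np.full(centers.shape[0], 1.0 / centers.shape[0])
    reps = np.empty(macro.n_macrostates, dtype=np.int64)
    for k in range(macro.n_macrostates):
        members = np.flatnonzero(macro.assignment == k)
        if members.size == 0:
            raise ValidationError(f"macrostate {k} has no crisp member")
        w = pi[members] / pi[members].sum()
        centroid = (w[:, None] * centers[members]).sum(axis=0)
        if frame_microstates is not None:
            cand = np.flatnonzero(np.isin(frame_microstates, members))
        else:
            cand = np.arange(frames.shape[0])
        d = np.linalg.norm(frames[cand] - centroid, axis=1)
        reps[k] = cand[int(np.argmin(d))]
    macro.representatives = reps
    return reps
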