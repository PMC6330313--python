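"""Linear dimensionality reduction and free-energy surfaces.

PCA finds the high-variance linear combinations of the input coordinates;
tICA (time-lagged independent component analysis) finds the
high-*autocorrelation* combinations, i.e. the slowest-relaxing degrees of
freedom, by solving the generalized eigenproblem

    C(tau) v = lambda C(0) v,

with the time-lagged covariance symmetrized (enforcing real eigenvalues
for reversible dynamics) and the instantaneous covariance ridge-
regularized. Free-energy surfaces over 1D/2D projections are obtained as
F = -kT ln p from binned probabilities, min-shifted to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import scipy.linalg
from scipy import ndimage

from .errors import DimensionError, NumericalError, ValidationError

__all__ = ["ProjectionModel", "FreeEnergySurface", "fit_pca", "fit_tica",
           "project", "free_energy_surface", "count_fes_basins"]


@dataclass
class ProjectionModel:
    """A fitted linear projection (PCA or tICA)."""

    kind: str                      # "PCA" | "tICA"
    mean: np.ndarray               # feature mean, length d
    components: np.ndarray         # d x m, columns are components
    eigenvalues: np.ndarray        # length m, sorted descending
    lag: Optional[int] = None      # frames (tICA only)
    explained_variance: Optional[np.ndarray] = None  # fractions (PCA only)

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass
class FreeEnergySurface:
    """Binned probability and free energy over a 1D/2D projection.

    Probabilities are normalized over occupied bins; empty bins carry
    infinite free energy and are excluded from normalization.
    """

    edges: List[np.ndarray]
    probabilities: np.ndarray
    free_energy: np.ndarray       # kT, min-shifted to 0
    kT: float = 1.0

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def bin_centers(self) -> List[np.ndarray]:
        return [0.5 * (e[:-1] + e[1:]) for e in self.edges]

    @property
    def occupied(self) -> np.ndarray:
        return self.probabilities > 0


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    out = components.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_pca(X: np.ndarray, m: Optional[int] = None) -> ProjectionModel:
    """Principal component analysis via covariance eigendecomposition.

    Explained-variance fractions are relative to the total variance, so
    they sum to 1 when m = d.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n, d = X.shape
    if m is None:
        m = d
    if m > d:
        raise ValidationError(f"m={m} exceeds feature dimension {d}")
    if n < 2:
        raise ValidationError("need at least 2 frames")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite input")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return ProjectionModel("PCA", mean, evecs[:, :m], evals[:m],
                           explained_variance=frac[:m])


def fit_tica(X: Union[np.ndarray, Sequence[np.ndarray]], lag: int,
             m: Optional[int] = None, ridge: float = 1e-10
             ) -> ProjectionModel:
    """Time-lagged independent component analysis.

    ``X`` is a single time series (frames x d) or a list of them;
    covariances are pooled per series so no cross-series time pairs are
    formed. The symmetrized estimator

        C0 = <x x^T> over both window ends,
        Ct = (1/2) <x_t x_{t+lag}^T + x_{t+lag} x_t^T>

    yields real eigenvalues in [-1, 1] for reversible data.
    """
    series = [np.atleast_2d(np.asarray(s, float))
              for s in (X if isinstance(X, (list, tuple)) else [X])]
    if lag < 1:
        raise ValidationError("lag must be >= 1")
    usable = [s for s in series if s.shape[0] > lag + 1]
    if not usable:
        raise ValidationError("no series longer than lag + 1 frames")
    d = usable[0].shape[1]
    if m is None:
        m = d
    if m > d:
        raise ValidationError(f"m={m} exceeds feature dimension {d}")
    # pooled mean over both window ends
    total_n = 0
    mean = np.zeros(d)
    for s in usable:
        mean += s[:-lag].sum(axis=0) + s[lag:].sum(axis=0)
        total_n += 2 * (s.shape[0] - lag)
    mean /= total_n
    C0 = np.zeros((d, d))
    Ct = np.zeros((d, d))
    for s in usable:
        a = s[:-lag] - mean
        b = s[lag:] - mean
        C0 += a.T @ a + b.T @ b
        Ct += a.T @ b + b.T @ a
    C0 /= total_n
    Ct /= total_n
    C0r = C0 + ridge * np.eye(d)
    try:
        evals, evecs = scipy.linalg.eigh(Ct, C0r)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericalError(f"singular C(0) after regularization: {exc}")
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = _fix_signs(evecs[:, order])
    return ProjectionModel("tICA", mean, evecs[:, :m], evals[:m], lag=lag)


def project(model: ProjectionModel, X: np.ndarray) -> np.ndarray:
    """Apply the fitted linear map: (X - mean) @ components."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.mean.size:
        raise DimensionError(
            f"feature dimension {X.shape[1]} != model dimension "
            f"{model.mean.size}")
    return (X - model.mean) @ model.components


def free_energy_surface(Y: np.ndarray, bins=60, kT: float = 1.0,
                        ranges=None, pad: float = 0.05) -> FreeEnergySurface:
    """Histogram-based free energy over a 1D/2D projection.

    ``bins`` is an int or per-dimension bin count; the data range is
    padded by ``pad`` (fraction) unless explicit ``ranges`` are given.
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] < 1:
        raise ValidationError("need at least 1 frame")
    ndim = Y.shape[1]
    if ndim > 2:
        raise ValidationError("free-energy surfaces supported in 1D/2D")
    if np.isscalar(bins):
        bins = [int(bins)] * ndim
    if ranges is None:
        ranges = []
        for d in range(ndim):
            lo, hi = Y[:, d].min(), Y[:, d].max()
            width = (hi - lo) or 1.0
            ranges.append((lo - pad * width, hi + pad * width))
    hist, edges = np.histogramdd(Y, bins=bins, range=ranges)
    p = hist / hist.sum()
    with np.errstate(divide="ignore"):
        F = -kT * np.log(p)
    F -= F[np.isfinite(F)].min()
    return FreeEnergySurface(edges=list(edges), probabilities=p,
                             free_energy=F, kT=kT)


def count_fes_basins(fes: FreeEnergySurface, depth_threshold: float = 2.0,
                     smooth_sigma: float = 1.0) -> int:
    """Count local free-energy minima below min + depth_threshold (kT).

    The probability field is Gaussian-smoothed (sigma in bins) before
    minima detection; plateau minima touching each other count once.
    """
    p = ndimage.gaussian_filter(fes.probabilities, sigma=smooth_sigma,
                                mode="nearest")
    with np.errstate(divide="ignore"):
        F = -fes.kT * np.log(p)
    finite = np.isfinite(F)
    if not finite.any():
        return 0
    F = F - F[finite].min()
    is_min = (F == ndimage.minimum_filter(F, size=3, mode="nearest"))
    mask = is_min & finite & (F < depth_threshold)
    _, n_basins = ndimage.label(mask)
    return int(n_basins)
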