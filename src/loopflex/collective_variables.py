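"""Collective variables for biased sampling of loop torsions.

The enhanced-sampling CVs are linear combinations of the sine and cosine
of selected psi torsions,

    s(x) = sum_j [ a_j sin(x_{i_j}) + b_j cos(x_{i_j}) ],

one CV per loop (heavy-chain H3 and light-chain L3 analogues). Such a CV
is smooth, 2*pi-periodic in every torsion and bounded by
sum_j sqrt(a_j^2 + b_j^2), so in CV space it is *not* periodic. A raw
single-torsion CV (periodic in CV space) is also provided for tests and
1D landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError

__all__ = ["CVDefinition", "RawTorsionCV", "cv_value", "cv_gradient",
           "default_loop_cvs"]


@dataclass(frozen=True)
class CVDefinition:
    """Linear sin/cos combination over a subset of torsions."""

    torsion_indices: Tuple[int, ...]
    sin_weights: Tuple[float, ...]
    cos_weights: Tuple[float, ...]
    label: str = "cv"

    #: CVs built from sin/cos are bounded, not periodic, in CV space
    periodic: bool = False

    def __post_init__(self):
        idx = tuple(int(i) for i in self.torsion_indices)
        a = tuple(float(v) for v in self.sin_weights)
        b = tuple(float(v) for v in self.cos_weights)
        object.__setattr__(self, "torsion_indices", idx)
        object.__setattr__(self, "sin_weights", a)
        object.__setattr__(self, "cos_weights", b)
        if not (len(idx) == len(a) == len(b)):
            raise ValidationError(
                "torsion_indices, sin_weights, cos_weights must have "
                "equal lengths")
        if len(idx) == 0:
            raise ValidationError("CV selects no torsions")
        if all(x == 0 for x in a) and all(x == 0 for x in b):
            raise ValidationError("all CV weights are zero")

    @property
    def bound(self) -> float:
        """Upper bound on |s| (Cauchy-Schwarz per torsion)."""
        a = np.array(self.sin_weights)
        b = np.array(self.cos_weights)
        return float(np.sqrt(a ** 2 + b ** 2).sum())

    @property
    def value_range(self) -> float:
        """Width of the reachable CV interval (used for default hill widths)."""
        return 2.0 * self.bound

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, float))
        if max(self.torsion_indices) >= x.shape[-1]:
            raise ValidationError(
                f"CV '{self.label}' indexes torsion "
                f"{max(self.torsion_indices)} but input has {x.shape[-1]}")
        return x

    def value(self, x) -> float:
        x = self._check(x)
        idx = list(self.torsion_indices)
        a = np.array(self.sin_weights)
        b = np.array(self.cos_weights)
        return float(np.sum(a * np.sin(x[..., idx])
                            + b * np.cos(x[..., idx]), axis=-1))

    def values(self, X) -> np.ndarray:
        """Vectorized evaluation over frames (frames x n_torsions)."""
        X = np.atleast_2d(np.asarray(X, float))
        self._check(X[0])
        idx = list(self.torsion_indices)
        a = np.array(self.sin_weights)
        b = np.array(self.cos_weights)
        return np.sum(a * np.sin(X[:, idx]) + b * np.cos(X[:, idx]), axis=1)

    def gradient(self, x) -> np.ndarray:
        x = self._check(x)
        g = np.zeros_like(x)
        for i, a, b in zip(self.torsion_indices, self.sin_weights,
                           self.cos_weights):
            g[i] += a * np.cos(x[i]) - b * np.sin(x[i])
        return g


@dataclass(frozen=True)
class RawTorsionCV:
    """A single torsion used directly as CV (periodic in CV space)."""

    index: int
    label: str = "torsion"
    periodic: bool = True

    @property
    def value_range(self) -> float:
        return 2.0 * np.pi

    def _check(self, x):
        x = np.atleast_1d(np.asarray(x, float))
        if self.index >= x.shape[-1]:
            raise ValidationError(
                f"CV '{self.label}' indexes torsion {self.index} "
                f"but input has {x.shape[-1]}")
        return x

    def value(self, x) -> float:
        return float(self._check(x)[..., self.index])

    def values(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        self._check(X[0])
        return X[:, self.index].copy()

    def gradient(self, x) -> np.ndarray:
        x = self._check(x)
        g = np.zeros_like(x)
        g[self.index] = 1.0
        return g


def cv_value(cv, x) -> float:
    """s(x) for a CV definition; see :class:`CVDefinition`."""
    return cv.value(x)


def cv_gradient(cv, x) -> np.ndarray:
    """ds/dx; nonzero only at the CV's selected torsion indices."""
    return cv.gradient(x)


def default_loop_cvs(n_torsions_h3: int, n_torsions_l3: int = 0,
                     offset_l3: Optional[int] = None
                     ) -> Tuple[CVDefinition, Optional[CVDefinition]]:
    """Default CV pair: unit sin and cos weights on each loop's torsions.

    The first CV covers torsions [0, n_torsions_h3); the second covers the
    L3 block starting at ``offset_l3`` (default: right after H3). With
    ``n_torsions_l3 == 0`` the second CV is absent (None).
    """
    if n_torsions_h3 < 1:
        raise ValidationError("n_torsions_h3 must be >= 1")
    if n_torsions_l3 < 0:
        raise ValidationError("n_torsions_l3 must be >= 0")
    h3 = CVDefinition(tuple(range(n_torsions_h3)),
                      (1.0,) * n_torsions_h3, (1.0,) * n_torsions_h3,
                      label="psi-H3")
    if n_torsions_l3 == 0:
        return h3, None
    start = n_torsions_h3 if offset_l3 is None else offset_l3
    l3 = CVDefinition(tuple(range(start, start + n_torsions_l3)),
                      (1.0,) * n_torsions_l3, (1.0,) * n_torsions_l3,
                      label="psi-L3")
    return h3, l3
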