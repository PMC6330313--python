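"""Periodic-angle helpers.

All torsions in this package live on the circle with the wrap convention
(-pi, pi]. Keeping the convention in one place avoids the classic
off-by-one-branch bugs at exactly +/-pi.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(x):
    """Map angles to the interval (-pi, pi].

    Works elementwise on arrays. The boundary maps -pi -> +pi so the
    interval is half-open on the left.
    """
    x = np.asarray(x, dtype=float)
    return np.pi - np.mod(np.pi - x, TWO_PI)


def angular_difference(a, b):
    """Signed wrapped difference a - b in (-pi, pi], elementwise."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
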