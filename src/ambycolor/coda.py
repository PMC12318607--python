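"""Compositional geometry for the three-part pigmentation simplex.

A pigment composition is the triple of proportions
``(p_black, p_yellow, p_clear)`` of melanophore, xanthophore and
unpigmented pixels in a standard skin patch.  Proportions carry only
relative information and live on the 2-simplex, so the models operate on
two orthonormal isometric log-ratio (ILR) balances instead:

* ``z1`` — chromatophore cover: the geometric mean of the yellow and black
  parts against the clear part,
  ``z1 = sqrt(2/3) * ln( g(p_yellow, p_black) / p_clear )``;
* ``z2`` — melanophore-vs-xanthophore balance,
  ``z2 = sqrt(1/2) * ln( p_black / p_yellow )``.

The normalising constants ``sqrt(rs/(r+s))`` make the pair an isometry:
Aitchison distance on the simplex equals Euclidean distance in (z1, z2).

Part order throughout the package is ``(black, yellow, clear)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "close",
    "ilr_forward",
    "ilr_inverse",
    "aitchison_distance",
    "ternary_coords",
    "TERNARY_VERTICES",
]

# sqrt(2/3) and sqrt(1/2): orthonormal balance constants for a (2,1) and
# (1,1) split of the sequential binary partition {yellow,black | clear},
# {black | yellow}.
_C1 = np.sqrt(2.0 / 3.0)
_C2 = np.sqrt(0.5)


def close(counts, zero_policy: str = "pseudocount", pseudocount: float = 0.5):
    """Close raw (black, yellow, clear) counts to a point on the simplex.

    Parameters
    ----------
    counts : array-like, shape (..., 3)
        Non-negative pixel counts in part order (black, yellow, clear).
    zero_policy : {"pseudocount", "error"}
        How to handle zero counts.  ``"pseudocount"`` adds `pseudocount`
        to every part of any row containing a zero before closure (the
        Bayesian-multiplicative flavour of additive zero replacement);
        ``"error"`` raises on zeros.
    pseudocount : float
        Pseudo-pixels added per part under the pseudocount policy.

    Returns
    -------
    ndarray, shape (..., 3)
        Strictly positive proportions summing to 1.
    """
    x = np.asarray(counts, dtype=float)
    if x.shape[-1] != 3:
        raise ValueError("composition must have 3 parts (black, yellow, clear)")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("composition with zero total cannot be closed")
    has_zero = np.any(x == 0, axis=-1)
    if np.any(has_zero):
        if zero_policy == "pseudocount":
            x = x + np.where(has_zero[..., None], pseudocount, 0.0)
        elif zero_policy == "error":
            raise ValueError("zero count encountered with zero_policy='error'")
        else:
            raise ValueError(f"unknown zero_policy: {zero_policy!r}")
    return x / x.sum(axis=-1, keepdims=True)


def ilr_forward(p):
    """Map simplex points to the two ILR balances (z1, z2).

    `p` has part order (black, yellow, clear) on its last axis and must be
    strictly positive.
    """
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError("expected 3-part compositions")
    if np.any(p <= 0):
        raise ValueError("ILR requires strictly positive parts; close() first")
    b, y, c = p[..., 0], p[..., 1], p[..., 2]
    z1 = _C1 * np.log(np.sqrt(y * b) / c)
    z2 = _C2 * np.log(b / y)
    return np.stack([z1, z2], axis=-1)


def ilr_inverse(z):
    """Invert the balances back to (black, yellow, clear) proportions."""
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != 2:
        raise ValueError("expected (z1, z2) pairs")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite ILR coordinates")
    z1, z2 = z[..., 0], z[..., 1]
    # clr representation from the orthonormal basis vectors
    # v1 = c1*(1/2, 1/2, -1), v2 = c2*(1, -1, 0); closure removes the
    # additive constant, and subtracting the max stabilises exp().
    log_b = 0.5 * _C1 * z1 + _C2 * z2
    log_y = 0.5 * _C1 * z1 - _C2 * z2
    log_c = -_C1 * z1
    logs = np.stack([log_b, log_y, log_c], axis=-1)
    logs -= logs.max(axis=-1, keepdims=True)
    ex = np.exp(logs)
    return ex / ex.sum(axis=-1, keepdims=True)


def aitchison_distance(p, q):
    """Aitchison distance between compositions (equals ILR Euclidean)."""
    zp, zq = ilr_forward(p), ilr_forward(q)
    return np.linalg.norm(zp - zq, axis=-1)


# Equilateral triangle with unit side: black at the apex, yellow at the
# lower-left corner, clear at the lower-right corner.
TERNARY_VERTICES = np.array(
    [[0.5, np.sqrt(3.0) / 2.0], [0.0, 0.0], [1.0, 0.0]]
)


def ternary_coords(p, vertices=None):
    """Barycentric-to-Cartesian coordinates for ternary plotting.

    The default triangle puts 100 % black at the apex, 100 % yellow at the
    lower-left and 100 % clear at the lower-right.
    """
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError("expected 3-part compositions")
    v = TERNARY_VERTICES if vertices is None else np.asarray(vertices, float)
    return p @ v
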