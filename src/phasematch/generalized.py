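"""Generalized coordinates of motion.

A variable in generalized coordinates is represented by the vector of its
successive temporal derivatives ``(x, x', x'', ...)`` truncated at a finite
embedding order ``n``.  This module provides the shift (derivative) operator
acting on such vectors, utilities for embedding analytic signals, truncated
Taylor arithmetic for propagating derivatives through nonlinear sensory
mappings, and the precision structure induced by smooth (Gaussian
autocorrelated) random fluctuations.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "shift_operator",
    "embed_signal",
    "taylor_shift_scale",
    "taylor_sin_cos",
    "taylor_mul",
    "smoothness_covariance",
    "smoothness_precision",
    "generalized_precision",
]


def shift_operator(order: int) -> np.ndarray:
    """Return the derivative (shift) operator ``D`` on generalized vectors.

    ``D @ (v0, v1, ..., v_{n-1}) == (v1, ..., v_{n-1}, 0)``: each order is
    replaced by the next one, and the top order is truncated to zero.

    Parameters
    ----------
    order
        Embedding order ``n`` (number of derivative orders represented).
    """
    if not isinstance(order, (int, np.integer)) or order < 1:
        raise ValueError(f"embedding order must be a positive integer, got {order!r}")
    return np.eye(order, k=1)


def embed_signal(derivatives, order: int) -> np.ndarray:
    """Embed a scalar signal in generalized coordinates from its derivatives.

    Parameters
    ----------
    derivatives
        Sequence of analytic temporal derivatives of the signal at the current
        time, starting at order 0 (the value itself).  At least ``order``
        entries must be supplied; extras are ignored.
    order
        Embedding order of the result.
    """
    d = np.asarray(derivatives, dtype=float).ravel()
    if order < 1:
        raise ValueError(f"embedding order must be positive, got {order}")
    if d.size < order:
        raise ValueError(
            f"need {order} derivative orders, got {d.size}"
        )
    if not np.all(np.isfinite(d[:order])):
        raise ValueError("derivatives must be finite")
    return d[:order].copy()


# ---------------------------------------------------------------------------
# Truncated Taylor arithmetic on derivative vectors.
#
# Internally a derivative vector (v0, v1, ..., v_{n-1}) corresponds to the
# Taylor coefficients c_k = v_k / k!.  Recurrences below are the standard
# power-series ones, translated back to derivative values at the end.

_FACTORIALS = np.array([math.factorial(k) for k in range(33)], dtype=float)


def _to_coeffs(derivs: np.ndarray) -> np.ndarray:
    return derivs / _FACTORIALS[: derivs.size]


def _to_derivs(coeffs: np.ndarray) -> np.ndarray:
    return coeffs * _FACTORIALS[: coeffs.size]


def taylor_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Derivative vector of the product of two signals (Leibniz rule)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size
    ca, cb = _to_coeffs(a), _to_coeffs(b)
    cp = np.zeros(n)
    for k in range(n):
        cp[k] = np.dot(ca[: k + 1], cb[: k + 1][::-1])
    return _to_derivs(cp)


def taylor_sin_cos(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Derivative vectors of ``sin(u(t))`` and ``cos(u(t))``.

    ``u`` is the derivative vector of the phase signal.  Uses the coupled
    series recurrence s' = c u', c' = -s u'.
    """
    u = np.asarray(u, dtype=float)
    n = u.size
    cu = _to_coeffs(u)
    s = np.zeros(n)
    c = np.zeros(n)
    s[0] = math.sin(cu[0])
    c[0] = math.cos(cu[0])
    for k in range(1, n):
        # k*s_k = sum_{j=1..k} j*u_j*c_{k-j};  k*c_k = -sum_{j=1..k} j*u_j*s_{k-j}
        j = np.arange(1, k + 1)
        s[k] = np.dot(j * cu[1 : k + 1], c[k - 1 :: -1][:k]) / k
        c[k] = -np.dot(j * cu[1 : k + 1], s[k - 1 :: -1][:k]) / k
    return _to_derivs(s), _to_derivs(c)


def taylor_jacobian(w: np.ndarray) -> np.ndarray:
    """Jacobian of a series composition with derivative multiplier ``w``.

    If ``s(t) = m(u(t))`` and ``w`` is the derivative vector of ``m'(u(t))``,
    then ``d s^(k) / d u^(j) = C(k, j) * w^(k-j)`` for ``j <= k`` (Leibniz
    rule applied to ``ds = m'(u) du``); the result is the lower-triangular
    matrix of these sensitivities.
    """
    w = np.asarray(w, dtype=float)
    n = w.size
    T = np.zeros((n, n))
    for k in range(n):
        for j in range(k + 1):
            T[k, j] = math.comb(k, j) * w[k - j]
    return T


def taylor_shift_scale(u: np.ndarray, offset: float = 0.0, scale: float = 1.0) -> np.ndarray:
    """Affine map of a derivative vector: ``scale*u + offset`` (offset on order 0)."""
    out = scale * np.asarray(u, dtype=float)
    out[0] += offset
    return out


# ---------------------------------------------------------------------------
# Precision of generalized fluctuations under a Gaussian autocorrelation.

def smoothness_covariance(order: int, smoothness: float) -> np.ndarray:
    """Covariance among derivative orders of a unit-variance smooth process.

    For a stationary process with Gaussian autocorrelation
    ``rho(h) = exp(-h^2 / (2 s^2))`` the covariance between derivative
    orders i and j is ``(-1)^j rho^(i+j)(0)``; odd totals vanish.  ``s`` is
    the temporal correlation length in the integration time unit.
    """
    if smoothness <= 0:
        raise ValueError(f"smoothness must be positive, got {smoothness}")
    # Even derivatives of the Gaussian at 0: rho^(2m)(0) = (-1)^m (2m-1)!! / s^(2m)
    n = order
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            tot = i + j
            if tot % 2:
                continue
            m = tot // 2
            dfact = math.prod(range(1, 2 * m, 2)) if m > 0 else 1  # (2m-1)!!
            rho_d = ((-1) ** m) * dfact / smoothness ** (2 * m)
            V[i, j] = ((-1) ** j) * rho_d
    return V


def smoothness_precision(order: int, smoothness: float) -> np.ndarray:
    """Inverse of :func:`smoothness_covariance` (unit-precision roughness matrix)."""
    return np.linalg.inv(smoothness_covariance(order, smoothness))


def generalized_precision(log_prec: float, order: int, smoothness: float) -> np.ndarray:
    """Precision matrix over generalized orders for one error channel.

    The scalar precision ``exp(log_prec)`` applies at order 0 and is expanded
    over higher orders by the smoothness model of the assumed fluctuations.
    """
    return math.exp(log_prec) * smoothness_precision(order, smoothness)
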