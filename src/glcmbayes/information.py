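"""Discrete and Gaussian information-theoretic primitives.

All discrete quantities (entropy, mutual information, conditional mutual
information) are reported in bits; the Gaussian differential-entropy and
mutual-information formulas are reported in nats, following the usual
convention for the closed-form normal expressions.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "entropy",
    "mutual_information",
    "conditional_mutual_information",
    "gaussian_entropy",
    "gaussian_mi",
    "joint_counts",
]

_NORM_TOL = 1e-6


def entropy(p) -> float:
    """Shannon entropy -sum p*log2(p) of a probability vector, in bits.

    Zero entries contribute nothing (0*log 0 := 0). Raises ``ValueError``
    if *p* has negative entries or does not sum to 1 within 1e-6.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probability vector has negative entries")
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"probability vector sums to {p.sum()!r}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def joint_counts(x, y) -> np.ndarray:
    """Contingency table of two integer state columns (dense, zero-based)."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("state columns differ in length")
    xi, x_inv = np.unique(x, return_inverse=True)
    yi, y_inv = np.unique(y, return_inverse=True)
    counts = np.zeros((xi.size, yi.size))
    np.add.at(counts, (x_inv, y_inv), 1.0)
    return counts


def mutual_information(x, y, pseudo_count: float = 0.0) -> float:
    """Mutual information MI(X;Y) in bits from two discrete state columns.

    The joint frequency table is optionally smoothed by adding
    *pseudo_count* to every cell before normalisation.  Equals
    ``H(X) - H(X|Y)`` up to floating point.
    """
    counts = joint_counts(x, y) + pseudo_count
    return mutual_information_from_joint(counts / counts.sum())


def mutual_information_from_joint(pxy: np.ndarray) -> float:
    """MI in bits from a (normalised) joint probability table."""
    pxy = np.asarray(pxy, dtype=float)
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    ratio = np.ones_like(pxy)
    ratio[mask] = pxy[mask] / (px @ py)[mask]
    return float((pxy[mask] * np.log2(ratio[mask])).sum())


def conditional_mutual_information(x, y, z, pseudo_count: float = 0.0) -> float:
    """Conditional mutual information CMI(X;Y|Z) in bits.

    Computed as sum_z p(z) * MI(X;Y | Z=z) from frequency estimates.
    Non-negative up to smoothing error.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    z = np.asarray(z)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("state columns differ in length")
    n = x.size
    cmi = 0.0
    for zv in np.unique(z):
        sel = z == zv
        counts = joint_counts(x[sel], y[sel]) + pseudo_count
        cmi += (sel.sum() / n) * mutual_information_from_joint(counts / counts.sum())
    return float(cmi)


def _check_pd(c: np.ndarray) -> np.ndarray:
    c = np.atleast_2d(np.asarray(c, dtype=float))
    if c.shape[0] != c.shape[1]:
        raise ValueError("covariance matrix must be square")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    try:
        np.linalg.cholesky(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive-definite") from exc
    return c


def gaussian_entropy(c) -> float:
    """Differential entropy of a multivariate normal, in nats.

    H = (n/2) ln(2*pi*e) + (1/2) ln|C| for an n-dimensional normal with
    covariance C (must be symmetric positive-definite).
    """
    c = _check_pd(c)
    n = c.shape[0]
    _, logdet = np.linalg.slogdet(c)
    return float(0.5 * n * np.log(2 * np.pi * np.e) + 0.5 * logdet)


def gaussian_mi(c_joint, c_x, c_y) -> float:
    """Gaussian mutual information (1/2) ln(|Cx||Cy|/|Cxy|), in nats.

    For a bivariate normal with correlation rho this reduces to
    -(1/2) ln(1 - rho^2).  Raises for non-PD blocks or a (near-)singular
    joint covariance.
    """
    c_joint = _check_pd(c_joint)
    c_x = _check_pd(c_x)
    c_y = _check_pd(c_y)
    det_joint = np.linalg.det(c_joint)
    if det_joint <= 1e-12:
        raise ValueError("joint covariance is singular or nearly singular")
    mi = 0.5 * np.log(np.linalg.det(c_x) * np.linalg.det(c_y) / det_joint)
    return float(max(mi, 0.0))
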