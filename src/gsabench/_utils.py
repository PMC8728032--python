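"""Internal numerical helpers: seeding, Mahalanobis standardisation, and a
vectorised Shapiro-Wilk statistic.

The Shapiro-Wilk code follows the AS R94 approximation (Royston 1995 weights
with the Royston 1992 normalising transformation, valid for 4 <= n <= 2000).
It is implemented here in batched form because the projection-based normality
tests need n SW statistics per sample, repeated over hundreds of Monte-Carlo
null draws; the values agree with ``scipy.stats.shapiro`` (same algorithm) and
are cross-checked against it in the test-suite.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy import stats

from .errors import ParameterError, SingularMatrixError

__all__ = [
    "rng_from",
    "child_seeds",
    "mle_cov",
    "inv_sqrt_psd",
    "standardize",
    "standardize_batch",
    "shapiro_w",
    "sw_z",
]


def rng_from(seed: int, *key: int) -> Generator:
    """Generator for the substream of ``seed`` addressed by ``key``.

    The (seed, key) -> stream map is a pure function, so any replication or
    method in a larger study can be re-run in isolation.
    """
    return default_rng(SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key)))


def child_seeds(seed: int, n: int, *key: int) -> np.ndarray:
    """``n`` independent integer seeds (< 2**31) derived from ``seed``."""
    ss = SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))
    return ss.generate_state(n) % np.uint32(2**31)


def mle_cov(x: np.ndarray) -> np.ndarray:
    """Maximum-likelihood (divisor n) covariance of an n x p matrix."""
    xc = x - x.mean(axis=0)
    return xc.T @ xc / x.shape[0]


def inv_sqrt_psd(s: np.ndarray, n: int | None = None) -> np.ndarray:
    """Symmetric inverse square root of a covariance matrix.

    Eigenvalues below 1e-12 * trace are treated as singular and refused,
    since every downstream test requires a genuinely invertible covariance.
    """
    w, v = np.linalg.eigh(s)
    floor = 1e-12 * np.trace(s)
    if np.min(w) <= floor:
        hint = f" (n={n} <= p={s.shape[0]}?)" if n is not None and n <= s.shape[0] else ""
        raise SingularMatrixError(
            f"sample covariance is numerically singular{hint}; "
            "subset fewer variables or supply more observations"
        )
    return (v * (w**-0.5)) @ v.T


def standardize(x: np.ndarray) -> np.ndarray:
    """Mahalanobis standardisation z_i = S^{-1/2} (x_i - xbar), S the MLE."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    return (x - x.mean(axis=0)) @ inv_sqrt_psd(mle_cov(x), n=n)


def standardize_batch(x: np.ndarray) -> np.ndarray:
    """Standardise a stack of samples of shape (B, n, p) in one shot."""
    n = x.shape[-2]
    xc = x - x.mean(axis=-2, keepdims=True)
    s = np.einsum("...ni,...nj->...ij", xc, xc) / n
    w, v = np.linalg.eigh(s)
    tr = np.trace(s, axis1=-2, axis2=-1)
    if np.any(w.min(axis=-1) <= 1e-12 * tr):
        raise SingularMatrixError("a Monte-Carlo draw produced a singular covariance")
    inv_sqrt = np.einsum("...ik,...k,...jk->...ij", v, w**-0.5, v)
    return np.einsum("...ni,...ij->...nj", xc, inv_sqrt)


@lru_cache(maxsize=128)
def _shapiro_weights(n: int) -> np.ndarray:
    """AS R94 weights a_1..a_n for the Shapiro-Wilk W statistic."""
    if n < 3:
        raise ParameterError("Shapiro-Wilk requires n >= 3")
    m = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    mm = m @ m
    c = m / np.sqrt(mm)
    u = 1.0 / np.sqrt(n)
    if n == 3:
        return np.array([-np.sqrt(0.5), 0.0, np.sqrt(0.5)])
    a_n = (
        c[-1]
        + 0.221157 * u
        - 0.147981 * u**2
        - 2.071190 * u**3
        + 4.434685 * u**4
        - 2.706056 * u**5
    )
    if n <= 5:
        phi = (mm - 2 * m[-1] ** 2) / (1 - 2 * a_n**2)
        a = m / np.sqrt(phi)
        a[-1], a[0] = a_n, -a_n
        return a
    a_n1 = (
        c[-2]
        + 0.042981 * u
        - 0.293762 * u**2
        - 1.752461 * u**3
        + 5.682633 * u**4
        - 3.582633 * u**5
    )
    phi = (mm - 2 * m[-1] ** 2 - 2 * m[-2] ** 2) / (1 - 2 * a_n**2 - 2 * a_n1**2)
    a = m / np.sqrt(phi)
    a[-1], a[0] = a_n, -a_n
    a[-2], a[1] = a_n1, -a_n1
    return a


def shapiro_w(x: np.ndarray) -> np.ndarray:
    """Shapiro-Wilk W along the last axis of ``x`` (any leading batch shape).

    Returns W in (0, 1]; raises DataError-free nan for zero-variance slices
    (callers decide whether that is an error).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    a = _shapiro_weights(n)
    xs = np.sort(x, axis=-1)
    num = (xs @ a) ** 2
    ss = ((xs - xs.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ss > 0, num / ss, np.nan)


def sw_z(w: np.ndarray, n: int) -> np.ndarray:
    """Royston's normalising transformation of W to an approximate N(0,1) z.

    Large z means strong evidence against normality. Valid for 4 <= n <= 2000.
    """
    if n < 4 or n > 2000:
        raise ParameterError(
            f"Shapiro-Wilk normalisation is defined for 4 <= n <= 2000, got n={n}"
        )
    w = np.asarray(w, dtype=float)
    # guard against log(0) for numerically perfect fits
    one_minus_w = np.clip(1.0 - w, 1e-300, None)
    if n <= 11:
        g = -2.273 + 0.459 * n
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sigma = np.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
        return (-np.log(g - np.log(one_minus_w)) - mu) / sigma
    ln = np.log(n)
    mu = -1.5861 - 0.31082 * ln - 0.083751 * ln**2 + 0.0038915 * ln**3
    sigma = np.exp(-0.4803 - 0.082676 * ln + 0.0030302 * ln**2)
    return (np.log(one_minus_w) - mu) / sigma
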