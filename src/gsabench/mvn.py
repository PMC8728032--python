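"""Six multivariate-normality (MVN) goodness-of-fit tests.

Three families are covered:

* distance-based — the Energy test (expected Euclidean distances between the
  standardised sample and a standard normal reference) and the Henze-Zirkler
  test (weighted L2 distance between characteristic functions);
* Shapiro-Wilk extensions — Royston's combination of coordinate-wise SW
  statistics, and the projection-based FA (min over data-driven directions)
  and TN (mean coordinate-wise SW deficiency after Mahalanobis
  standardisation) tests;
* moment-based — Mardia's multivariate skewness and kurtosis.

All statistics are affine invariant (they act on Mahalanobis-standardised
data), which is what justifies Monte-Carlo null distributions drawn from
N(0, I_p). Monte-Carlo p-values use the (b + 1) / (B + 1) convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from ._utils import (
    mle_cov,
    rng_from,
    shapiro_w,
    standardize,
    standardize_batch,
    sw_z,
)
from .errors import DataError, ParameterError

logger = logging.getLogger("gsabench")

MVN_METHODS = ("mardia", "hz", "royston", "fa", "tn", "energy")

__all__ = [
    "MVNTestResult",
    "MVN_METHODS",
    "mardia_test",
    "hz_test",
    "hz_beta",
    "royston_test",
    "fa_test",
    "tn_test",
    "energy_mvn_test",
    "mvn_battery",
]


@dataclass(frozen=True)
class MVNTestResult:
    """Outcome of one MVN test: statistic, p-value and null provenance."""

    method: str
    statistic: float
    p_value: float
    null_method: str
    n_resamples: int = 0
    components: dict = field(default_factory=dict)
    error: str | None = None

    def __post_init__(self):
        if self.error is None and not (0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")


def _as_matrix(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise DataError("sample must be an n x p matrix")
    if not np.isfinite(x).all():
        raise DataError("sample contains non-finite values")
    return x


# ---------------------------------------------------------------------------
# Mardia


def mardia_test(
    x: np.ndarray, alpha: float = 0.05, correction: bool = False
) -> MVNTestResult:
    """Mardia's multivariate skewness/kurtosis test.

    b1p = n^-2 sum_ij m_ij^3 and b2p = n^-1 sum_i m_ii^2 with
    m_ij = (x_i - xbar)' S^-1 (x_j - xbar), S the MLE covariance. The
    skewness statistic n b1p / 6 is referred to chi-square with
    p(p+1)(p+2)/6 df; the kurtosis z compares b2p with p(p+2) on the
    asymptotic scale. With ``correction=True`` both statistics use Mardia's
    exact finite-sample moments instead of the limits, which keeps the
    component tests calibrated at small n.

    The decision rule rejects when *either* component reaches ``alpha``; the
    reported p_value is min(p_skew, p_kurt) and is therefore a decision
    statistic, not a calibrated p-value (its null exceedance rate at alpha is
    about 1 - (1 - alpha)^2).
    """
    x = _as_matrix(x)
    n, p = x.shape
    z = standardize(x)
    m = z @ z.T
    b1 = float((m**3).sum()) / n**2
    b2 = float((np.diag(m) ** 2).sum()) / n

    df_skew = p * (p + 1) * (p + 2) / 6.0
    if correction:
        k = ((p + 1.0) * (n + 1) * (n + 3)) / (n * ((n + 1.0) * (p + 1) - 6))
        skew_stat = n * k * b1 / 6.0
        kurt_mean = p * (p + 2.0) * (n - 1) / (n + 1)
        kurt_var = (
            8.0 * p * (p + 2) * (n - 3) * (n - p - 1) * (n - p + 1)
        ) / ((n + 1.0) ** 2 * (n + 3) * (n + 5))
        z_kurt = (b2 - kurt_mean) / np.sqrt(kurt_var)
    else:
        skew_stat = n * b1 / 6.0
        z_kurt = (b2 - p * (p + 2.0)) / np.sqrt(8.0 * p * (p + 2) / n)

    p_skew = float(stats.chi2.sf(skew_stat, df_skew))
    p_kurt = float(2.0 * stats.norm.sf(abs(z_kurt)))
    p_min = min(p_skew, p_kurt)
    components = {
        "b1p": b1,
        "b2p": b2,
        "skewness_statistic": float(skew_stat),
        "kurtosis_z": float(z_kurt),
        "p_skewness": p_skew,
        "p_kurtosis": p_kurt,
        "alpha": alpha,
        "reject": bool(p_min <= alpha),
        "correction": correction,
    }
    statistic = b1 if p_skew <= p_kurt else b2
    return MVNTestResult(
        method="mardia",
        statistic=float(statistic),
        p_value=p_min,
        null_method="asymptotic",
        components=components,
    )


# ---------------------------------------------------------------------------
# Henze-Zirkler


def hz_beta(n: int, p: int) -> float:
    """Henze-Zirkler smoothing bandwidth beta(n, p)."""
    return float((n * (2 * p + 1) / 4.0) ** (1.0 / (p + 4)) / np.sqrt(2.0))


def _hz_statistic(z: np.ndarray, beta: float) -> float:
    n, p = z.shape[-2], z.shape[-1]
    g = z @ np.swapaxes(z, -1, -2)
    d = np.einsum("...ii->...i", g)
    dij = d[..., :, None] + d[..., None, :] - 2 * g
    term1 = np.exp(-(beta**2) / 2.0 * dij).sum(axis=(-2, -1)) / n**2
    term2 = (
        2.0
        * (1 + beta**2) ** (-p / 2.0)
        * np.exp(-(beta**2) / (2 * (1 + beta**2)) * d).sum(axis=-1)
        / n
    )
    term3 = (1 + 2 * beta**2) ** (-p / 2.0)
    return n * (term1 - term2 + term3)


def hz_test(
    x: np.ndarray,
    null_method: str = "asymptotic",
    n_mc: int = 499,
    seed: int = 0,
) -> MVNTestResult:
    """Henze-Zirkler test: n times the squared weighted L2 distance between
    the empirical characteristic function of the standardised sample and the
    standard normal one.

    The default p-value uses the lognormal approximation to the null
    distribution of the statistic (Henze & Zirkler 1990); a Monte-Carlo null
    is available with ``null_method="monte_carlo"``.
    """
    x = _as_matrix(x)
    n, p = x.shape
    z = standardize(x)
    beta = hz_beta(n, p)
    hz = float(_hz_statistic(z, beta))

    if null_method == "asymptotic":
        b2 = beta**2
        a = 1 + 2 * b2
        wb = (1 + b2) * (1 + 3 * b2)
        mu = 1 - a ** (-p / 2.0) * (1 + p * b2 / a + p * (p + 2) * b2**2 / (2 * a**2))
        si2 = (
            2 * (1 + 4 * b2) ** (-p / 2.0)
            + 2
            * a ** (-float(p))
            * (1 + 2 * p * b2**2 / a**2 + 3 * p * (p + 2) * b2**4 / (4 * a**4))
            - 4
            * wb ** (-p / 2.0)
            * (1 + 3 * p * b2**2 / (2 * wb) + p * (p + 2) * b2**4 / (2 * wb**2))
        )
        pmu = np.log(np.sqrt(mu**4 / (si2 + mu**2)))
        psi = np.sqrt(np.log((si2 + mu**2) / mu**2))
        p_value = float(stats.norm.sf((np.log(hz) - pmu) / psi))
        return MVNTestResult("hz", hz, p_value, "asymptotic", components={"beta": beta})
    if null_method == "monte_carlo":
        null = _mc_null("hz", n, p, n_mc, seed, beta=beta)
        p_value = float((1 + np.sum(null >= hz)) / (n_mc + 1))
        return MVNTestResult(
            "hz", hz, p_value, "monte_carlo", n_resamples=n_mc, components={"beta": beta}
        )
    raise ParameterError(f"unknown null_method {null_method!r}")


# ---------------------------------------------------------------------------
# Royston


def royston_test(x: np.ndarray) -> MVNTestResult:
    """Royston's test: coordinate-wise Shapiro-Wilk statistics, normalised to
    z-scores, combined into an equivalent-chi-square statistic H with
    correlation-adjusted degrees of freedom e in [1, p]."""
    x = _as_matrix(x)
    n, p = x.shape
    if n < 4 or n > 2000:
        raise ParameterError(f"Royston's test requires 4 <= n <= 2000, got n={n}")
    variances = x.var(axis=0)
    tol = 1e-20 * np.maximum(1.0, x.mean(axis=0) ** 2)
    if np.any(variances <= tol):
        bad = np.where(variances <= tol)[0].tolist()
        raise DataError(f"constant column(s) {bad}: degenerate variance")

    w = shapiro_w(x.T)
    z = sw_z(w, n)
    # half-normal folding of the SW evidence into a 1-df chi-square variable
    k = stats.norm.ppf(np.clip(stats.norm.cdf(-z) / 2.0, 1e-300, None)) ** 2

    if p == 1:
        e = 1.0
    else:
        ln = np.log(n)
        u, lam = 0.715, 5.0
        v = 0.21364 + 0.015124 * ln**2 - 0.0018034 * ln**3
        r = np.abs(np.corrcoef(x, rowvar=False))
        c = r**lam * (1 - u * (1 - r) ** u / v)
        mask = ~np.eye(p, dtype=bool)
        cbar = float(c[mask].mean())
        e = p / (1 + (p - 1) * cbar)
        e = float(np.clip(e, 1.0, p))

    h = e * float(np.mean(k))
    p_value = float(stats.chi2.sf(h, e))
    return MVNTestResult(
        "royston",
        h,
        p_value,
        "asymptotic",
        components={"edf": e, "w": w.tolist()},
    )


# ---------------------------------------------------------------------------
# FA / TN (projection-based SW tests) and their Monte-Carlo nulls


def _fa_statistic(z: np.ndarray) -> np.ndarray:
    """min over observation directions of SW applied to the projections.

    ``z`` has shape (..., n, p) and must already be standardised. Directions
    with zero norm are skipped.
    """
    norms = np.linalg.norm(z, axis=-1)
    zero = norms == 0
    if zero.all(axis=-1).any():
        raise DataError("all standardised observations have zero norm")
    if zero.any():
        logger.info("fa: skipping %d zero-norm direction(s)", int(zero.sum()))
    safe = np.where(norms[..., None] > 0, z / np.where(norms[..., None] == 0, 1, norms[..., None]), 0.0)
    # proj[..., i, k] = z_k . d_i  (projection of every observation onto d_i)
    proj = np.einsum("...ip,...kp->...ik", safe, z)
    w = shapiro_w(proj)  # SW over the last (observation) axis per direction
    w = np.where(zero, np.inf, w)  # skipped directions never attain the min
    return w.min(axis=-1)


def _tn_statistic(z: np.ndarray) -> np.ndarray:
    """T = mean_j (1 - W_j) over the p standardised coordinates."""
    w = shapiro_w(np.swapaxes(z, -1, -2))
    return (1.0 - w).mean(axis=-1)


def _energy_statistic(z: np.ndarray) -> np.ndarray:
    """One-sample energy distance between standardised data and N(0, I_p)."""
    n, p = z.shape[-2], z.shape[-1]
    ezz = 2.0 * np.exp(special.gammaln((p + 1) / 2.0) - special.gammaln(p / 2.0))
    r2 = (z**2).sum(axis=-1)
    # E||a - Z|| = E||Z|| * 1F1(-1/2; p/2; -||a||^2 / 2), E||Z|| = ezz/sqrt(2)
    eaz = (ezz / np.sqrt(2.0)) * special.hyp1f1(-0.5, p / 2.0, -r2 / 2.0)
    g = z @ np.swapaxes(z, -1, -2)
    d = np.einsum("...ii->...i", g)
    sq = np.clip(d[..., :, None] + d[..., None, :] - 2 * g, 0.0, None)
    mean_pair = np.sqrt(sq).sum(axis=(-2, -1)) / n**2
    return n * (2.0 * eaz.mean(axis=-1) - ezz - mean_pair)


_STAT_FNS = {
    "fa": _fa_statistic,
    "tn": _tn_statistic,
    "energy": _energy_statistic,
}


def _mc_null(
    method: str, n: int, p: int, n_mc: int, seed: int, beta: float | None = None,
    chunk: int = 250,
) -> np.ndarray:
    """Null statistics from standardised N(0, I_p) samples, batched."""
    rng = rng_from(seed, 7000 + MVN_METHODS.index(method) if method in MVN_METHODS else 7999)
    out = np.empty(n_mc, dtype=float)
    done = 0
    while done < n_mc:
        b = min(chunk, n_mc - done)
        z = standardize_batch(rng.standard_normal((b, n, p)))
        if method == "hz":
            out[done : done + b] = _hz_statistic(z, beta)
        else:
            out[done : done + b] = _STAT_FNS[method](z)
        done += b
    return out


def fa_test(x: np.ndarray, n_mc: int = 499, seed: int = 0) -> MVNTestResult:
    """FA projection test: standardise, project onto every observation's own
    direction, take the minimum Shapiro-Wilk W over directions. Small W is
    evidence against normality; the p-value is Monte-Carlo under N(0, I_p)
    (valid by affine invariance)."""
    x = _as_matrix(x)
    n, p = x.shape
    z = standardize(x)
    statistic = float(_fa_statistic(z[None])[0])
    null = _mc_null("fa", n, p, n_mc, seed)
    p_value = float((1 + np.sum(null <= statistic)) / (n_mc + 1))
    return MVNTestResult("fa", statistic, p_value, "monte_carlo", n_resamples=n_mc)


def tn_test(x: np.ndarray, n_mc: int = 499, seed: int = 0) -> MVNTestResult:
    """TN test: mean Shapiro-Wilk deficiency (1 - W) across the p coordinates
    of the standardised sample, with a Monte-Carlo null. Large T rejects."""
    x = _as_matrix(x)
    n, p = x.shape
    z = standardize(x)
    statistic = float(_tn_statistic(z[None])[0])
    null = _mc_null("tn", n, p, n_mc, seed)
    p_value = float((1 + np.sum(null >= statistic)) / (n_mc + 1))
    return MVNTestResult("tn", statistic, p_value, "monte_carlo", n_resamples=n_mc)


def energy_mvn_test(x: np.ndarray, n_boot: int = 499, seed: int = 0) -> MVNTestResult:
    """One-sample energy test of multivariate normality.

    E = n [ (2/n) sum_i E||y_i - Z|| - E||Z - Z'|| - n^-2 sum_ij ||y_i - y_j|| ]
    with Z, Z' iid N(0, I_p) and y the standardised sample;
    E||Z - Z'|| = 2 Gamma((p+1)/2) / Gamma(p/2) and E||a - Z|| is evaluated
    through the confluent-hypergeometric closed form in ||a||^2. The p-value
    is a parametric bootstrap: resample N(0, I_p), re-standardise, recompute.
    """
    x = _as_matrix(x)
    n, p = x.shape
    z = standardize(x)
    statistic = float(_energy_statistic(z[None])[0])
    null = _mc_null("energy", n, p, n_boot, seed)
    p_value = float((1 + np.sum(null >= statistic)) / (n_boot + 1))
    return MVNTestResult(
        "energy", statistic, p_value, "parametric_bootstrap", n_resamples=n_boot
    )


# ---------------------------------------------------------------------------
# Battery


def mvn_battery(
    x: np.ndarray,
    alpha: float = 0.05,
    n_mc: int = 499,
    seed: int = 0,
    methods: tuple[str, ...] | None = None,
    hz_null: str = "asymptotic",
    mardia_correction: bool = False,
) -> list[MVNTestResult]:
    """Run the six MVN tests on one sample, in the stable order
    (mardia, hz, royston, fa, tn, energy), sharing one seed stream.

    An individual test failure is recorded in that test's result (statistic
    and p-value NaN, ``error`` set) without aborting the battery.
    """
    methods = tuple(methods) if methods else MVN_METHODS
    unknown = set(methods) - set(MVN_METHODS)
    if unknown:
        raise ParameterError(f"unknown MVN method(s): {sorted(unknown)}")
    results: list[MVNTestResult] = []
    for method in MVN_METHODS:
        if method not in methods:
            continue
        try:
            if method == "mardia":
                res = mardia_test(x, alpha=alpha, correction=mardia_correction)
            elif method == "hz":
                res = hz_test(x, null_method=hz_null, n_mc=n_mc, seed=seed)
            elif method == "royston":
                res = royston_test(x)
            elif method == "fa":
                res = fa_test(x, n_mc=n_mc, seed=seed)
            elif method == "tn":
                res = tn_test(x, n_mc=n_mc, seed=seed)
            else:
                res = energy_mvn_test(x, n_boot=n_mc, seed=seed)
        except (DataError, ParameterError, np.linalg.LinAlgError) as exc:
            logger.warning("MVN battery: %s failed: %s", method, exc)
            res = MVNTestResult(
                method, float("nan"), float("nan"), "failed", error=str(exc)
            )
        results.append(res)
    return results
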