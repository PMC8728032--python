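"""The two study protocols and the distance-from-normality table.

* The gene-subset rejection-rate protocol: repeatedly draw a small random
  subset of a gene set (5 genes for cohorts of at most 30 samples, 10 above
  that), apply an MVN test, and report the rejection rate
  Q = #{p_i <= alpha} / n_reps. Under genuinely multivariate-normal data Q
  sits near alpha; large Q is evidence against joint normality.

* The type-I-error / power study: for each study design (A..H) and each mean
  shift delta, estimate each GSA test's rejection rate over independent
  replications. delta = 0 rows estimate the type-I error.

* The kNN Kullback-Leibler divergence estimator and the per-design
  KL(case || N(0, I)) + KL(control || N(0, I)) summary.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._utils import child_seeds
from .datagen import generate_setting, make_setting, sample_mixture
from .datasets import ExpressionDataset, KLResult, RejectionSummary, TwoGroupDataset
from .errors import DataError, ParameterError
from .gsa import (
    GSA_METHODS,
    global_test,
    gsea_test,
    hotelling_test,
    ks_mean_test,
    ks_var_test,
    n_statistic_test,
    pscore_test,
    roast_test,
)
from .mvn import (
    MVN_METHODS,
    energy_mvn_test,
    fa_test,
    hz_test,
    mardia_test,
    royston_test,
    tn_test,
)

logger = logging.getLogger("gsabench")

__all__ = [
    "subset_size_rule",
    "q_rejection_rate",
    "power_study",
    "mvn_calibration_study",
    "kl_divergence_knn",
    "kl_table",
    "run_gsa_method",
    "run_mvn_method",
]


def subset_size_rule(n_samples: int) -> int:
    """Gene-subset size for the rejection-rate protocol: 10 genes when the
    cohort exceeds 30 samples, else 5 (keeps the sample covariance
    invertible)."""
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    return 10 if n_samples > 30 else 5


def run_mvn_method(
    method: str, x: np.ndarray, n_mc: int = 199, seed: int = 0
) -> float:
    """Dispatch one MVN test by name; returns its p-value."""
    if method == "mardia":
        return mardia_test(x).p_value
    if method == "hz":
        return hz_test(x).p_value
    if method == "royston":
        return royston_test(x).p_value
    if method == "fa":
        return fa_test(x, n_mc=n_mc, seed=seed).p_value
    if method == "tn":
        return tn_test(x, n_mc=n_mc, seed=seed).p_value
    if method == "energy":
        return energy_mvn_test(x, n_boot=n_mc, seed=seed).p_value
    raise ParameterError(f"unknown MVN method {method!r}")


def run_gsa_method(
    method: str, data: TwoGroupDataset, n_resamples: int = 199, seed: int = 0
) -> float:
    """Dispatch one GSA test by name; returns its p-value."""
    if method == "global":
        return global_test(data, n_perm=n_resamples, seed=seed).p_value
    if method == "hotelling":
        return hotelling_test(data, n_perm=n_resamples, seed=seed).p_value
    if method == "roast":
        return roast_test(data, n_rot=n_resamples, seed=seed).p_value
    if method == "pscore":
        return pscore_test(data, seed=seed).p_value
    if method == "gsea":
        return gsea_test(data, n_perm=n_resamples, seed=seed).p_value
    if method == "nstat":
        return n_statistic_test(data, n_perm=n_resamples, seed=seed).p_value
    if method == "ks_mean":
        return ks_mean_test(data, n_perm=n_resamples, seed=seed).p_value
    if method == "ks_var":
        return ks_var_test(data, n_perm=n_resamples, seed=seed).p_value
    raise ParameterError(f"unknown GSA method {method!r}")


def q_rejection_rate(
    expr: ExpressionDataset,
    set_name: str,
    test: str | Callable[[np.ndarray, int], float],
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    n_mc: int = 199,
) -> RejectionSummary:
    """Gene-subset rejection-rate protocol for one gene set and one MVN test.

    Each replication samples ``subset_size`` genes from the set without
    replacement, runs the test on the samples x subset matrix and records its
    p-value; Q is the fraction at or below ``alpha``. Replications whose test
    fails (singular covariance) contribute NaN and are excluded from the
    denominator, with the exclusion count reported.

    ``test`` is an MVN method name or a callable ``(matrix, seed) -> p``.
    """
    genes = expr.resolve_set(set_name)
    n_samples = expr.n_samples
    size = subset_size_rule(n_samples)
    if len(genes) < size:
        raise DataError(
            f"gene set {set_name!r} resolves to {len(genes)} genes, "
            f"fewer than the subset size {size}"
        )
    if n_samples <= size + 1:
        raise DataError(
            f"{n_samples} samples cannot support {size}-gene subsets "
            "(covariance would be singular)"
        )
    test_fn: Callable[[np.ndarray, int], float]
    if callable(test):
        test_fn, method_name = test, getattr(test, "__name__", "custom")
    else:
        method_name = str(test)
        if method_name not in MVN_METHODS:
            raise ParameterError(f"unknown MVN method {method_name!r}")
        test_fn = lambda m, s: run_mvn_method(method_name, m, n_mc=n_mc, seed=s)

    seeds = child_seeds(seed, 2 * n_reps)
    full = expr.subset_matrix(genes)  # samples x set genes, densified once
    gene_pos = np.arange(len(genes))
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(seeds[2 * r])
        cols = rng.choice(gene_pos, size=size, replace=False)
        try:
            pvals[r] = test_fn(full[:, cols], int(seeds[2 * r + 1]))
        except (DataError, np.linalg.LinAlgError) as exc:
            logger.warning("q protocol replication %d failed: %s", r, exc)
            pvals[r] = np.nan
    ok = ~np.isnan(pvals)
    n_excluded = int((~ok).sum())
    if ok.sum() == 0:
        raise DataError("every protocol replication failed")
    q = float(np.sum(pvals[ok] <= alpha) / ok.sum())
    return RejectionSummary(
        method=method_name,
        q=q,
        n_reps=int(ok.sum()),
        alpha=alpha,
        subset_size=size,
        seed=seed,
        n_excluded=n_excluded,
    )


def power_study(
    settings: Sequence[str],
    deltas: Sequence[float],
    methods: Sequence[str] | None = None,
    n_reps: int = 1000,
    n_resamples: int = 199,
    n_per_group: int = 50,
    p: int = 30,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate type-I error (delta = 0) and power for GSA tests on a
    settings x deltas grid.

    Within each (setting, delta) cell every replication generates one
    two-group dataset and runs *all* requested methods on it (shared data,
    independent resampling streams), as in a paired benchmark design. The
    result is a long-format table with columns setting, delta, method, power,
    n_reps, n_failed, mc_se; it is an exact function of (seed, parameters).
    """
    methods = list(methods) if methods else list(GSA_METHODS)
    unknown = set(methods) - set(GSA_METHODS)
    if unknown:
        raise ParameterError(f"unknown GSA method(s): {sorted(unknown)}")
    rows = []
    for si, setting in enumerate(settings):
        for di, delta in enumerate(deltas):
            seeds = child_seeds(seed, n_reps * (len(methods) + 1), si, di)
            rejections = {m: 0 for m in methods}
            failures = {m: 0 for m in methods}
            for r in range(n_reps):
                block = seeds[r * (len(methods) + 1) : (r + 1) * (len(methods) + 1)]
                data = generate_setting(
                    setting, delta, n_per_group=n_per_group, p=p, seed=int(block[0])
                )
                for mi, method in enumerate(methods):
                    try:
                        pv = run_gsa_method(
                            method, data, n_resamples=n_resamples, seed=int(block[mi + 1])
                        )
                    except (DataError, np.linalg.LinAlgError) as exc:
                        logger.warning(
                            "power cell (%s, %.2f) rep %d: %s failed: %s",
                            setting, delta, r, method, exc,
                        )
                        failures[method] += 1
                        continue
                    rejections[method] += pv <= alpha
            for method in methods:
                n_ok = n_reps - failures[method]
                power = rejections[method] / n_ok if n_ok else np.nan
                rows.append(
                    {
                        "setting": str(setting).upper(),
                        "delta": float(delta),
                        "method": method,
                        "power": power,
                        "n_reps": n_ok,
                        "n_failed": failures[method],
                        "mc_se": float(np.sqrt(power * (1 - power) / n_ok))
                        if n_ok
                        else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def mvn_calibration_study(
    n_reps: int = 1000,
    n: int = 50,
    p: int = 10,
    alpha: float = 0.05,
    n_mc: int = 199,
    seed: int = 0,
    methods: Sequence[str] | None = None,
) -> pd.Series:
    """Null rejection rate Q of each MVN test on independent N(0, I_p)
    samples of size n — the rejection-rate protocol under a true null."""
    methods = list(methods) if methods else list(MVN_METHODS)
    unknown = set(methods) - set(MVN_METHODS)
    if unknown:
        raise ParameterError(f"unknown MVN method(s): {sorted(unknown)}")
    seeds = child_seeds(seed, n_reps * (len(methods) + 1))
    rejections = {m: 0 for m in methods}
    for r in range(n_reps):
        block = seeds[r * (len(methods) + 1) : (r + 1) * (len(methods) + 1)]
        x = np.random.default_rng(block[0]).standard_normal((n, p))
        for mi, method in enumerate(methods):
            pv = run_mvn_method(method, x, n_mc=n_mc, seed=int(block[mi + 1]))
            rejections[method] += pv <= alpha
    return pd.Series({m: rejections[m] / n_reps for m in methods}, name="Q")


# ---------------------------------------------------------------------------
# Kullback-Leibler divergence


def kl_divergence_knn(
    sample_p: np.ndarray, sample_q: np.ndarray, k: int = 5
) -> float:
    """k-nearest-neighbour estimator of KL(P || Q) from two samples.

    (p / n) sum_i log(nu_k(i) / rho_k(i)) + log(m / (n - 1)), with rho_k the
    k-th NN distance of each P point within sample_p (self excluded) and
    nu_k its k-th NN distance into sample_q. Finite-sample estimates can be
    negative. Points of sample_q at exactly zero distance from a query point
    are treated as self-matches and skipped (logged), which keeps the
    estimator finite when the two samples share points.
    """
    from sklearn.neighbors import NearestNeighbors

    sample_p = np.atleast_2d(np.asarray(sample_p, dtype=float))
    sample_q = np.atleast_2d(np.asarray(sample_q, dtype=float))
    if sample_p.shape[1] != sample_q.shape[1]:
        raise ParameterError("samples must share a common dimension")
    n, dim = sample_p.shape
    m = sample_q.shape[0]
    if k < 1 or k >= n or k >= m:
        raise ParameterError(f"need 1 <= k < both sample sizes, got k={k}")

    algo = "brute" if dim > 15 else "auto"
    nn_p = NearestNeighbors(n_neighbors=k + 1, algorithm=algo).fit(sample_p)
    rho = nn_p.kneighbors(sample_p)[0][:, k]  # self is the 0-distance first hit
    # query one extra neighbour so exact coincidences can be skipped
    extra = min(k + 1, m)
    nn_q = NearestNeighbors(n_neighbors=extra, algorithm=algo).fit(sample_q)
    dq = nn_q.kneighbors(sample_p)[0]
    coincident = dq[:, 0] == 0.0
    if coincident.any():
        logger.info(
            "kl_divergence_knn: %d query point(s) coincide with sample_q points; "
            "treated as self-matches",
            int(coincident.sum()),
        )
    nu = np.where(coincident, dq[:, min(k, extra - 1)], dq[:, k - 1])

    eps = np.finfo(float).tiny
    if np.any(rho <= 0) or np.any(nu <= 0):
        logger.info("kl_divergence_knn: zero NN distances floored to epsilon")
    rho = np.clip(rho, eps, None)
    nu = np.clip(nu, eps, None)
    return float(dim * np.mean(np.log(nu / rho)) + np.log(m / (n - 1.0)))


def kl_table(
    settings: Iterable[str],
    delta_used: float = 0.5,
    n_used: int = 10000,
    k: int = 5,
    seed: int = 0,
) -> list[KLResult]:
    """Distance-from-normality summary per study design: the sum of the
    estimated KL divergences of the case and control generating distributions
    from the p-dimensional standard normal N(0, I).

    The mean shift and estimation sample size are free parameters of this
    summary (defaults: the grid midpoint delta = 0.5 and n = 10000 draws).
    """
    out = []
    for si, sid in enumerate(settings):
        spec = make_setting(sid, delta_used)
        seeds = child_seeds(seed, 4, si)
        case = sample_mixture(list(spec.case), n_used, int(seeds[0]))
        control = sample_mixture(list(spec.control), n_used, int(seeds[1]))
        ref_rng = np.random.default_rng(seeds[2])
        ref1 = ref_rng.standard_normal((n_used, spec.p))
        ref2 = np.random.default_rng(seeds[3]).standard_normal((n_used, spec.p))
        kl_case = kl_divergence_knn(case, ref1, k=k)
        kl_control = kl_divergence_knn(control, ref2, k=k)
        out.append(
            KLResult(
                setting_id=spec.setting_id,
                delta_used=delta_used,
                n_used=n_used,
                k_neighbors=k,
                kl_sum=kl_case + kl_control,
                kl_case=kl_case,
                kl_control=kl_control,
            )
        )
    return out
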