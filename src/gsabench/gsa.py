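"""Eight self-contained functional-class-scoring (FCS) gene-set tests.

Each test asks whether the genes of one set, taken jointly, associate with a
binary phenotype. Four are parametric — the random-effects global test,
Hotelling's T2, a rotation test with empirical-Bayes moderated t statistics,
and a pathway-activity-score logistic regression — and four nonparametric —
a self-contained sum-of-t enrichment test, the two-sample energy N-statistic,
and two minimum-spanning-tree Kolmogorov-Smirnov tests (location and scale).

Resampling nulls permute sample labels (or rotate the residual space); all
Monte-Carlo p-values use the (b + 1) / (B + 1) convention, and every
permutation test supports exhaustive enumeration (``n_perm="exact"``) when
the group sizes make it affordable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import special, stats
from scipy.spatial.distance import pdist, squareform

from ._utils import rng_from
from .datasets import TwoGroupDataset
from .errors import DataError, ParameterError

logger = logging.getLogger("gsabench")

GSA_METHODS = (
    "global",
    "hotelling",
    "roast",
    "pscore",
    "gsea",
    "nstat",
    "ks_mean",
    "ks_var",
)

__all__ = [
    "GSATestResult",
    "GSA_METHODS",
    "global_test",
    "hotelling_test",
    "roast_test",
    "pscore_test",
    "gsea_test",
    "n_statistic_test",
    "mst_hdp_ranks",
    "euclidean_mst_edges",
    "ks_mean_test",
    "ks_var_test",
]


@dataclass(frozen=True)
class GSATestResult:
    """Outcome of one gene-set association test."""

    method: str
    statistic: float
    p_value: float
    null_method: str
    n_resamples: int = 0
    seed: int = 0
    note: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# permutation machinery


def _case_indicators(
    n: int, n2: int, n_perm, rng
) -> tuple[np.ndarray, bool]:
    """(B, n) boolean case-membership indicators for permuted labels.

    With ``n_perm="exact"`` all C(n, n2) assignments are enumerated (the
    identity among them) and p-values are exact proportions; otherwise B
    uniformly random assignments are drawn and the +1 convention applies.
    """
    if n_perm == "exact":
        total = math.comb(n, n2)
        if total > 200_000:
            raise ParameterError(
                f"exact enumeration of {total} label assignments is not affordable"
            )
        out = np.zeros((total, n), dtype=bool)
        for b, idx in enumerate(combinations(range(n), n2)):
            out[b, list(idx)] = True
        return out, True
    n_perm = int(n_perm)
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    out = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(out, order[:, :n2], True, axis=1)
    return out, False


def _resampling_p(obs: float, null: np.ndarray, exact: bool) -> float:
    """Upper-tail resampling p-value (caller pre-transforms for two-sided)."""
    hits = int(np.sum(null >= obs - 1e-12))
    if exact:
        return hits / null.size
    return (1 + hits) / (null.size + 1)


def _check_groups(data: TwoGroupDataset):
    if data.n1 < 1 or data.n2 < 1:
        raise DataError("both groups must be non-empty")


# ---------------------------------------------------------------------------
# global test


def global_test(
    data: TwoGroupDataset, n_perm: int | str = 999, seed: int = 0
) -> GSATestResult:
    """Random-effects global test for heterogeneity of gene effects.

    With Y the 0/1 label vector and X the column-centred samples x genes
    matrix, Q = (Y - ybar)' X X' (Y - ybar) / m. The null is label
    permutation.
    """
    _check_groups(data)
    x, y = data.pooled()
    m = x.shape[1]
    xc = x - x.mean(axis=0)
    k = xc @ xc.T
    n, n2 = y.size, int(y.sum())

    def stat(ind: np.ndarray) -> np.ndarray:
        yc = ind.astype(float) - n2 / n
        return np.einsum("bi,ij,bj->b", yc, k, yc) / m

    obs = float(stat(y.astype(bool)[None])[0])
    rng = rng_from(seed, 0)
    ind, exact = _case_indicators(n, n2, n_perm, rng)
    null = stat(ind)
    p = _resampling_p(obs, null, exact)
    return GSATestResult(
        "global", obs, p, "permutation", n_resamples=null.size, seed=seed
    )


# ---------------------------------------------------------------------------
# Hotelling


def hotelling_test(
    data: TwoGroupDataset,
    shrinkage: bool | None = None,
    n_perm: int | str = 999,
    seed: int = 0,
) -> GSATestResult:
    """Hotelling's T2 comparison of the two group mean vectors.

    Classical path (default whenever n1 + n2 - 2 > p): pooled covariance and
    the exact F reference T2 (n1+n2-p-1)/((n1+n2-2) p) ~ F(p, n1+n2-p-1).
    Shrinkage path (small samples / p >= n): Ledoit-Wolf shrunk pooled
    covariance with a label-permutation p-value.
    """
    _check_groups(data)
    n1, n2, p = data.n1, data.n2, data.p
    d = n1 + n2 - 2
    if shrinkage is None:
        shrinkage = d <= p

    def t2_classical(xc: np.ndarray, xt: np.ndarray) -> float:
        diff = xc.mean(axis=0) - xt.mean(axis=0)
        sp = ((xc - xc.mean(0)).T @ (xc - xc.mean(0)) + (xt - xt.mean(0)).T @ (xt - xt.mean(0))) / d
        try:
            sol = np.linalg.solve(sp, diff)
        except np.linalg.LinAlgError as exc:
            raise DataError(
                "pooled covariance is singular; use shrinkage=True"
            ) from exc
        return float(n1 * n2 / (n1 + n2) * diff @ sol)

    if not shrinkage:
        if d <= p:
            raise DataError(
                f"classical Hotelling needs n1+n2-2 > p (got {d} <= {p}); "
                "use shrinkage=True"
            )
        t2 = t2_classical(data.x_control, data.x_case)
        f = t2 * (n1 + n2 - p - 1) / (d * p)
        p_value = float(stats.f.sf(f, p, n1 + n2 - p - 1))
        return GSATestResult("hotelling", t2, p_value, "analytic_f", seed=seed)

    from sklearn.covariance import LedoitWolf

    x, y = data.pooled()

    def t2_shrunk(ind: np.ndarray) -> float:
        g1, g2 = x[~ind], x[ind]
        diff = g1.mean(axis=0) - g2.mean(axis=0)
        resid = np.vstack([g1 - g1.mean(0), g2 - g2.mean(0)])
        cov = LedoitWolf(assume_centered=True).fit(resid).covariance_
        sol = np.linalg.solve(cov, diff)
        return float(g1.shape[0] * g2.shape[0] / (n1 + n2) * diff @ sol)

    obs = t2_shrunk(y.astype(bool))
    rng = rng_from(seed, 0)
    ind, exact = _case_indicators(n1 + n2, n2, n_perm, rng)
    null = np.array([t2_shrunk(row) for row in ind])
    p_value = _resampling_p(obs, null, exact)
    return GSATestResult(
        "hotelling", obs, p_value, "permutation", n_resamples=null.size, seed=seed,
        note="ledoit-wolf shrinkage",
    )


# ---------------------------------------------------------------------------
# rotation test with moderated t (ROAST-style)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, as in the moderated-t
    literature's F-distribution moment fit)."""
    if y <= 0:
        raise ParameterError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment fit of a scaled F distribution to gene-level variances.

    Returns (d0, s0_squared): the prior degrees of freedom and prior variance
    of the empirical-Bayes shrinkage. d0 = inf means complete shrinkage to
    the common value s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 <= 0):
        raise DataError("non-positive gene variance; cannot fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    if s2.size < 2:
        return np.inf, float(np.exp(emean))
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0)


def _moderated_z(u0: np.ndarray, rss: np.ndarray, d: int, d0: float, s0: float) -> np.ndarray:
    s2 = rss / d
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d * s2 + d0 * s0) / (d + d0)
        df_total = d + d0
    if np.any(s2_post <= 0):
        raise DataError(
            f"zero residual variance after shrinkage for gene(s) "
            f"{np.where(s2_post <= 0)[0].tolist()}"
        )
    t = u0 / np.sqrt(s2_post)
    if np.isinf(df_total):
        return t
    # map moderated t (df d + d0) to a standard-normal z, tail-safe
    sign = np.sign(t)
    return sign * stats.norm.isf(np.clip(stats.t.sf(np.abs(t), df_total), 1e-300, None))


def roast_test(
    data: TwoGroupDataset,
    n_rot: int = 999,
    set_stat: str = "mean",
    seed: int = 0,
) -> GSATestResult:
    """Rotation gene-set test with empirical-Bayes moderated t statistics.

    Per gene, the two-group linear model is reduced (via the QR decomposition
    of the design) to an effect coordinate plus n1+n2-2 residual coordinates;
    residual variances are shrunk toward a prior fitted from all genes in the
    set; moderated t values are mapped to z. The set statistic is mean(z)
    (two-sided) or mean(z^2). The null redraws the effect direction uniformly
    on the unit sphere of the reduced (d+1)-dimensional space — a rotation —
    which preserves the intergenic correlation, and re-computes the per-gene
    statistics each time with the same fitted prior.
    """
    _check_groups(data)
    if set_stat not in ("mean", "msq"):
        raise ParameterError(f"unknown set_stat {set_stat!r}")
    x, y = data.pooled()
    n, p = x.shape
    d = n - 2
    if d < 2:
        raise DataError("rotation test needs n1 + n2 - 2 >= 2 residual df")
    design = np.column_stack([np.ones(n), y.astype(float)])
    q, _ = np.linalg.qr(design, mode="complete")
    # orient the effect axis so a positive coordinate means case > control
    if q[:, 1] @ y < 0:
        q[:, 1] = -q[:, 1]
    coords = q[:, 1:].T @ x  # (d+1) x p: effect coordinate first, residuals after
    u0 = coords[0]
    rss = (coords[1:] ** 2).sum(axis=0)
    d0, s0 = fit_f_dist(rss / d, d)
    z = _moderated_z(u0, rss, d, d0, s0)
    obs = float(np.mean(z) if set_stat == "mean" else np.mean(z**2))

    rng = rng_from(seed, 0)
    r = rng.standard_normal((int(n_rot), d + 1))
    r /= np.linalg.norm(r, axis=1, keepdims=True)
    u0_rot = r @ coords  # (B, p)
    total = (coords**2).sum(axis=0)  # ||(u0, resid)||^2 per gene, rotation-invariant
    rss_rot = np.clip(total - u0_rot**2, 1e-300, None)
    z_rot = _moderated_z(u0_rot, rss_rot, d, d0, s0)
    null = z_rot.mean(axis=1) if set_stat == "mean" else (z_rot**2).mean(axis=1)

    if set_stat == "mean":
        p_value = float((1 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (n_rot + 1))
    else:
        p_value = float((1 + np.sum(null >= obs - 1e-12)) / (n_rot + 1))
    return GSATestResult(
        "roast", obs, p_value, "rotation", n_resamples=int(n_rot), seed=seed,
        note=f"set_stat={set_stat}",
    )


# ---------------------------------------------------------------------------
# pathway activity score (P-score)


def pscore_test(data: TwoGroupDataset, seed: int = 0) -> GSATestResult:
    """Pathway-activity-score logistic regression.

    Per gene: ranks across all samples; gene weight = mean absolute Pearson
    correlation with the other set genes. Per sample: score = weighted mean
    of its gene ranks. The score's coefficient in a logistic regression of
    the label is tested with a 1-df likelihood-ratio test.

    This rank/|correlation| construction is a documented stand-in for the
    published pathway-activity score and is isolated in this function.
    """
    import statsmodels.api as sm

    _check_groups(data)
    x, y = data.pooled()
    n, p = x.shape
    if p < 2:
        raise DataError("the pathway activity score needs >= 2 genes")
    ranks = stats.rankdata(x, axis=0)  # within-gene ranks across samples
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    w = np.abs(corr).sum(axis=0) / (p - 1)
    if w.sum() <= 0:
        raise DataError("all gene weights are zero; score undefined")
    score = ranks @ w / w.sum()

    ll_null = data.n1 * np.log(data.n1 / n) + data.n2 * np.log(data.n2 / n)
    note = None
    try:
        model = sm.Logit(y, sm.add_constant(score))
        fit = model.fit(disp=0, maxiter=200)
        lr = float(2.0 * (fit.llf - ll_null))
        if not fit.mle_retvals.get("converged", True):
            note = "logistic fit did not converge (possible separation)"
    except Exception as exc:  # perfect separation and kin
        lr = float(-2.0 * ll_null)
        note = f"perfect separation fallback: {exc}"
    lr = max(lr, 0.0)
    p_value = float(stats.chi2.sf(lr, 1))
    return GSATestResult(
        "pscore", lr, p_value, "likelihood_ratio", seed=seed, note=note
    )


# ---------------------------------------------------------------------------
# self-contained GSEA (sum of t statistics, sample permutation)


def _pooled_t(x: np.ndarray, ind: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per gene for each (B, n) case indicator.

    Genes with zero pooled variance get t = 0 (logged once by the caller).
    """
    n = x.shape[0]
    n2 = ind[0].sum()
    n1 = n - n2
    a = ind.astype(float)
    sum2 = a @ x
    sum1 = x.sum(axis=0) - sum2
    m1, m2 = sum1 / n1, sum2 / n2
    sq2 = a @ (x**2)
    sq1 = (x**2).sum(axis=0) - sq2
    ss1 = sq1 - n1 * m1**2
    ss2 = sq2 - n2 * m2**2
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / np.where(denom == 0, 1, denom), 0.0)
    return t


def gsea_test(
    data: TwoGroupDataset, n_perm: int | str = 999, seed: int = 0
) -> GSATestResult:
    """Self-contained enrichment test: the set statistic is the sum of the
    per-gene pooled two-sample t statistics, with a two-sided sample-label
    permutation null."""
    _check_groups(data)
    if data.n1 < 2 or data.n2 < 2:
        raise DataError("t statistics need >= 2 samples per group")
    x, y = data.pooled()
    n, n2 = y.size, int(y.sum())
    t_obs = _pooled_t(x, y.astype(bool)[None])[0]
    if np.any(_zero_var_both(data)):
        logger.info(
            "gsea: %d zero-variance gene(s) contribute t = 0",
            int(_zero_var_both(data).sum()),
        )
    obs = float(t_obs.sum())
    rng = rng_from(seed, 0)
    ind, exact = _case_indicators(n, n2, n_perm, rng)
    null = _pooled_t(x, ind).sum(axis=1)
    p_value = _resampling_p(abs(obs), np.abs(null), exact)
    return GSATestResult(
        "gsea", obs, p_value, "permutation", n_resamples=null.size, seed=seed
    )


def _zero_var_both(data: TwoGroupDataset) -> np.ndarray:
    return (data.x_control.var(axis=0) == 0) & (data.x_case.var(axis=0) == 0)


# ---------------------------------------------------------------------------
# N-statistic (two-sample energy)


def _n_statistic_from_dist(dmat: np.ndarray, ind: np.ndarray) -> np.ndarray:
    """Two-sample energy statistic for each (B, n) case indicator, from the
    precomputed pooled pairwise distance matrix."""
    a = ind.astype(float)
    n = dmat.shape[0]
    n2 = a[0].sum()
    n1 = n - n2
    ad = a @ dmat  # (B, n): sum over case rows of distances to each point
    cross = (ad * (1 - a)).sum(axis=1)
    within2 = (ad * a).sum(axis=1)
    total = dmat.sum()
    within1 = total - 2 * cross - within2
    return (n1 * n2 / (n1 + n2)) * (
        2.0 / (n1 * n2) * cross - within1 / n1**2 - within2 / n2**2
    )


def n_statistic_test(
    data: TwoGroupDataset, n_perm: int | str = 999, seed: int = 0
) -> GSATestResult:
    """N-statistic: the two-sample Euclidean energy distance between the case
    and control multivariate samples, with a label-permutation null. Zero iff
    the two groups are identical multisets; nonnegative always."""
    _check_groups(data)
    x, y = data.pooled()
    dmat = squareform(pdist(x))
    obs = float(_n_statistic_from_dist(dmat, y.astype(bool)[None])[0])
    rng = rng_from(seed, 0)
    ind, exact = _case_indicators(y.size, int(y.sum()), n_perm, rng)
    null = _n_statistic_from_dist(dmat, ind)
    p_value = _resampling_p(obs, null, exact)
    return GSATestResult(
        "nstat", obs, p_value, "permutation", n_resamples=null.size, seed=seed
    )


# ---------------------------------------------------------------------------
# MST rankings + multivariate Kolmogorov-Smirnov tests


def euclidean_mst_edges(x: np.ndarray) -> list[tuple[int, int]]:
    """Edges of the Euclidean minimum spanning tree of the rows of ``x``.

    Kruskal with edges inserted in (i < j) index order, so distance ties
    (duplicate points included) break deterministically by sample index.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise DataError("an MST needs at least 2 points")
    dmat = squareform(pdist(x))
    if not np.isfinite(dmat).all():
        raise DataError("non-finite pairwise distances")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=dmat[i, j])
    t = nx.minimum_spanning_tree(g, algorithm="kruskal")
    return sorted((min(u, v), max(u, v)) for u, v in t.edges)


def mst_hdp_ranks(x: np.ndarray, mode: str = "location") -> np.ndarray:
    """One-dimensional ordering of multivariate points.

    location: build the Euclidean MST, root it at a node of maximum (hop)
    eccentricity — smallest index on ties — and emit the high-directed-
    preorder depth-first traversal, visiting children in decreasing subtree
    size (index order on ties). Sensitive to mean shifts.

    scale: order points by increasing Euclidean distance from the pooled
    centroid (radial ranking), sensitive to dispersion differences.

    Returns the visit order: an array ``order`` with ``order[k]`` the sample
    index holding rank k + 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if mode == "scale":
        radii = np.linalg.norm(x - x.mean(axis=0), axis=1)
        return np.argsort(radii, kind="stable")
    if mode != "location":
        raise ParameterError(f"unknown ranking mode {mode!r}")

    edges = euclidean_mst_edges(x)
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    for nbrs in adj:
        nbrs.sort()

    def bfs_depths(root: int) -> np.ndarray:
        depth = np.full(n, -1)
        depth[root] = 0
        queue = [root]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if depth[v] < 0:
                        depth[v] = depth[u] + 1
                        nxt.append(v)
            queue = nxt
        return depth

    ecc = np.array([bfs_depths(i).max() for i in range(n)])
    root = int(np.argmax(ecc))  # argmax returns the smallest index on ties

    # iterative post-order for subtree sizes, then HDP preorder
    parent = np.full(n, -1)
    order_stack, visit = [root], []
    seen = np.zeros(n, dtype=bool)
    seen[root] = True
    while order_stack:
        u = order_stack.pop()
        visit.append(u)
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                parent[v] = u
                order_stack.append(v)
    size = np.ones(n, dtype=int)
    for u in reversed(visit):
        if parent[u] >= 0:
            size[parent[u]] += size[u]

    order: list[int] = []
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        children = sorted(
            (v for v in adj[u] if parent[v] == u),
            key=lambda v: (size[v], -v),
        )
        stack.extend(children)  # popped largest-subtree (smallest index) first
    return np.array(order, dtype=int)


def _ks_running_max(labels_in_order: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """max_i |F1(i) - F2(i)| over prefixes of the ordering; labels are (B, n)
    case indicators already arranged in rank order."""
    a = labels_in_order.astype(float)
    cum_case = np.cumsum(a, axis=-1) / n2
    cum_ctrl = np.cumsum(1.0 - a, axis=-1) / n1
    return np.abs(cum_ctrl - cum_case).max(axis=-1)


def _ks_test(data: TwoGroupDataset, mode: str, n_perm, seed: int) -> GSATestResult:
    _check_groups(data)
    x, y = data.pooled()
    order = mst_hdp_ranks(x, mode="location" if mode == "mean" else "scale")
    n, n2 = y.size, int(y.sum())
    obs = float(_ks_running_max(y.astype(bool)[None][:, order], data.n1, n2)[0])
    rng = rng_from(seed, 0)
    ind, exact = _case_indicators(n, n2, n_perm, rng)
    null = _ks_running_max(ind[:, order], data.n1, n2)
    p_value = _resampling_p(obs, null, exact)
    return GSATestResult(
        f"ks_{mode}", obs, p_value, "permutation", n_resamples=null.size, seed=seed
    )


def ks_mean_test(
    data: TwoGroupDataset, n_perm: int | str = 999, seed: int = 0
) -> GSATestResult:
    """Multivariate KS test for a mean difference: running difference of the
    two groups' empirical fractions along the MST high-directed-preorder
    ranking; D = max |difference|. Labels are permuted over the fixed pooled
    ranking (the ranking is label-independent)."""
    return _ks_test(data, "mean", n_perm, seed)


def ks_var_test(
    data: TwoGroupDataset, n_perm: int | str = 999, seed: int = 0
) -> GSATestResult:
    """Multivariate KS test for a dispersion difference: as ks_mean but along
    the radial (distance-from-centroid) ranking."""
    return _ks_test(data, "var", n_perm, seed)
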