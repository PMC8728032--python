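"""Simulated inputs: the eight two-group study designs A..H and synthetic
expression datasets.

The designs cover three kinds of departure from multivariate normality that
occur in transcriptomic data: gene-gene correlation only (A), heavy tails
(multivariate t with 3 df; B), mixtures in both groups (C, D) and disease
subtypes — mixtures in the case group only (E..H). Dimensions default to
p = 30 genes and 50 samples per group. The two compound-symmetry scale
matrices use rho = 0.1 (Sigma1) and rho = 0.5 (Sigma2).

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.random import Generator, SeedSequence

from ._utils import rng_from
from .datasets import (
    ExpressionDataset,
    GeneSetCollection,
    MixtureComponent,
    SimulationSetting,
    TwoGroupDataset,
)
from .errors import ParameterError

__all__ = [
    "compound_symmetry_cov",
    "sample_component",
    "sample_mixture",
    "make_setting",
    "generate_setting",
    "generate_expression_dataset",
    "SETTING_IDS",
]

SETTING_IDS = ("A", "B", "C", "D", "E", "F", "G", "H")


def compound_symmetry_cov(p: int, rho: float) -> np.ndarray:
    """Compound-symmetry correlation matrix: unit diagonal, ``rho`` off it.

    Positive definiteness requires -1/(p-1) < rho < 1.
    """
    if p < 1:
        raise ParameterError("dimension p must be >= 1")
    lower = -1.0 / (p - 1) if p > 1 else -np.inf
    if not (lower < rho < 1.0):
        raise ParameterError(
            f"rho={rho} outside the admissible range ({lower:.4g}, 1) for p={p}"
        )
    return np.full((p, p), rho) + (1.0 - rho) * np.eye(p)


@lru_cache(maxsize=64)
def _cs_cholesky(p: int, rho: float) -> np.ndarray:
    return np.linalg.cholesky(compound_symmetry_cov(p, rho))


def _component_chol(comp: MixtureComponent) -> np.ndarray:
    try:
        return np.linalg.cholesky(comp.scale)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "component scale matrix is not positive definite"
        ) from exc


def _draw_component(comp: MixtureComponent, n: int, rng: Generator) -> np.ndarray:
    chol = _component_chol(comp)
    z = rng.standard_normal((n, comp.p)) @ chol.T
    if comp.family == "student_t":
        # scale-matrix parameterisation: x = mu + z / sqrt(g/df), g ~ chi2(df),
        # so the covariance is df/(df-2) * scale for df > 2
        g = rng.chisquare(comp.df, size=n)
        z = z / np.sqrt(g / comp.df)[:, None]
    return comp.mean + z


def sample_component(comp: MixtureComponent, n: int, seed: int) -> np.ndarray:
    """Draw n i.i.d. rows from a single mixture component."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    return _draw_component(comp, n, rng_from(seed, 0))


def sample_mixture(
    components: list[MixtureComponent] | tuple[MixtureComponent, ...],
    n: int,
    seed: int,
) -> np.ndarray:
    """Draw n i.i.d. rows from a finite mixture.

    Each row independently samples its component index by weight and then
    draws from that component (weights are probabilities, not quotas). With a
    single component this reduces exactly to :func:`sample_component` under
    the same seed.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    weights = np.array([c.weight for c in components], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-12:
        raise ParameterError(f"mixture weights sum to {weights.sum()}, not 1")
    if len(components) == 1:
        return sample_component(components[0], n, seed)
    idx_rng = rng_from(seed, len(components))
    indices = idx_rng.choice(len(components), size=n, p=weights)
    out = np.empty((n, components[0].p), dtype=float)
    for k, comp in enumerate(components):
        mask = indices == k
        if mask.any():
            out[mask] = _draw_component(comp, int(mask.sum()), rng_from(seed, k))
    return out


def _mvn(mean, scale, weight=1.0) -> MixtureComponent:
    return MixtureComponent("normal", mean, scale, weight)


def _mvt(mean, scale, weight=1.0, df=3) -> MixtureComponent:
    return MixtureComponent("student_t", mean, scale, weight, df=df)


def make_setting(
    setting_id: str,
    delta: float,
    n_per_group: int = 50,
    p: int = 30,
    rho1: float = 0.1,
    rho2: float = 0.5,
    df: int = 3,
) -> SimulationSetting:
    """Instantiate one of the study designs A..H.

    A: MVN(0, S1) vs MVN(d, S1)
    B: MVT(0, S2) vs MVT(d, S2)
    C: .5 MVN(0,S1)+.5 MVN(1,S2)  vs the same shifted by d
    D: as C with MVT(3 df) components
    E: MVN(0,S1) vs .5 MVN(0,S1)+.5 MVN(d,S1)
    F: MVT(0,S2) vs .5 MVT(0,S2)+.5 MVT(d,S2)
    G: MVN(0,S1) vs .4 MVN(0,S1)+.3 MVN(d/2,S1)+.3 MVN(d,S1)
    H: MVT(0,S2) vs .4 MVT(0,S2)+.3 MVT(d/2,S2)+.3 MVT(d,S2)

    where S1/S2 are compound-symmetry with rho1/rho2, 0/1 are the constant
    vectors and d is the constant shift vector (delta, ..., delta).
    """
    setting_id = setting_id.upper()
    if setting_id not in SETTING_IDS:
        raise ParameterError(f"unknown setting id {setting_id!r}; expected one of A..H")
    s1 = compound_symmetry_cov(p, rho1)
    s2 = compound_symmetry_cov(p, rho2)
    zero = np.zeros(p)
    one = np.ones(p)
    d = np.full(p, float(delta))

    if setting_id == "A":
        control = (_mvn(zero, s1),)
        case = (_mvn(d, s1),)
    elif setting_id == "B":
        control = (_mvt(zero, s2, df=df),)
        case = (_mvt(d, s2, df=df),)
    elif setting_id == "C":
        control = (_mvn(zero, s1, 0.5), _mvn(one, s2, 0.5))
        case = (_mvn(d, s1, 0.5), _mvn(one + d, s2, 0.5))
    elif setting_id == "D":
        control = (_mvt(zero, s1, 0.5, df), _mvt(one, s2, 0.5, df))
        case = (_mvt(d, s1, 0.5, df), _mvt(one + d, s2, 0.5, df))
    elif setting_id == "E":
        control = (_mvn(zero, s1),)
        case = (_mvn(zero, s1, 0.5), _mvn(d, s1, 0.5))
    elif setting_id == "F":
        control = (_mvt(zero, s2, df=df),)
        case = (_mvt(zero, s2, 0.5, df), _mvt(d, s2, 0.5, df))
    elif setting_id == "G":
        control = (_mvn(zero, s1),)
        case = (_mvn(zero, s1, 0.4), _mvn(0.5 * d, s1, 0.3), _mvn(d, s1, 0.3))
    else:  # H
        control = (_mvt(zero, s2, df=df),)
        case = (_mvt(zero, s2, 0.4, df), _mvt(0.5 * d, s2, 0.3, df), _mvt(d, s2, 0.3, df))

    return SimulationSetting(
        setting_id=setting_id,
        control=control,
        case=case,
        delta=float(delta),
        p=p,
        n_per_group=n_per_group,
        rho1=rho1,
        rho2=rho2,
    )


def generate_setting(
    setting_id: str,
    delta: float,
    n_per_group: int = 50,
    p: int = 30,
    seed: int = 0,
    rho1: float = 0.1,
    rho2: float = 0.5,
    df: int = 3,
) -> TwoGroupDataset:
    """Generate one replication of a study design as a TwoGroupDataset."""
    spec = make_setting(setting_id, delta, n_per_group, p, rho1, rho2, df)
    seed = int(seed)
    x_control = sample_mixture(spec.control, n_per_group, _sub(seed, 1))
    x_case = sample_mixture(spec.case, n_per_group, _sub(seed, 2))
    return TwoGroupDataset(x_control=x_control, x_case=x_case, seed=seed)


def _sub(seed: int, k: int) -> int:
    """Derived integer seed for substream k (kept below 2**31)."""
    return int(SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % 2**31)


def generate_expression_dataset(
    n_genes: int,
    n_samples_per_group: int,
    gene_set_sizes: list[int] | tuple[int, ...] = (30,),
    set_settings: list[tuple[str, float]] | None = None,
    marginal: str = "normal",
    rho: float = 0.1,
    seed: int = 0,
) -> ExpressionDataset:
    """Synthetic genes x samples expression dataset with declared gene sets.

    Genes inside declared sets are generated with compound-symmetry
    correlation ``rho`` (and, when ``set_settings`` supplies a
    (setting_id, delta) pair for the set, with that design's group structure);
    background genes are i.i.d. The ``marginal`` transform is applied
    elementwise: "normal" (identity), "lognormal" (exp of the generated
    Gaussian values, a constructed normality violation) or "t" (the set/
    background draws use Student-t with 3 df).

    Gene and sample ids are deterministic functions of position; labels mark
    the two sample groups (control 0, case 1). The result is GMT-exportable.
    """
    if marginal not in ("normal", "lognormal", "t"):
        raise ParameterError(f"unknown marginal {marginal!r}")
    sizes = [int(s) for s in gene_set_sizes]
    if any(s < 1 for s in sizes):
        raise ParameterError("gene-set sizes must be >= 1")
    if sum(sizes) > n_genes:
        raise ParameterError(
            f"gene-set sizes sum to {sum(sizes)} > n_genes={n_genes}"
        )
    if set_settings is not None and len(set_settings) != len(sizes):
        raise ParameterError("set_settings must align with gene_set_sizes")

    n1 = n2 = int(n_samples_per_group)
    n = n1 + n2
    matrix = np.empty((n_genes, n), dtype=float)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    sample_ids = [f"CTRL{i + 1:04d}" for i in range(n1)] + [
        f"CASE{i + 1:04d}" for i in range(n2)
    ]
    labels = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])

    sets = GeneSetCollection()
    cursor = 0
    for k, size in enumerate(sizes):
        members = gene_ids[cursor : cursor + size]
        if set_settings is None:
            cov = compound_symmetry_cov(size, rho)
            fam = "student_t" if marginal == "t" else "normal"
            comp = MixtureComponent(
                fam, np.zeros(size), cov, 1.0, df=3 if fam == "student_t" else None
            )
            block = sample_component(comp, n, _sub(seed, 10 + k)).T
        else:
            sid, delta = set_settings[k]
            tg = generate_setting(
                sid, delta, n_per_group=n1, p=size, seed=_sub(seed, 10 + k)
            )
            block = np.vstack([tg.x_control, tg.x_case]).T
        matrix[cursor : cursor + size] = block
        sets.add(f"SET{k + 1}", f"synthetic gene set {k + 1}", members)
        cursor += size

    bg_rng = rng_from(seed, 999)
    n_bg = n_genes - cursor
    if n_bg:
        if marginal == "t":
            bg = bg_rng.standard_t(3, size=(n_bg, n))
        else:
            bg = bg_rng.standard_normal((n_bg, n))
        matrix[cursor:] = bg

    if marginal == "lognormal":
        matrix = np.exp(matrix)

    return ExpressionDataset(
        values=matrix,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        labels=labels,
        gene_sets=sets,
    )
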