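"""In-memory containers shared by the generators, tests, protocols and IO.

Expression matrices follow the field convention genes x samples on disk and in
``ExpressionDataset``; tests consume samples x genes matrices, produced by the
``subset_matrix``/``samples_by_genes`` accessors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import DataError, ParameterError

logger = logging.getLogger("gsabench")


@dataclass(frozen=True)
class MixtureComponent:
    """One component of a per-group mixture: a multivariate normal or a
    multivariate Student-t.

    ``scale`` is the scale matrix of the component; for the Student-t family
    the true covariance is df/(df-2) times ``scale`` (for df > 2).
    """

    family: str  # "normal" | "student_t"
    mean: np.ndarray
    scale: np.ndarray
    weight: float
    df: int | None = None

    def __post_init__(self):
        if self.family not in ("normal", "student_t"):
            raise ParameterError(f"unknown component family {self.family!r}")
        mean = np.asarray(self.mean, dtype=float)
        scale = np.asarray(self.scale, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "scale", scale)
        if scale.shape != (mean.size, mean.size):
            raise ParameterError("scale matrix shape must match the mean dimension")
        if not np.allclose(scale, scale.T):
            raise ParameterError("scale matrix must be symmetric")
        if not (0.0 <= self.weight <= 1.0):
            raise ParameterError("component weight must lie in [0, 1]")
        if self.family == "student_t":
            if self.df is None or self.df < 1:
                raise ParameterError("student_t components need df >= 1")

    @property
    def p(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class SimulationSetting:
    """One row of the simulation design: per-group mixture specifications.

    ``setting_id`` is one of A..H. ``delta`` is the common per-gene mean shift
    of the case group; ``rho1``/``rho2`` are the compound-symmetry correlations
    of the two scale matrices used by the design.
    """

    setting_id: str
    control: tuple[MixtureComponent, ...]
    case: tuple[MixtureComponent, ...]
    delta: float
    p: int = 30
    n_per_group: int = 50
    rho1: float = 0.1
    rho2: float = 0.5

    def __post_init__(self):
        for name, comps in (("control", self.control), ("case", self.case)):
            total = sum(c.weight for c in comps)
            if abs(total - 1.0) > 1e-12:
                raise ParameterError(f"{name} mixture weights sum to {total}, not 1")
            for c in comps:
                if c.p != self.p:
                    raise ParameterError("component dimension differs from setting p")
        if self.delta < 0:
            raise ParameterError("delta must be >= 0")


@dataclass(frozen=True)
class TwoGroupDataset:
    """A simulated two-group sample: control (n1 x p) and case (n2 x p)."""

    x_control: np.ndarray
    x_case: np.ndarray
    seed: int = 0

    def __post_init__(self):
        xc = np.asarray(self.x_control, dtype=float)
        xt = np.asarray(self.x_case, dtype=float)
        object.__setattr__(self, "x_control", xc)
        object.__setattr__(self, "x_case", xt)
        if xc.ndim != 2 or xt.ndim != 2 or xc.shape[1] != xt.shape[1]:
            raise DataError("control and case matrices must be 2-D with equal p")
        if not (np.isfinite(xc).all() and np.isfinite(xt).all()):
            raise DataError("two-group data contain non-finite values")

    @property
    def n1(self) -> int:
        return self.x_control.shape[0]

    @property
    def n2(self) -> int:
        return self.x_case.shape[0]

    @property
    def p(self) -> int:
        return self.x_control.shape[1]

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y): pooled samples x genes matrix and 0/1 labels (case = 1),
        control rows first."""
        x = np.vstack([self.x_control, self.x_case])
        y = np.concatenate([np.zeros(self.n1, dtype=int), np.ones(self.n2, dtype=int)])
        return x, y


class GeneSetCollection(Mapping):
    """Ordered name -> (description, gene list) map, GMT-shaped.

    Duplicate genes within a set are removed (first occurrence kept) with a
    log notice; set names must be unique and gene lists non-empty.
    """

    def __init__(self, sets: Sequence[tuple[str, str, Sequence[str]]] = ()):
        self._sets: dict[str, tuple[str, list[str]]] = {}
        for name, description, genes in sets:
            self.add(name, description, genes)

    def add(self, name: str, description: str, genes: Sequence[str]) -> None:
        if name in self._sets:
            raise DataError(f"duplicate gene-set name {name!r}")
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            logger.info(
                "gene set %s: removed %d duplicate gene id(s)",
                name,
                len(genes) - len(deduped),
            )
        if not deduped:
            raise DataError(f"gene set {name!r} is empty")
        self._sets[name] = (description, deduped)

    def __getitem__(self, name: str) -> tuple[str, list[str]]:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def genes(self, name: str) -> list[str]:
        return self._sets[name][1]

    def description(self, name: str) -> str:
        return self._sets[name][0]


@dataclass
class ExpressionDataset:
    """A named genes x samples expression matrix with optional binary labels
    and an optional gene-set collection.

    ``values`` may be dense (ndarray) or scipy.sparse; sparse storage is
    densified only when a gene subset is extracted. Gene-set members need not
    all be present in ``gene_ids`` — membership is resolved at use.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = None
    gene_sets: GeneSetCollection = field(default_factory=GeneSetCollection)

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("gene ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("sample ids are not unique")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.size != len(self.sample_ids):
                raise DataError("label vector length does not match sample count")
            if not set(np.unique(self.labels)) <= {0, 1}:
                raise DataError("labels must be binary 0/1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Dense genes x samples DataFrame view."""
        dense = self.values.toarray() if sp.issparse(self.values) else self.values
        return pd.DataFrame(dense, index=self.gene_ids, columns=self.sample_ids)

    def resolve_set(self, set_name: str) -> list[str]:
        """Gene-set members present in the matrix, in set order."""
        present = set(self.gene_ids)
        return [g for g in self.gene_sets.genes(set_name) if g in present]

    def subset_matrix(self, genes: Sequence[str]) -> np.ndarray:
        """samples x genes dense matrix for the requested genes (in order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise DataError(f"genes absent from the matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        block = self.values[rows, :]
        if sp.issparse(block):
            block = block.toarray()
        return np.asarray(block, dtype=float).T

    def samples_by_genes(self) -> np.ndarray:
        """Full dense samples x genes matrix."""
        return self.subset_matrix(self.gene_ids)


@dataclass(frozen=True)
class RejectionSummary:
    """Outcome of the gene-subset rejection-rate protocol for one test."""

    method: str
    q: float
    n_reps: int
    alpha: float
    subset_size: int
    seed: int
    n_excluded: int = 0

    def __post_init__(self):
        if not (0.0 <= self.q <= 1.0):
            raise ParameterError("rejection rate must lie in [0, 1]")


@dataclass(frozen=True)
class KLResult:
    """Estimated distance-from-normality of one simulation setting: the sum of
    the case-vs-N(0,I) and control-vs-N(0,I) Kullback-Leibler divergences."""

    setting_id: str
    delta_used: float
    n_used: int
    k_neighbors: int
    kl_sum: float
    kl_case: float
    kl_control: float
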