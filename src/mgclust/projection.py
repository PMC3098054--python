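"""Soft clustering by generalized projections onto similarity constraints.

The clustering state is a row-stochastic I x K matrix X whose row i is
the probability distribution of gene i over K cluster labels.  Each
similarity constraint defines a projector implemented by relaxation
labeling (RL): per sweep, every gene's distribution is multiplied by the
support it receives from its nearest neighbors under that constraint,

    q_ik = sum over i' in ∂_i of exp(v_ii') * x_i'k,
    x_ik <- x_ik * q_ik / sum_k' x_ik' * q_ik',

a growth-transform update that never decreases the gain function

    G(X) = sum_i sum_k x_ik * q_ik.

The simultaneous-projection loop combines the per-constraint projections
as a weighted average, X_m = sum_n w_n * P_n(X_{m-1}), with nonnegative
weights summing to one, for M outer iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "SoftClustering",
    "NeighborhoodSystem",
    "ProjectorConfig",
    "POCSConfig",
    "ProjectionTrace",
    "init_soft_clustering",
    "build_neighborhood",
    "gain",
    "rl_project",
    "simultaneous_project",
    "hard_assign",
    "write_soft_clustering",
    "read_soft_clustering",
    "write_hard_labels",
    "write_trace",
]

logger = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-9


@dataclass
class SoftClustering:
    """Row-stochastic membership matrix X = (x_ik), K >= 2 clusters."""

    gene_ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.gene_ids):
            raise ValueError("X must be an I x K matrix matching gene_ids")
        if self.X.shape[1] < 2:
            raise ValueError("K must be >= 2")
        if np.any(self.X < -_ROW_SUM_TOL) or np.any(self.X > 1 + _ROW_SUM_TOL):
            raise ValueError("memberships must lie in [0, 1]")
        if np.any(np.abs(self.X.sum(axis=1) - 1.0) > _ROW_SUM_TOL):
            raise ValueError("rows must sum to 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_clusters(self) -> int:
        return self.X.shape[1]


@dataclass
class NeighborhoodSystem:
    """Per gene, its nearest defined-similarity neighbors (self excluded).

    ``neighbors[i]`` is ordered by non-increasing similarity, ties broken
    by ascending gene index; ``support`` holds the dense matrix A with
    A[i, i'] = exp(v_ii') for i' in ∂_i and 0 elsewhere.
    """

    gene_ids: list[str]
    neighbors: list[np.ndarray]
    similarities: list[np.ndarray]
    support: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.support is None:
            a = np.zeros((n, n))
            for i, (idx, sims) in enumerate(zip(self.neighbors, self.similarities)):
                if len(idx):
                    a[i, idx] = np.exp(sims)
            self.support = a


@dataclass
class ProjectorConfig:
    """Relaxation-labeling projector settings: J sweeps over n_neighbors-NN."""

    j_iterations: int = 5
    n_neighbors: int = 10

    def __post_init__(self) -> None:
        if self.j_iterations < 1:
            raise ValueError("j_iterations must be >= 1")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")


@dataclass
class POCSConfig:
    """Simultaneous-projection settings.

    ``weights`` are the per-constraint combination weights w_n (GO first
    by convention, default (0.8, 0.2)); they must be nonnegative and sum
    to one.  ``m_projections`` is the outer iteration count M.
    """

    k_clusters: int = 10
    m_projections: int = 3
    weights: tuple[float, ...] = (0.8, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = tuple(float(w) for w in self.weights)
        if self.m_projections < 1:
            raise ValueError("m_projections must be >= 1")
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2")
        if any(w < 0 for w in self.weights) or abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("projection weights must be nonnegative and sum to 1")


@dataclass
class ProjectionTrace:
    """Per-iteration diagnostics of the simultaneous projection.

    ``gains[m][n]`` is the gain of the combined solution X_m under
    constraint n; ``history[m]`` is X_m itself (history[0] = X_0).
    """

    gains: list[list[float]] = field(default_factory=list)
    history: list[np.ndarray] = field(default_factory=list)

    def rows(self):
        for m, per_constraint in enumerate(self.gains, start=1):
            for n, g in enumerate(per_constraint):
                yield m, n, g


def init_soft_clustering(gene_ids, k: int, seed: int) -> SoftClustering:
    """Random initialization: each row drawn from the flat Dirichlet on the K-simplex."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    X = rng.dirichlet(np.ones(k), size=len(list(gene_ids)))
    return SoftClustering(list(gene_ids), X)


def build_neighborhood(s: SimilarityMatrix, n_neighbors: int = 10) -> NeighborhoodSystem:
    """Up to ``n_neighbors`` highest-similarity defined neighbors per gene.

    Self is excluded; ties are broken by ascending gene index; genes with
    no defined pair get an empty neighborhood (logged).
    """
    n = s.n_genes
    neighbors: list[np.ndarray] = []
    sims: list[np.ndarray] = []
    n_empty = 0
    for i in range(n):
        cand = np.where(s.mask[i])[0]
        cand = cand[cand != i]
        if cand.size == 0:
            n_empty += 1
            neighbors.append(np.empty(0, dtype=int))
            sims.append(np.empty(0))
            continue
        # stable sort on descending similarity keeps ascending index on ties
        order = cand[np.argsort(-s.values[i, cand], kind="stable")][:n_neighbors]
        neighbors.append(order)
        sims.append(s.values[i, order])
    if n_empty:
        logger.info("%d gene(s) have empty neighborhoods", n_empty)
    return NeighborhoodSystem(s.gene_ids, neighbors, sims)


def gain(x: SoftClustering, s: SimilarityMatrix, nbhd: NeighborhoodSystem) -> float:
    """G(X) = sum_i sum_k x_ik * sum_{i' in ∂_i} exp(v_ii') * x_i'k."""
    return float(np.sum(x.X * (nbhd.support @ x.X)))


def _rl_sweeps(X: np.ndarray, support: np.ndarray, j_iterations: int) -> np.ndarray:
    X = X.copy()
    for _ in range(j_iterations):
        Q = support @ X  # supports from the previous sweep's values
        Xn = X * Q
        z = Xn.sum(axis=1)
        ok = z > 0
        Xn[ok] /= z[ok, None]
        Xn[~ok] = X[~ok]  # empty neighborhood / zero support: identity
        X = Xn
    return X


def rl_project(
    x: SoftClustering,
    s: SimilarityMatrix,
    nbhd: NeighborhoodSystem,
    cfg: ProjectorConfig | None = None,
) -> SoftClustering:
    """Relaxation-labeling projector: J synchronous multiplicative sweeps.

    All genes are updated from the previous sweep's values; rows with an
    empty neighborhood or zero support are left unchanged.  The gain
    never decreases across sweeps.
    """
    cfg = cfg or ProjectorConfig()
    if x.gene_ids != nbhd.gene_ids:
        raise ValueError("clustering and neighborhood gene_ids differ")
    return SoftClustering(x.gene_ids, _rl_sweeps(x.X, nbhd.support, cfg.j_iterations))


def simultaneous_project(
    x0: SoftClustering,
    constraints: list[tuple[SimilarityMatrix, ProjectorConfig]],
    cfg: POCSConfig,
) -> tuple[SoftClustering, ProjectionTrace]:
    """Weighted simultaneous projection: X_m = sum_n w_n * P_n(X_{m-1}).

    Returns the final solution X_M together with a trace of per-constraint
    gain values after every outer iteration (for convergence diagnostics).
    """
    if len(cfg.weights) != len(constraints):
        raise ValueError(
            f"{len(cfg.weights)} weight(s) for {len(constraints)} constraint(s)"
        )
    nbhds = [build_neighborhood(s, pc.n_neighbors) for s, pc in constraints]
    trace = ProjectionTrace()
    X = x0.X.copy()
    trace.history.append(X.copy())
    for _ in range(cfg.m_projections):
        projected = [
            _rl_sweeps(X, nb.support, pc.j_iterations)
            for nb, (_, pc) in zip(nbhds, constraints)
        ]
        # convex combination of row-stochastic matrices stays row-stochastic
        X = sum(w * P for w, P in zip(cfg.weights, projected))
        trace.history.append(X.copy())
        trace.gains.append(
            [float(np.sum(X * (nb.support @ X))) for nb in nbhds]
        )
    return SoftClustering(x0.gene_ids, X), trace


def hard_assign(x: SoftClustering) -> np.ndarray:
    """Winner-take-all labels: argmax per row, ties to the lowest cluster index."""
    return np.argmax(x.X, axis=1)


def write_soft_clustering(x: SoftClustering, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(f"p{k + 1}" for k in range(x.n_clusters)) + "\n")
        for gene, row in zip(x.gene_ids, x.X):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_soft_clustering(path) -> SoftClustering:
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            gene_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return SoftClustering(gene_ids, np.array(rows))


def write_hard_labels(gene_ids, labels, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tcluster\n")
        for gene, lab in zip(gene_ids, labels):
            fh.write(f"{gene}\t{int(lab) + 1}\n")


def write_trace(trace: ProjectionTrace, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("iteration\tconstraint\tgain\n")
        for m, n, g in trace.rows():
            fh.write(f"{m}\t{n}\t{g!r}\n")
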