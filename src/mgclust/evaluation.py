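"""Clustering performance measures and GO-deletion cross-validation.

Two measures score a predicted clustering against a reference table in
which a gene may belong to several clusters:

* **GLL (gene log likelihood)** evaluates the soft solution X directly.
  Each reference cluster w receives a distribution p_w over the K
  predicted clusters — by default the normalized conditional-independence
  product p_wk ∝ prod over member genes of x_ik — and
  GLL = sum_w sum_{i in w} ln(sum_k p_wk * x_ik).  It is always <= 0 and
  higher is better; a gene with several reference memberships contributes
  one term per membership.

* **NMI (normalized mutual information)** evaluates the winner-take-all
  hard labels.  The contingency table counts one unit per
  (gene, reference-membership) pair, which reduces to standard NMI when
  every gene has a single membership.  Natural logarithms throughout;
  NMI = I(W;K) / sqrt(H(W) * H(K)) by default.

The cross-validation harness deletes all GO annotations of each held-out
fold before building the GO constraint, runs the projection pipeline,
and scores the held-out genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .expression import ExpressionMatrix, expression_similarity
from .ontology import AnnotationSet, OntologyGraph, gene_go_similarity_matrix
from .projection import (
    POCSConfig,
    ProjectorConfig,
    SoftClustering,
    hard_assign,
    init_soft_clustering,
    simultaneous_project,
)

__all__ = [
    "ReferenceClustering",
    "ClusterPredictiveDistribution",
    "read_reference_clusters",
    "estimate_pwk",
    "gll",
    "nmi",
    "CrossvalResult",
    "crossval_go",
]

logger = logging.getLogger(__name__)

_PWK_FLOOR = 1e-12


@dataclass
class ReferenceClustering:
    """Binary I x W multi-membership matrix Y over named reference clusters."""

    gene_ids: list[str]
    cluster_names: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.cluster_names = list(self.cluster_names)
        self.Y = np.asarray(self.Y, dtype=bool)
        if len(self.cluster_names) < 2:
            raise ValueError("a reference clustering needs W >= 2 clusters")
        if self.Y.shape != (len(self.gene_ids), len(self.cluster_names)):
            raise ValueError("Y must be I x W")
        if np.any(self.Y.sum(axis=1) == 0):
            raise ValueError("every evaluated gene must have >= 1 membership")

    @property
    def n_w(self) -> np.ndarray:
        """Genes per reference cluster."""
        return self.Y.sum(axis=0)

    def restrict(self, genes) -> "ReferenceClustering":
        """Restriction to a gene subset, dropping reference clusters left empty."""
        keep = set(genes)
        rows = [i for i, g in enumerate(self.gene_ids) if g in keep]
        if not rows:
            raise ValueError("no evaluable genes in the restriction")
        Y = self.Y[rows]
        cols = np.where(Y.sum(axis=0) > 0)[0]
        if cols.size < 2:
            raise ValueError("fewer than 2 reference clusters cover the gene subset")
        return ReferenceClustering(
            [self.gene_ids[i] for i in rows],
            [self.cluster_names[j] for j in cols],
            Y[:, cols],
        )


@dataclass
class ClusterPredictiveDistribution:
    """Per reference cluster w, a distribution p_w over the K predicted clusters."""

    cluster_names: list[str]
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if np.any(self.P < 0) or np.any(np.abs(self.P.sum(axis=1) - 1) > 1e-9):
            raise ValueError("each p_w must be a probability distribution")


def read_reference_clusters(path, gene_universe) -> ReferenceClustering:
    """Read a two-column gene<TAB>cluster TSV restricted to a gene universe.

    Repeated genes denote multi-membership; genes outside the universe
    are dropped (logged).  An empty intersection is a hard error.
    """
    universe = list(gene_universe)
    uset = set(universe)
    memberships: dict[str, set[str]] = {}
    cluster_names: list[str] = []
    n_outside = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno} is not gene<TAB>cluster")
            gene, cluster = parts
            if gene == "gene" and lineno == 1:
                continue  # optional header
            if gene not in uset:
                n_outside += 1
                continue
            if cluster not in cluster_names:
                cluster_names.append(cluster)
            memberships.setdefault(gene, set()).add(cluster)
    if n_outside:
        logger.warning("dropped %d membership row(s) outside the gene universe", n_outside)
    if not memberships:
        raise ValueError(f"{path}: no reference gene overlaps the gene universe")
    gene_ids = [g for g in universe if g in memberships]
    col = {c: j for j, c in enumerate(cluster_names)}
    Y = np.zeros((len(gene_ids), len(cluster_names)), dtype=bool)
    for i, g in enumerate(gene_ids):
        for c in memberships[g]:
            Y[i, col[c]] = True
    return ReferenceClustering(gene_ids, cluster_names, Y)


def _aligned_X(x: SoftClustering, y: ReferenceClustering) -> np.ndarray:
    pos = {g: i for i, g in enumerate(x.gene_ids)}
    try:
        rows = [pos[g] for g in y.gene_ids]
    except KeyError as exc:
        raise ValueError(f"reference gene {exc.args[0]!r} missing from clustering") from None
    return x.X[rows]


def estimate_pwk(
    x: SoftClustering, y: ReferenceClustering, method: str = "product"
) -> ClusterPredictiveDistribution:
    """Distribution of each reference cluster over predicted clusters.

    ``"product"`` (default): p_wk ∝ prod_{i in w} x_ik, treating member
    genes as conditionally independent; computed in log space with each
    x_ik floored at 1e-12.  ``"mean"``: p_wk = mean_{i in w} x_ik, the
    empirical-average alternative.
    """
    X = _aligned_X(x, y)
    empty = np.where(y.Y.sum(axis=0) == 0)[0]
    if empty.size:
        raise ValueError(
            f"reference cluster {y.cluster_names[empty[0]]!r} has no member genes"
        )
    if method == "product":
        logx = np.log(np.maximum(X, _PWK_FLOOR))
        logp = y.Y.T.astype(float) @ logx  # W x K sums of member log-memberships
        P = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    elif method == "mean":
        P = (y.Y.T.astype(float) @ X) / y.n_w[:, None]
        P = P / P.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown estimate_pwk method {method!r}")
    return ClusterPredictiveDistribution(y.cluster_names, P)


def gll(
    x: SoftClustering,
    y: ReferenceClustering,
    method: str = "product",
    per_membership: bool = False,
) -> float:
    """Gene log likelihood of the reference clusters under the soft solution.

    GLL = sum_w sum_{i in w} ln(sum_k p_wk * x_ik), natural log; <= 0,
    higher is better.  ``per_membership=True`` divides by the number of
    (gene, membership) pairs for cross-dataset comparability.
    """
    X = _aligned_X(x, y)
    P = estimate_pwk(x, y, method=method).P
    inner = X @ P.T  # (i, w) -> sum_k p_wk x_ik
    terms = np.log(np.maximum(inner[y.Y], _PWK_FLOOR))
    total = float(terms.sum())
    total = min(total, 0.0)
    return total / y.Y.sum() if per_membership else total


def nmi(labels_pred, y: ReferenceClustering, normalization: str = "sqrt") -> float:
    """Normalized mutual information between hard labels and the reference.

    The W x K contingency counts one unit per (gene, membership) pair.
    Identical trivial partitions (both entropies zero) give 1; one-sided
    zero entropy gives 0.  ``normalization``: "sqrt" for
    I/sqrt(H_W * H_K), "sum" for 2I/(H_W + H_K).
    """
    labels_pred = np.asarray(labels_pred, dtype=int)
    if labels_pred.shape[0] != len(y.gene_ids):
        raise ValueError("labels must align with the reference gene_ids")
    W = len(y.cluster_names)
    K = int(labels_pred.max()) + 1 if labels_pred.size else 0
    cont = np.zeros((W, K))
    for i, lab in enumerate(labels_pred):
        cont[:, lab] += y.Y[i]
    n = cont.sum()
    pw = cont.sum(axis=1) / n
    pk = cont.sum(axis=0) / n
    pj = cont / n
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pj / np.outer(pw, pk)
        mi = float(np.nansum(np.where(pj > 0, pj * np.log(ratio), 0.0)))
        hw = float(-np.sum(pw[pw > 0] * np.log(pw[pw > 0])))
        hk = float(-np.sum(pk[pk > 0] * np.log(pk[pk > 0])))
    if hw == 0.0 and hk == 0.0:
        return 1.0
    if hw == 0.0 or hk == 0.0:
        return 0.0
    # identical partitions (one nonzero per row and column): NMI is exactly 1
    if (
        W == K
        and np.all((cont > 0).sum(axis=1) <= 1)
        and np.all((cont > 0).sum(axis=0) <= 1)
    ):
        return 1.0
    if normalization == "sqrt":
        value = mi / np.sqrt(hw * hk)
    elif normalization == "sum":
        value = 2.0 * mi / (hw + hk)
    else:
        raise ValueError(f"unknown NMI normalization {normalization!r}")
    return float(min(max(value, 0.0), 1.0))


@dataclass
class CrossvalResult:
    """Per-fold held-out metrics plus their mean and standard deviation."""

    folds: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("fold\tmetric\tvalue\n")
            for rec in self.folds:
                fh.write(f"{rec['fold']}\tgll\t{rec['gll']!r}\n")
                fh.write(f"{rec['fold']}\tnmi\t{rec['nmi']!r}\n")
            for metric in ("gll", "nmi"):
                fh.write(
                    f"mean\t{metric}\t{self.summary[metric + '_mean']!r}"
                    f" ± {self.summary[metric + '_sd']!r}\n".replace("\t ", "\t")
                )


def crossval_go(
    expr: ExpressionMatrix,
    graph: OntologyGraph,
    ann: AnnotationSet,
    y: ReferenceClustering,
    cfg: POCSConfig,
    projector_cfg: ProjectorConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
    evaluate: str = "held_out",
) -> CrossvalResult:
    """GO-deletion cross-validation.

    Genes are partitioned into ``n_folds`` seeded folds; per fold, every
    GO annotation of the held-out genes is deleted before the GO
    similarity matrix is built (their GO rows become masked, so the GO
    projector leaves them unchanged while the expression projector still
    moves them), the simultaneous projection runs, and GLL/NMI are
    computed over the held-out genes only (``evaluate="all"`` scores all
    reference genes instead).
    """
    if evaluate not in ("held_out", "all"):
        raise ValueError(f"unknown evaluate mode {evaluate!r}")
    pcfg = projector_cfg or ProjectorConfig()
    if expr.missing_mask.any():
        raise ValueError("expression matrix contains missing values; impute first")
    gene_ids = expr.gene_ids
    expr_sim = expression_similarity(expr)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(gene_ids))
    fold_indices = np.array_split(order, n_folds)
    result = CrossvalResult()
    for f, idx in enumerate(fold_indices):
        held_genes = [gene_ids[i] for i in sorted(idx)]
        ann_f = ann.without_genes(held_genes)
        go_sim = gene_go_similarity_matrix(graph, ann_f, gene_ids)
        init_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(f,)).generate_state(1)[0]
            % (2**31)
        )
        x0 = init_soft_clustering(gene_ids, cfg.k_clusters, seed=init_seed)
        x_final, _ = simultaneous_project(
            x0, [(go_sim, pcfg), (expr_sim, pcfg)], cfg
        )
        eval_genes = held_genes if evaluate == "held_out" else gene_ids
        try:
            y_f = y.restrict(eval_genes)
        except ValueError as exc:
            raise ValueError(
                f"fold {f}: {exc}; try fewer folds so each holds evaluable genes"
            ) from exc
        labels = hard_assign(x_final)
        pos = {g: i for i, g in enumerate(gene_ids)}
        labels_f = labels[[pos[g] for g in y_f.gene_ids]]
        result.folds.append(
            {
                "fold": f,
                "n_heldout": len(held_genes),
                "n_evaluated": len(y_f.gene_ids),
                "gll": gll(x_final, y_f),
                "nmi": nmi(labels_f, y_f),
            }
        )
    for metric in ("gll", "nmi"):
        vals = np.array([rec[metric] for rec in result.folds])
        result.summary[f"{metric}_mean"] = float(vals.mean())
        result.summary[f"{metric}_sd"] = float(vals.std(ddof=1))
    return result
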