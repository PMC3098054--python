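"""Seeded generators for every input the clustering pipeline consumes.

The generators emulate the statistical structure of cluster-organized
time-course microarray data with GO-style annotations, without any
external download: overlapping reference memberships, sinusoidal
cluster prototypes with cluster-specific phase (so some cluster pairs
are correlated and some anti-correlated), a small typed GO DAG per
aspect with is-a/part-of edges and multi-parent terms, and
cluster-coherent annotations with configurable noise and missingness.
A gene planted in two clusters averages its clusters' expression
prototypes and draws annotations from both clusters' term subtrees —
the generative analogue of a bifunctional gene.

All outputs are deterministic functions of ``SyntheticConfig.seed`` and
can be round-tripped through the package's TSV/OBO/GAF readers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import ReferenceClustering
from .expression import ExpressionMatrix
from .ontology import ASPECTS, AnnotationSet, OntologyGraph

__all__ = [
    "SyntheticConfig",
    "simulate_reference",
    "simulate_expression",
    "simulate_ontology",
    "simulate_annotations",
    "write_obo",
    "write_gaf",
    "write_reference_table",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    Defaults emulate a small cluster-structured time-course screen:
    120 genes in 4 planted clusters over 20 time points, Gaussian
    expression noise of 0.1 (profiles have amplitude 1), 10% annotation
    noise, no overlap and no unannotated genes unless requested.
    """

    n_genes: int = 120
    n_clusters: int = 4
    n_timepoints: int = 20
    overlap_prob: float = 0.0
    noise_sd: float = 0.1
    annot_noise: float = 0.1
    annot_missing: float = 0.0
    terms_per_cluster: int = 6
    missing_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("overlap_prob", "annot_noise", "annot_missing", "missing_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.n_genes >= self.n_clusters >= 2:
            raise ValueError("need n_genes >= n_clusters >= 2")
        if self.n_timepoints < 3:
            raise ValueError("need n_timepoints >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.terms_per_cluster < 1:
            raise ValueError("terms_per_cluster must be >= 1")

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def cluster_names(self) -> list[str]:
        return [f"C{w + 1}" for w in range(self.n_clusters)]


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generator
    return np.random.default_rng([cfg.seed, stream])


def simulate_reference(cfg: SyntheticConfig) -> ReferenceClustering:
    """Planted multi-membership reference clusters.

    Every gene gets one primary cluster by balanced round-robin; with
    probability ``overlap_prob`` it additionally joins one other cluster.
    """
    rng = _rng(cfg, 1)
    W = cfg.n_clusters
    Y = np.zeros((cfg.n_genes, W), dtype=bool)
    for i in range(cfg.n_genes):
        primary = i % W
        Y[i, primary] = True
        if rng.random() < cfg.overlap_prob:
            extra = int(rng.integers(W - 1))
            Y[i, extra if extra < primary else extra + 1] = True
    return ReferenceClustering(cfg.gene_ids(), cfg.cluster_names(), Y)


def cluster_prototypes(cfg: SyntheticConfig) -> np.ndarray:
    """Sinusoids of period L and amplitude 1 with cluster-specific phase."""
    t = np.arange(cfg.n_timepoints)
    phases = 2 * np.pi * np.arange(cfg.n_clusters) / cfg.n_clusters
    return np.sin(2 * np.pi * t[None, :] / cfg.n_timepoints + phases[:, None])


def simulate_expression(ref: ReferenceClustering, cfg: SyntheticConfig) -> ExpressionMatrix:
    """Cluster-structured log-ratio time courses with additive Gaussian noise.

    A gene's mean profile is the average of its clusters' prototypes;
    with ``missing_prob`` > 0, entries are knocked out at random to
    exercise imputation.
    """
    rng = _rng(cfg, 2)
    protos = cluster_prototypes(cfg)
    Yf = ref.Y.astype(float)
    means = (Yf @ protos) / Yf.sum(axis=1, keepdims=True)
    values = means + rng.normal(0.0, cfg.noise_sd, means.shape)
    mask = rng.random(values.shape) < cfg.missing_prob
    values = np.where(mask, np.nan, values)
    return ExpressionMatrix(ref.gene_ids, values, mask)


def _aspect_term_id(aspect_idx: int, n: int) -> str:
    return f"GO:{aspect_idx + 1:02d}{n:05d}"


def simulate_ontology(cfg: SyntheticConfig) -> OntologyGraph:
    """A small typed DAG per GO aspect.

    Each aspect gets one root, one subtree head per planted cluster, and
    ``terms_per_cluster`` descendants per head chained to random earlier
    terms of the same subtree; roughly 20% of edges are part-of and some
    terms get a second parent, so best-over-paths S-value logic is
    exercised.
    """
    rng = _rng(cfg, 3)
    terms: dict[str, tuple[str, str]] = {}
    edges: set[tuple[str, str, str]] = set()
    namespaces = dict(zip(ASPECTS, range(len(ASPECTS))))
    for aspect, a_idx in namespaces.items():
        root = _aspect_term_id(a_idx, 0)
        terms[root] = (f"{aspect} root", aspect)
        counter = 1
        for w in range(cfg.n_clusters):
            head = _aspect_term_id(a_idx, counter)
            counter += 1
            terms[head] = (f"{aspect} cluster {w + 1} head", aspect)
            edges.add((head, root, "is_a"))
            subtree = [head]
            for d in range(cfg.terms_per_cluster):
                term = _aspect_term_id(a_idx, counter)
                counter += 1
                terms[term] = (f"{aspect} cluster {w + 1} term {d + 1}", aspect)
                parent = subtree[int(rng.integers(len(subtree)))]
                rel = "part_of" if rng.random() < 0.2 else "is_a"
                edges.add((term, parent, rel))
                if len(subtree) > 1 and rng.random() < 0.25:
                    # second parent: a diamond toward the subtree head
                    other = subtree[int(rng.integers(len(subtree)))]
                    if other != parent:
                        rel2 = "part_of" if rng.random() < 0.2 else "is_a"
                        edges.add((term, other, rel2))
                subtree.append(term)
    return OntologyGraph(terms, edges)


def _subtree_terms(graph: OntologyGraph, cfg: SyntheticConfig) -> dict[str, dict[int, list[str]]]:
    """Per aspect, per cluster index, the sorted terms of that cluster's subtree."""
    out: dict[str, dict[int, list[str]]] = {a: {} for a in ASPECTS}
    for term, (name, aspect) in graph.terms.items():
        if " cluster " not in name:
            continue
        w = int(name.split(" cluster ")[1].split(" ")[0]) - 1
        out[aspect].setdefault(w, []).append(term)
    for aspect in out:
        for w in out[aspect]:
            out[aspect][w].sort()
    return out


def simulate_annotations(
    ref: ReferenceClustering, graph: OntologyGraph, cfg: SyntheticConfig
) -> AnnotationSet:
    """Cluster-coherent annotations with noise and missingness.

    Each annotated gene receives 1-3 terms per aspect drawn from the
    subtrees of its reference clusters; with probability ``annot_noise``
    a drawn term is replaced by a uniformly random term of the same
    aspect, and a fraction ``annot_missing`` of genes (exact count)
    receives no annotations at all.
    """
    rng = _rng(cfg, 4)
    pools = _subtree_terms(graph, cfg)
    all_terms = {a: sorted(t for t, (_, asp) in graph.terms.items() if asp == a) for a in ASPECTS}
    n_missing = int(round(cfg.annot_missing * len(ref.gene_ids)))
    missing = set(
        rng.choice(len(ref.gene_ids), size=n_missing, replace=False).tolist()
        if n_missing
        else []
    )
    ann = AnnotationSet()
    for i, gene in enumerate(ref.gene_ids):
        if i in missing:
            continue
        clusters = np.where(ref.Y[i])[0]
        for aspect in ASPECTS:
            pool = sorted(set().union(*(pools[aspect].get(int(w), []) for w in clusters)))
            if not pool:
                continue
            n_terms = int(rng.integers(1, min(3, len(pool)) + 1))
            drawn = rng.choice(len(pool), size=n_terms, replace=False)
            for d in drawn:
                term = pool[int(d)]
                if rng.random() < cfg.annot_noise:
                    term = all_terms[aspect][int(rng.integers(len(all_terms[aspect])))]
                ann.add(gene, aspect, term)
    return ann


# ---------------------------------------------------------------------------
# writers (same dialects as the package readers)

_ASPECT_TO_NAMESPACE = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}
_ASPECT_TO_GAF = {"BP": "P", "MF": "F", "CC": "C"}


def write_obo(graph: OntologyGraph, path) -> None:
    """Write the ontology as OBO 1.2 [Term] stanzas."""
    parents: dict[str, list[tuple[str, str]]] = {t: [] for t in graph.terms}
    for child, parent, rel in sorted(graph.edges):
        parents[child].append((parent, rel))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(graph.terms):
            name, aspect = graph.terms[term]
            fh.write(f"\n[Term]\nid: {term}\nname: {name}\n")
            fh.write(f"namespace: {_ASPECT_TO_NAMESPACE[aspect]}\n")
            for alias, canonical in sorted(graph.alt_id_map.items()):
                if canonical == term:
                    fh.write(f"alt_id: {alias}\n")
            for parent, rel in parents[term]:
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
        fh.write("\n[Typedef]\nid: part_of\nname: part of\n")


def write_gaf(ann: AnnotationSet, path, taxon: str = "taxon:4932") -> None:
    """Write annotations as a 17-column GAF 2.2 file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in ann.genes():
            for aspect in ASPECTS:
                for term in sorted(ann.terms_for(gene, aspect)):
                    cols = [
                        "SYN",  # DB
                        gene,  # DB Object ID
                        gene,  # DB Object Symbol
                        "involved_in",  # Qualifier
                        term,  # GO ID
                        "SYN_REF:0000001",  # DB:Reference
                        "IEA",  # Evidence Code
                        "",  # With/From
                        _ASPECT_TO_GAF[aspect],  # Aspect
                        gene,  # DB Object Name
                        "",  # Synonym
                        "gene",  # DB Object Type
                        taxon,  # Taxon
                        "20080225",  # Date
                        "SYN",  # Assigned By
                        "",  # Annotation Extension
                        "",  # Gene Product Form ID
                    ]
                    fh.write("\t".join(cols) + "\n")


def write_reference_table(ref: ReferenceClustering, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tcluster\n")
        for i, gene in enumerate(ref.gene_ids):
            for j in np.where(ref.Y[i])[0]:
                fh.write(f"{gene}\t{ref.cluster_names[j]}\n")
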