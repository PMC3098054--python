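"""Gene Ontology structure, annotations, and the semantic-similarity constraint.

The second clustering constraint scores gene pairs by how semantically
close their GO annotations are, following Wang-style graph-based term
similarity: each term ``c`` induces the sub-DAG of its ancestors, every
ancestor ``t`` receives an S-value — the best product of per-edge
semantic contribution factors (0.8 for is-a, 0.6 for part-of) over
upward paths from ``c`` to ``t`` — and two terms are compared through
the S-values of their shared ancestors.  Gene-level similarity is the
best-match average over the two genes' term sets, computed per GO aspect
(BP, MF, CC) and combined as the unweighted mean over the aspects where
both genes carry at least one annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet
import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "ASPECTS",
    "DEFAULT_EDGE_WEIGHTS",
    "OntologyGraph",
    "AnnotationSet",
    "parse_obo",
    "parse_gaf",
    "ancestor_closure",
    "s_values",
    "semantic_value",
    "term_similarity",
    "term_set_similarity",
    "gene_go_similarity_matrix",
]

logger = logging.getLogger(__name__)

ASPECTS = ("BP", "MF", "CC")

_NAMESPACE_TO_ASPECT = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}

#: Semantic contribution factor per edge relation.
DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}

_KEPT_RELATIONS = frozenset(DEFAULT_EDGE_WEIGHTS)


@dataclass
class OntologyGraph:
    """Typed GO DAG restricted to non-obsolete terms and is-a/part-of edges.

    ``terms`` maps term id -> (name, aspect); ``edges`` is a set of
    (child_id, parent_id, relation) triples; ``alt_id_map`` resolves
    aliases to canonical ids.
    """

    terms: dict[str, tuple[str, str]]
    edges: set[tuple[str, str, str]]
    alt_id_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, parent, rel in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge ({child}, {parent}) references unknown term")
            if rel not in _KEPT_RELATIONS:
                raise ValueError(f"unsupported relation {rel!r}")
        g = self.digraph()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[0][0]}"
            raise ValueError(f"ontology contains a cycle: {path}")

    def digraph(self) -> nx.DiGraph:
        """Child -> parent DiGraph; parallel relations merged, keeping both types."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent, rel in self.edges:
            if g.has_edge(child, parent):
                g[child][parent]["relations"].add(rel)
            else:
                g.add_edge(child, parent, relations={rel})
        return g

    def resolve(self, term_id: str) -> str | None:
        """Canonical id for a term or alt_id; None if unknown."""
        if term_id in self.terms:
            return term_id
        return self.alt_id_map.get(term_id)

    def aspect(self, term_id: str) -> str:
        return self.terms[term_id][1]


@dataclass
class AnnotationSet:
    """Mapping gene id -> aspect -> set of annotated GO term ids."""

    mapping: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def add(self, gene: str, aspect: str, term: str) -> None:
        self.mapping.setdefault(gene, {}).setdefault(aspect, set()).add(term)

    def genes(self) -> list[str]:
        return sorted(self.mapping)

    def terms_for(self, gene: str, aspect: str) -> frozenset[str]:
        return frozenset(self.mapping.get(gene, {}).get(aspect, ()))

    def aspects_for(self, gene: str) -> list[str]:
        return [a for a in ASPECTS if self.mapping.get(gene, {}).get(a)]

    def without_genes(self, genes) -> "AnnotationSet":
        """A copy with all annotations of ``genes`` deleted (for cross-validation)."""
        drop = set(genes)
        return AnnotationSet(
            {
                g: {a: set(ts) for a, ts in asp.items()}
                for g, asp in self.mapping.items()
                if g not in drop
            }
        )


def _scan_stanza_ids(path) -> None:
    """Pre-scan [Term] stanzas so a missing id is reported with its index."""
    stanza = 0
    in_term = False
    has_id = True
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("["):
                if in_term and not has_id:
                    raise ValueError(f"[Term] stanza #{stanza} has no id")
                in_term = line == "[Term]"
                if in_term:
                    stanza += 1
                    has_id = False
            elif in_term and line.startswith("id:"):
                has_id = True
    if in_term and not has_id:
        raise ValueError(f"[Term] stanza #{stanza} has no id")


def parse_obo(path) -> OntologyGraph:
    """Parse an OBO 1.2 ontology into a typed DAG.

    Obsolete terms are dropped, alt_ids recorded, and relationship types
    other than is-a/part-of discarded (with a logged count).  A directed
    cycle among the retained edges is a hard error.
    """
    _scan_stanza_ids(path)
    raw = obonet.read_obo(path, ignore_obsolete=True)
    terms: dict[str, tuple[str, str]] = {}
    alt_id_map: dict[str, str] = {}
    n_bad_namespace = 0
    for node, data in raw.nodes(data=True):
        namespace = data.get("namespace")
        aspect = _NAMESPACE_TO_ASPECT.get(namespace)
        if aspect is None:
            if data:  # bare nodes created by dangling edges carry no data
                n_bad_namespace += 1
            continue
        terms[node] = (data.get("name", node), aspect)
        for alias in data.get("alt_id", []):
            alt_id_map[alias] = node
    if n_bad_namespace:
        logger.warning("dropped %d term(s) with unknown namespace", n_bad_namespace)
    edges: set[tuple[str, str, str]] = set()
    n_dropped_rel = 0
    n_dangling = 0
    for child, parent, rel in raw.edges(keys=True):
        if rel not in _KEPT_RELATIONS:
            n_dropped_rel += 1
            continue
        if child not in terms or parent not in terms:
            n_dangling += 1
            continue
        edges.add((child, parent, rel))
    if n_dropped_rel:
        logger.info("dropped %d edge(s) with unsupported relation types", n_dropped_rel)
    if n_dangling:
        logger.warning("dropped %d edge(s) with missing endpoints", n_dangling)
    return OntologyGraph(terms, edges, alt_id_map)


def parse_gaf(path, graph: OntologyGraph, exclude_evidence=()) -> AnnotationSet:
    """Parse a GAF 2.x annotation file against an ontology.

    Rows whose qualifier contains NOT are skipped, GO ids are resolved
    through alt_ids, ids absent from the graph are skipped (logged), and
    all evidence codes are kept unless listed in ``exclude_evidence``.
    """
    exclude = set(exclude_evidence)
    ann = AnnotationSet()
    n_unknown = 0
    n_not = 0
    n_excluded = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise ValueError(
                    f"{path}: line {lineno} has {len(cols)} columns, expected >= 15"
                )
            symbol, qualifier, go_id = cols[2], cols[3], cols[4]
            evidence, aspect_code = cols[6], cols[8]
            if "NOT" in qualifier.split("|"):
                n_not += 1
                continue
            if evidence in exclude:
                n_excluded += 1
                continue
            term = graph.resolve(go_id)
            if term is None:
                n_unknown += 1
                continue
            aspect = _GAF_ASPECT.get(aspect_code)
            if aspect is None:
                aspect = graph.aspect(term)
            ann.add(symbol, aspect, term)
    if n_unknown:
        logger.warning("skipped %d annotation(s) with GO ids absent from graph", n_unknown)
    if n_not:
        logger.info("skipped %d NOT-qualified annotation(s)", n_not)
    if n_excluded:
        logger.info("skipped %d annotation(s) by evidence code", n_excluded)
    return ann


def ancestor_closure(graph: OntologyGraph, c: str) -> set[str]:
    """The term ``c`` together with all its ancestors (either relation)."""
    g = graph.digraph()
    if c not in g:
        raise KeyError(f"unknown term {c!r}")
    return {c} | nx.descendants(g, c)


def s_values(
    graph: OntologyGraph, c: str, edge_weights: dict[str, float] | None = None
) -> dict[str, float]:
    """S-values of every ancestor of ``c``: S_c(c) = 1 and

    S_c(t) = max over child edges (t' -> t) within the ancestor DAG of
    w_rel * S_c(t'), i.e. the best product of semantic contribution
    factors over upward paths from ``c`` to ``t``.
    """
    w = DEFAULT_EDGE_WEIGHTS if edge_weights is None else edge_weights
    g = graph.digraph()
    if c not in g:
        raise KeyError(f"unknown term {c!r}")
    closure = {c} | nx.descendants(g, c)
    sub = g.subgraph(closure)
    s: dict[str, float] = {}
    for t in nx.topological_sort(sub):  # children before parents
        if t == c:
            s[t] = 1.0
            continue
        s[t] = max(
            max(w[rel] for rel in sub[child][t]["relations"]) * s[child]
            for child in sub.predecessors(t)
        )
    return s


def semantic_value(
    graph: OntologyGraph, c: str, edge_weights: dict[str, float] | None = None
) -> float:
    """SV(c): the sum of S-values over the ancestor closure of ``c`` (>= 1)."""
    return sum(s_values(graph, c, edge_weights).values())


def term_similarity(
    graph: OntologyGraph,
    c1: str,
    c2: str,
    edge_weights: dict[str, float] | None = None,
) -> float:
    """Semantic similarity of two terms via their shared ancestors:

    S_GO(c1, c2) = sum over t in T_c1 ∩ T_c2 of (S_c1(t) + S_c2(t)),
    divided by (SV(c1) + SV(c2)); 0 when the ancestor sets are disjoint.
    """
    s1 = s_values(graph, c1, edge_weights)
    s2 = s_values(graph, c2, edge_weights)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    num = sum(s1[t] + s2[t] for t in common)
    return num / (sum(s1.values()) + sum(s2.values()))


def term_set_similarity(
    graph: OntologyGraph,
    set1,
    set2,
    edge_weights: dict[str, float] | None = None,
    _pair_sim=None,
) -> float:
    """Best-match-average functional similarity between two term sets.

    Each term's best match in the other set is averaged over both
    directions: (sum of row maxima + sum of column maxima) / (|set1| + |set2|).
    """
    set1, set2 = list(set1), list(set2)
    if not set1 or not set2:
        raise ValueError("term sets must be non-empty (mask the pair instead)")
    if _pair_sim is None:
        cache: dict[frozenset, float] = {}

        def _pair_sim(a, b):
            key = frozenset((a, b))
            if key not in cache:
                cache[key] = term_similarity(graph, a, b, edge_weights)
            return cache[key]

    sims = np.array([[_pair_sim(a, b) for b in set2] for a in set1])
    return (sims.max(axis=1).sum() + sims.max(axis=0).sum()) / (len(set1) + len(set2))


def gene_go_similarity_matrix(
    graph: OntologyGraph,
    ann: AnnotationSet,
    gene_ids,
    edge_weights: dict[str, float] | None = None,
) -> SimilarityMatrix:
    """Joint BP/MF/CC gene-pair similarity matrix.

    For each gene pair the per-aspect best-match-average similarity is
    computed over the aspects where BOTH genes have at least one
    annotation, then combined as the unweighted mean of those aspect
    values.  Pairs sharing no annotated aspect are masked undefined; the
    diagonal is 1 for annotated genes and masked for unannotated ones.
    """
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    # memoized S-value maps per term; term-pair similarity cache
    s_cache: dict[str, dict[str, float]] = {}
    sv_cache: dict[str, float] = {}

    def _svals(t):
        if t not in s_cache:
            s_cache[t] = s_values(graph, t, edge_weights)
            sv_cache[t] = sum(s_cache[t].values())
        return s_cache[t]

    pair_cache: dict[frozenset, float] = {}

    def _pair_sim(a, b):
        key = frozenset((a, b))
        if key not in pair_cache:
            s1, s2 = _svals(a), _svals(b)
            common = s1.keys() & s2.keys()
            pair_cache[key] = (
                sum(s1[t] + s2[t] for t in common) / (sv_cache[a] + sv_cache[b])
                if common
                else 0.0
            )
        return pair_cache[key]

    term_sets = {
        g: {a: sorted(ann.terms_for(g, a)) for a in ASPECTS if ann.terms_for(g, a)}
        for g in gene_ids
    }
    unannotated = [g for g in gene_ids if not term_sets[g]]
    if unannotated:
        logger.info("%d gene(s) without annotations have masked GO rows", len(unannotated))
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i, gi in enumerate(gene_ids):
        if term_sets[gi]:
            values[i, i] = 1.0
            mask[i, i] = True
        for j in range(i + 1, n):
            gj = gene_ids[j]
            shared = [a for a in term_sets[gi] if a in term_sets[gj]]
            if not shared:
                continue
            v = float(
                np.mean(
                    [
                        term_set_similarity(
                            graph,
                            term_sets[gi][a],
                            term_sets[gj][a],
                            edge_weights,
                            _pair_sim=_pair_sim,
                        )
                        for a in shared
                    ]
                )
            )
            v = min(v, 1.0)
            values[i, j] = values[j, i] = v
            mask[i, j] = mask[j, i] = True
    return SimilarityMatrix(gene_ids, values, mask, kind="go")
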