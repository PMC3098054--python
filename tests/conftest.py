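import numpy as np
import pytest

from mgclust import (
    OntologyGraph,
    SyntheticConfig,
    expression_similarity,
    gene_go_similarity_matrix,
    impute_missing,
    simulate_annotations,
    simulate_expression,
    simulate_ontology,
    simulate_reference,
)


@pytest.fixture
def chain_graph():
    """c --is_a--> p: the smallest non-trivial ancestor chain."""
    return OntologyGraph(
        terms={"c": ("child", "BP"), "p": ("parent", "BP")},
        edges={("c", "p", "is_a")},
    )


@pytest.fixture
def diamond_graph():
    """c reaches root r via an is-a path (c->p1->r) and a part-of path (c->p2->r)."""
    return OntologyGraph(
        terms={
            "c": ("child", "BP"),
            "p1": ("left parent", "BP"),
            "p2": ("right parent", "BP"),
            "r": ("root", "BP"),
        },
        edges={
            ("c", "p1", "is_a"),
            ("p1", "r", "is_a"),
            ("c", "p2", "part_of"),
            ("p2", "r", "part_of"),
        },
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small complete synthetic dataset shared by pipeline-level tests."""
    cfg = SyntheticConfig(n_genes=40, n_clusters=4, n_timepoints=12, seed=7)
    ref = simulate_reference(cfg)
    graph = simulate_ontology(cfg)
    ann = simulate_annotations(ref, graph, cfg)
    expr = impute_missing(simulate_expression(ref, cfg))
    return {
        "cfg": cfg,
        "ref": ref,
        "graph": graph,
        "ann": ann,
        "expr": expr,
        "expr_sim": expression_similarity(expr),
        "go_sim": gene_go_similarity_matrix(graph, ann, expr.gene_ids),
    }


def random_dag(rng, max_terms=30):
    """Random typed DAG: each term's parents have strictly lower index."""
    n = int(rng.integers(3, max_terms + 1))
    terms = {f"T{i}": (f"term {i}", "BP") for i in range(n)}
    edges = set()
    for i in range(1, n):
        n_parents = int(rng.integers(1, min(i, 2) + 1))
        parents = rng.choice(i, size=n_parents, replace=False)
        for p in parents:
            rel = "part_of" if rng.random() < 0.3 else "is_a"
            edges.add((f"T{i}", f"T{int(p)}", rel))
    return OntologyGraph(terms, edges)


def s_value_oracle(graph, c, weights=None):
    """Brute-force S-values: max product of edge factors over ALL directed paths."""
    from mgclust import DEFAULT_EDGE_WEIGHTS

    w = weights or DEFAULT_EDGE_WEIGHTS
    out = {c: 1.0}
    up = {}
    for child, parent, rel in graph.edges:
        up.setdefault(child, []).append((parent, w[rel]))

    def dfs(node, product):
        for parent, factor in up.get(node, []):
            p = product * factor
            if p > out.get(parent, 0.0):
                out[parent] = p
            dfs(parent, p)

    dfs(c, 1.0)
    return out
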