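import random

import pytest

from sbmlpatterns.graphs import (
    HAS_PRODUCT,
    IS_MODIFIER,
    IS_REACTANT,
    LabelledDigraph,
    Network,
    NetworkSet,
    NodeLabel,
    REACTION,
    SPECIES,
)

REACTION_LABEL = NodeLabel(REACTION)
SPECIES_LABEL = NodeLabel(SPECIES)


def random_network(
    rng: random.Random,
    n_species: int = 4,
    n_reactions: int = 3,
    n_edges: int = 6,
    sbo_terms=None,
) -> LabelledDigraph:
    """A random valid bipartite reaction graph (may be disconnected)."""
    nodes = {}
    for i in range(n_species):
        term = rng.choice(sbo_terms[SPECIES]) if sbo_terms else None
        nodes[f"s{i}"] = NodeLabel(SPECIES, term)
    for i in range(n_reactions):
        term = rng.choice(sbo_terms[REACTION]) if sbo_terms else None
        nodes[f"r{i}"] = NodeLabel(REACTION, term)
    edges = set()
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * n_edges:
        attempts += 1
        s = f"s{rng.randrange(n_species)}"
        r = f"r{rng.randrange(n_reactions)}"
        role = rng.choice([IS_REACTANT, IS_MODIFIER, HAS_PRODUCT])
        edge = (r, s, role) if role == HAS_PRODUCT else (s, r, role)
        edges.add(edge)
    g = LabelledDigraph(nodes, edges)
    # keep only nodes that participate, so components stay meaningful
    used = {n for e in edges for n in (e[0], e[1])}
    if used:
        g = LabelledDigraph({n: nodes[n] for n in used}, edges)
    return g


def random_connected_network(rng, n_species=4, n_reactions=3, n_edges=6):
    """Largest weakly connected component of a random network."""
    from sbmlpatterns.graphs import split_components

    g = random_network(rng, n_species, n_reactions, n_edges)
    comps = split_components(g, "tmp")
    if len(comps) == 0:
        return random_connected_network(rng, n_species, n_reactions, n_edges)
    best = max(comps, key=lambda net: net.graph.n_nodes)
    return best.graph


def make_network_set(graphs) -> NetworkSet:
    return NetworkSet(
        [Network(g, f"m{i}", 1) for i, g in enumerate(graphs)]
    )


@pytest.fixture
def rng():
    return random.Random(20240901)


@pytest.fixture
def cdc2k_tuples():
    """The two-participation worked example: a shared species between
    a dephosphorylation (product role) and a phosphorylation (reactant role)."""
    return {
        ("100233", "HAS_PRODUCT", "100186"),
        ("100229", "HAS_REACTANT", "100186"),
    }
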