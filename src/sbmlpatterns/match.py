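"""Injective embedding search for labelled digraph patterns.

An embedding of a pattern into a network is an injective node mapping
that preserves node labels, edge presence, edge direction and edge
labels (non-induced: the network may have extra edges among the mapped
nodes).  This is the subgraph-isomorphism primitive every frequent
subgraph miner rests on; counting all embeddings mirrors the row count
of a graph-database query with pairwise node-inequality constraints, so
automorphic re-assignments count separately.
"""

from __future__ import annotations

from typing import Iterator, Optional, Sequence

from .graphs import LabelledDigraph


def _search_order(pattern: LabelledDigraph) -> list[str]:
    """Order pattern nodes so each (after the first) touches a previous one.

    Highest-degree node first, then greedy by connectivity to the placed
    prefix — keeps the backtracking frontier connected, which lets edge
    constraints prune immediately.
    """
    if pattern.n_nodes == 0:
        return []
    deg: dict[str, int] = {n: 0 for n in pattern.nodes}
    adj: dict[str, set[str]] = {n: set() for n in pattern.nodes}
    for s, t, _ in pattern.edges:
        deg[s] += 1
        deg[t] += 1
        adj[s].add(t)
        adj[t].add(s)
    order = [max(pattern.nodes, key=lambda n: (deg[n], n))]
    placed = set(order)
    while len(order) < pattern.n_nodes:
        frontier = [n for n in pattern.nodes if n not in placed and adj[n] & placed]
        if not frontier:  # disconnected pattern: start a new component
            frontier = [n for n in pattern.nodes if n not in placed]
        nxt = max(frontier, key=lambda n: (len(adj[n] & placed), deg[n], n))
        order.append(nxt)
        placed.add(nxt)
    return order


def iter_embeddings(
    pattern: LabelledDigraph, g: LabelledDigraph
) -> Iterator[dict[str, str]]:
    """Yield every injective label/direction-preserving embedding pattern -> g."""
    if pattern.n_nodes == 0 or pattern.n_nodes > g.n_nodes:
        return
    order = _search_order(pattern)
    # Graph candidates per label, and adjacency sets for O(1) edge checks.
    by_label: dict[object, list[str]] = {}
    for nid, lab in g.nodes.items():
        by_label.setdefault(lab, []).append(nid)
    for lst in by_label.values():
        lst.sort()
    gedges = g.edges
    # Pattern edge constraints between order[k] and earlier nodes.
    constraints: list[list[tuple[str, bool, str]]] = []
    pos = {n: k for k, n in enumerate(order)}
    for k, pn in enumerate(order):
        cons = []
        for s, t, lab in pattern.edges:
            if s == pn and pos[t] < k:
                cons.append((t, True, lab))   # mapped(pn) -> mapped(t)
            elif t == pn and pos[s] < k:
                cons.append((s, False, lab))  # mapped(s) -> mapped(pn)
        constraints.append(cons)
    # Degree pre-filter on the graph side.
    gdeg: dict[str, int] = {n: 0 for n in g.nodes}
    for s, t, _ in gedges:
        gdeg[s] += 1
        gdeg[t] += 1
    pdeg: dict[str, int] = {n: 0 for n in pattern.nodes}
    for s, t, _ in pattern.edges:
        pdeg[s] += 1
        pdeg[t] += 1

    mapping: dict[str, str] = {}
    used: set[str] = set()

    def backtrack(k: int) -> Iterator[dict[str, str]]:
        if k == len(order):
            yield dict(mapping)
            return
        pn = order[k]
        for cand in by_label.get(pattern.nodes[pn], ()):
            if cand in used or gdeg[cand] < pdeg[pn]:
                continue
            ok = True
            for other, outgoing, lab in constraints[k]:
                m = mapping[other]
                edge = (cand, m, lab) if outgoing else (m, cand, lab)
                if edge not in gedges:
                    ok = False
                    break
            if ok:
                mapping[pn] = cand
                used.add(cand)
                yield from backtrack(k + 1)
                used.discard(cand)
                del mapping[pn]

    yield from backtrack(0)


def supports(pattern: LabelledDigraph, g: LabelledDigraph) -> bool:
    """True iff at least one injective embedding of *pattern* into *g* exists."""
    return next(iter_embeddings(pattern, g), None) is not None


def count_embeddings(
    pattern: LabelledDigraph, model_networks: Sequence[LabelledDigraph]
) -> int:
    """Raw injective assignment count of *pattern* summed over a model's networks.

    Automorphic re-assignments count separately, mirroring the row count
    of the generated distribution query.
    """
    return sum(1 for net in model_networks for _ in iter_embeddings(pattern, net))


def automorphism_count(pattern: LabelledDigraph) -> int:
    """|Aut(pattern)|: embeddings of the pattern into itself."""
    return count_embeddings(pattern, [pattern])


def count_orbits(
    pattern: LabelledDigraph, model_networks: Sequence[LabelledDigraph]
) -> int:
    """Embedding count quotiented by pattern automorphisms (distinct occurrences)."""
    aut = automorphism_count(pattern)
    raw = count_embeddings(pattern, model_networks)
    assert raw % aut == 0
    return raw // aut
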