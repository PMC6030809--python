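"""Independent brute-force oracles for the test suite.

Everything here is deliberately naive — permutation enumeration and
exhaustive subgraph generation — and shares no code with the package's
canonical-form, matching or mining machinery, so it can serve as ground
truth for them.
"""

from itertools import permutations

import networkx as nx
from networkx.algorithms.isomorphism import DiGraphMatcher

from sbmlpatterns.graphs import LabelledDigraph


def brute_canonical_form(g: LabelledDigraph):
    """Canonical form by minimisation over all node orderings.

    Only feasible for small graphs (≤ 8 nodes); independent of DFS codes.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    best = None
    for perm in permutations(range(n)):
        idx = {nodes[k]: perm[k] for k in range(n)}
        labels = tuple(
            lab for _, lab in sorted(
                ((idx[node], g.nodes[node].sort_key) for node in nodes)
            )
        )
        edges = tuple(sorted((idx[s], idx[t], lab) for s, t, lab in g.edges))
        cand = (labels, edges)
        if best is None or cand < best:
            best = cand
    return best


def brute_count_embeddings(pattern: LabelledDigraph, g: LabelledDigraph) -> int:
    """Count injective embeddings by enumerating all injective assignments."""
    pnodes = sorted(pattern.nodes)
    gnodes = sorted(g.nodes)
    count = 0
    for assignment in permutations(gnodes, len(pnodes)):
        mapping = dict(zip(pnodes, assignment))
        if any(g.nodes[mapping[p]] != pattern.nodes[p] for p in pnodes):
            continue
        if all(
            (mapping[s], mapping[t], lab) in g.edges for s, t, lab in pattern.edges
        ):
            count += 1
    return count


def nx_supports(pattern: LabelledDigraph, g: LabelledDigraph) -> bool:
    """Second independent route: networkx VF2 monomorphism on digraphs with
    edge-label *sets* (parallel differently-labelled edges merged)."""

    def to_nx(graph: LabelledDigraph) -> nx.DiGraph:
        out = nx.DiGraph()
        for nid, lab in graph.nodes.items():
            out.add_node(nid, label=lab)
        for s, t, lab in graph.edges:
            if out.has_edge(s, t):
                out[s][t]["roles"] = out[s][t]["roles"] | {lab}
            else:
                out.add_edge(s, t, roles={lab})
        return out

    matcher = DiGraphMatcher(
        to_nx(g),
        to_nx(pattern),
        node_match=lambda a, b: a["label"] == b["label"],
        edge_match=lambda a, b: b["roles"] <= a["roles"],
    )
    return matcher.subgraph_is_monomorphic()


def _connected_edge_subsets(g: LabelledDigraph, max_edges: int):
    """All connected edge subsets of g with 1..max_edges edges."""
    edges = sorted(g.edges)
    adj = {}
    for e in edges:
        adj.setdefault(e[0], set()).add(e)
        adj.setdefault(e[1], set()).add(e)
    seen = set()
    frontier = [frozenset([e]) for e in edges]
    seen.update(frontier)
    all_sets = list(frontier)
    while frontier:
        nxt = []
        for es in frontier:
            if len(es) >= max_edges:
                continue
            nodes = {n for e in es for n in (e[0], e[1])}
            for node in nodes:
                for e in adj.get(node, ()):
                    if e in es:
                        continue
                    grown = es | {e}
                    if grown not in seen:
                        seen.add(grown)
                        nxt.append(grown)
        all_sets.extend(nxt)
        frontier = nxt
    return all_sets


def enumerate_connected_subgraph_forms(g: LabelledDigraph, max_edges: int):
    """Canonical forms of every connected subgraph of g up to max_edges edges,
    including single-node subgraphs."""
    forms = set()
    for nid, lab in g.nodes.items():
        forms.add(brute_canonical_form(LabelledDigraph({nid: lab})))
    for es in _connected_edge_subsets(g, max_edges):
        nodes = {n for e in es for n in (e[0], e[1])}
        sub = LabelledDigraph({n: g.nodes[n] for n in nodes}, set(es))
        forms.add(brute_canonical_form(sub))
    return forms


def oracle_mine(unit_graphs, min_support, max_support, max_edges):
    """Exhaustive-enumeration miner: canonical form -> support.

    ``unit_graphs`` is a list of lists (one inner list of graphs per
    transaction unit).  Returns only forms within the support interval.
    """
    support: dict = {}
    for graphs in unit_graphs:
        forms = set()
        for g in graphs:
            forms |= enumerate_connected_subgraph_forms(g, max_edges)
        for f in forms:
            support[f] = support.get(f, 0) + 1
    return {
        f: s for f, s in support.items() if min_support <= s <= max_support
    }
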