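"""Canonical DFS codes for labelled digraphs.

A DFS code encodes a graph as the edge sequence of a depth-first
traversal; the lexicographic minimum over all traversals is a canonical
form: two connected labelled digraphs have equal minimum DFS codes iff
they are label-preserving isomorphic.  The classic construction is for
undirected graphs; reaction networks are directed, so each code edge
carries a direction flag (0 when the stored edge runs from the earlier
discovery index to the later one, 1 otherwise) ordered *after* the edge
label in the lexicographic comparison.

A code edge is the 6-tuple ``(i, j, li, le, dir, lj)`` where ``i, j``
are discovery indices, ``li, lj`` node-label sort keys and ``le`` the
edge-label rank.  Forward edges discover a new vertex (``j == max+1``),
backward edges close a cycle back onto the rightmost path.

The minimum code is computed by the standard simultaneous-embedding
search: grow all partial embeddings that realize the current minimal
code prefix, at each round append the globally minimal valid extension
and drop embeddings that cannot realize it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .errors import ContractError
from .graphs import EDGE_LABEL_ORDER, LabelledDigraph, NodeLabel

# A code edge: (i, j, li, le, dir, lj) with li/lj = NodeLabel.sort_key,
# le = EDGE_LABEL_ORDER rank, dir in {0, 1}.
CodeEdge = tuple[int, int, tuple[str, str], int, int, tuple[str, str]]

# A full code: ("N", root label key) for a single node, ("E", edge tuple) otherwise.
DFSCode = tuple


@dataclass(frozen=True)
class _Embedding:
    """A partial DFS embedding: discovery order plus rightmost path."""

    order: tuple[str, ...]          # discovery index -> graph node
    rmp: tuple[int, ...]            # rightmost path as discovery indices
    used: frozenset[tuple[str, str, str]]  # graph edges already encoded

    def node_at(self, idx: int) -> str:
        return self.order[idx]


def _edge_between(g: LabelledDigraph, a: str, b: str) -> Iterable[tuple[str, str, str]]:
    """All stored edges joining nodes *a* and *b* in either orientation."""
    for label in EDGE_LABEL_ORDER:
        if (a, b, label) in g.edges:
            yield (a, b, label)
        if (b, a, label) in g.edges:
            yield (b, a, label)


def _extension_key(is_backward: bool, i: int, j: int, li, le, d, lj):
    """Sort key implementing the gSpan neighbourhood order for one growth round.

    Backward extensions precede forward ones; backward edges sort by
    increasing target index; forward edges by decreasing source index
    (deepest point of the rightmost path first); labels break ties with
    the direction flag ordered after the edge label.
    """
    if is_backward:
        return (0, j, li, le, d, lj)
    return (1, -i, li, le, d, lj)


def minimum_dfs_code(g: LabelledDigraph) -> DFSCode:
    """Compute the canonical (minimum) DFS code of a connected labelled digraph.

    Raises :class:`ContractError` on empty or disconnected input.
    Deterministic; equal codes characterise isomorphism.
    """
    if g.n_nodes == 0:
        raise ContractError("minimum_dfs_code requires a non-empty graph")
    if g.n_edges == 0:
        if g.n_nodes > 1:
            raise ContractError("minimum_dfs_code requires a connected graph")
        (label,) = g.nodes.values()
        return ("N", label.sort_key)

    # Seed one embedding per node; the first round's minimisation selects roots.
    embeddings = [
        _Embedding(order=(n,), rmp=(0,), used=frozenset()) for n in g.nodes
    ]
    code: list[CodeEdge] = []

    while True:
        best_key = None
        best_edge: Optional[CodeEdge] = None
        realizers: list[tuple[_Embedding, tuple, bool, Optional[str]]] = []

        for emb in embeddings:
            placed = {node: idx for idx, node in enumerate(emb.order)}
            rm_node = emb.node_at(emb.rmp[-1])
            # Backward: from the rightmost vertex to a vertex on the rightmost path.
            for j_idx in emb.rmp[:-1]:
                other = emb.node_at(j_idx)
                for e in _edge_between(g, rm_node, other):
                    if e in emb.used:
                        continue
                    src, tgt, label = e
                    d = 0 if src == rm_node else 1
                    ce: CodeEdge = (
                        emb.rmp[-1], j_idx,
                        g.nodes[rm_node].sort_key, EDGE_LABEL_ORDER[label], d,
                        g.nodes[other].sort_key,
                    )
                    key = _extension_key(True, *ce)
                    if best_key is None or key < best_key:
                        best_key, best_edge, realizers = key, ce, []
                    if key == best_key:
                        realizers.append((emb, e, True, None))
            # Forward: from any vertex on the rightmost path to an unplaced node.
            new_idx = len(emb.order)
            for i_idx in emb.rmp:
                anchor = emb.node_at(i_idx)
                for e in g.incident(anchor):
                    src, tgt, label = e
                    other = tgt if src == anchor else src
                    if other in placed or e in emb.used:
                        continue
                    d = 0 if src == anchor else 1
                    ce = (
                        i_idx, new_idx,
                        g.nodes[anchor].sort_key, EDGE_LABEL_ORDER[label], d,
                        g.nodes[other].sort_key,
                    )
                    key = _extension_key(False, *ce)
                    if best_key is None or key < best_key:
                        best_key, best_edge, realizers = key, ce, []
                    if key == best_key:
                        realizers.append((emb, e, False, other))

        if best_edge is None:
            break
        code.append(best_edge)

        next_embeddings = []
        seen: set[tuple] = set()
        for emb, e, is_backward, new_node in realizers:
            if is_backward:
                new_emb = replace(emb, used=emb.used | {e})
            else:
                i_idx = best_edge[0]
                pos = emb.rmp.index(i_idx)
                new_emb = _Embedding(
                    order=emb.order + (new_node,),
                    rmp=emb.rmp[: pos + 1] + (len(emb.order),),
                    used=emb.used | {e},
                )
            sig = (new_emb.order, new_emb.rmp, new_emb.used)
            if sig not in seen:
                seen.add(sig)
                next_embeddings.append(new_emb)
        embeddings = next_embeddings

    if len(code) != g.n_edges:
        raise ContractError("minimum_dfs_code requires a connected graph")
    return ("E", tuple(code))


def code_node_count(code: DFSCode) -> int:
    if code[0] == "N":
        return 1
    return 1 + max(max(i, j) for i, j, *_ in code[1])


def graph_from_code(code: DFSCode, name_prefix: str = "Node_") -> LabelledDigraph:
    """Materialise the pattern graph of a DFS code.

    Node identifiers follow discovery order (``Node_0``, ``Node_1``, ...),
    which is the naming used in mined-pattern output files.
    """
    inv_edge_order = {v: k for k, v in EDGE_LABEL_ORDER.items()}
    g = LabelledDigraph()
    if code[0] == "N":
        kind, term = code[1]
        g.add_node(f"{name_prefix}0", NodeLabel(kind, term or None))
        return g
    for (i, j, li, le, d, lj) in code[1]:
        for idx, key in ((i, li), (j, lj)):
            nid = f"{name_prefix}{idx}"
            if nid not in g.nodes:
                kind, term = key
                g.add_node(nid, NodeLabel(kind, term or None))
        src, tgt = (f"{name_prefix}{i}", f"{name_prefix}{j}") if d == 0 else (
            f"{name_prefix}{j}", f"{name_prefix}{i}")
        g.edges.add((src, tgt, inv_edge_order[le]))
    g._validate()
    return g


def is_isomorphic(a: LabelledDigraph, b: LabelledDigraph) -> bool:
    """Label-preserving digraph isomorphism via canonical-code equality."""
    if a.n_nodes != b.n_nodes or a.n_edges != b.n_edges:
        return False
    return minimum_dfs_code(a) == minimum_dfs_code(b)
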