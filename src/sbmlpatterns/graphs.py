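"""Labelled bipartite reaction digraphs.

A reaction network is a directed bipartite graph: species and reaction
nodes, with edges labelled by the role a species plays in a reaction.
Reactants and modifiers point *into* a reaction, products point *out*
of it, so edge direction follows the flow of matter / influence:

    species --IS_REACTANT-->  reaction
    species --IS_MODIFIER-->  reaction
    reaction --HAS_PRODUCT--> species

The raw export format instead lists participations as three-tuples
``(reaction, HAS_REACTANT | HAS_MODIFIER | HAS_PRODUCT, species)`` with
the reaction always first; :func:`orient_edges` performs the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx

from .errors import DataError

# Node kinds
REACTION = "SBML_REACTION"
SPECIES = "SBML_SPECIES"

# Edge labels (graph roles)
IS_REACTANT = "IS_REACTANT"
IS_MODIFIER = "IS_MODIFIER"
HAS_PRODUCT = "HAS_PRODUCT"
EDGE_LABELS = (IS_REACTANT, IS_MODIFIER, HAS_PRODUCT)

# Export roles (tuple dialect; reaction-first orientation)
HAS_REACTANT = "HAS_REACTANT"
HAS_MODIFIER = "HAS_MODIFIER"
EXPORT_ROLES = (HAS_REACTANT, HAS_MODIFIER, HAS_PRODUCT)

# Fixed total order on edge labels used by the canonical DFS code.
EDGE_LABEL_ORDER = {IS_REACTANT: 0, IS_MODIFIER: 1, HAS_PRODUCT: 2}


@dataclass(frozen=True, order=True)
class NodeLabel:
    """Label of a network node: its kind, plus an SBO term in semantics-aware mode.

    Label equality (and hence pattern isomorphism) is equality of the
    ``(kind, sbo_term)`` pair.  In structural mode ``sbo_term`` is None.
    Ordering is lexicographic on ``(kind, sbo_term or "")`` which puts
    SBML_REACTION before SBML_SPECIES.
    """

    kind: str
    sbo_term: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in (REACTION, SPECIES):
            raise DataError(f"unknown node kind: {self.kind!r}")

    @property
    def sort_key(self) -> tuple[str, str]:
        return (self.kind, self.sbo_term or "")

    def text(self) -> str:
        """Render as DOT label text: ``KIND`` or ``KIND:SBO:0000NNN``."""
        if self.sbo_term is None:
            return self.kind
        return f"{self.kind}:{self.sbo_term}"


REACTION_LABEL = NodeLabel(REACTION)
SPECIES_LABEL = NodeLabel(SPECIES)


def parse_node_label(text: str) -> NodeLabel:
    """Parse DOT label text into a :class:`NodeLabel` (case-insensitive kind)."""
    head, sep, rest = text.partition(":")
    kind = head.strip().upper()
    if kind not in (REACTION, SPECIES):
        raise DataError(f"unknown node label: {text!r}")
    return NodeLabel(kind, rest.strip() if sep else None)


class LabelledDigraph:
    """A labelled directed bipartite graph of species and reaction nodes.

    Nodes are opaque string identifiers mapped to :class:`NodeLabel`;
    edges are ``(source, target, label)`` triples.  Parallel edges with
    distinct labels are allowed (a species may be both reactant and
    modifier of one reaction), duplicate triples are not.  Construction
    validates bipartiteness and the role/direction rules.
    """

    __slots__ = ("nodes", "edges")

    def __init__(
        self,
        nodes: dict[str, NodeLabel] | None = None,
        edges: Iterable[tuple[str, str, str]] = (),
    ) -> None:
        self.nodes: dict[str, NodeLabel] = dict(nodes or {})
        self.edges: set[tuple[str, str, str]] = set(edges)
        self._validate()

    def _validate(self) -> None:
        for src, tgt, label in self.edges:
            if src not in self.nodes or tgt not in self.nodes:
                raise DataError(f"edge ({src}, {tgt}, {label}) references unknown node")
            if label not in EDGE_LABEL_ORDER:
                raise DataError(f"unknown edge label: {label!r}")
            skind, tkind = self.nodes[src].kind, self.nodes[tgt].kind
            if label in (IS_REACTANT, IS_MODIFIER):
                ok = skind == SPECIES and tkind == REACTION
            else:  # HAS_PRODUCT
                ok = skind == REACTION and tkind == SPECIES
            if not ok:
                raise DataError(
                    f"edge ({src}, {tgt}, {label}) violates the bipartite "
                    f"direction rule ({skind} -> {tkind})"
                )

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_ids(self) -> list[str]:
        return sorted(self.nodes)

    def add_node(self, node_id: str, label: NodeLabel) -> None:
        existing = self.nodes.get(node_id)
        if existing is not None and existing != label:
            raise DataError(f"node {node_id} relabelled from {existing} to {label}")
        self.nodes[node_id] = label

    def add_edge(self, src: str, tgt: str, label: str) -> None:
        self.edges.add((src, tgt, label))
        self._validate()

    def copy(self) -> "LabelledDigraph":
        return LabelledDigraph(dict(self.nodes), set(self.edges))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelledDigraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self) -> int:  # content hash; graphs are small
        return hash((frozenset(self.nodes.items()), frozenset(self.edges)))

    def __repr__(self) -> str:
        return f"<LabelledDigraph |V|={self.n_nodes} |E|={self.n_edges}>"

    # -- adjacency helpers (used by the matcher and the miner) ------------
    def incident(self, node: str) -> Iterator[tuple[str, str, str]]:
        for e in self.edges:
            if e[0] == node or e[1] == node:
                yield e

    def to_networkx(self) -> nx.MultiDiGraph:
        """Convert to a :class:`networkx.MultiDiGraph` with ``label`` attributes."""
        g = nx.MultiDiGraph()
        for nid, lab in self.nodes.items():
            g.add_node(nid, label=lab)
        for src, tgt, label in self.edges:
            g.add_edge(src, tgt, label=label)
        return g


@dataclass(frozen=True)
class Network:
    """A weakly connected reaction network with its provenance."""

    graph: LabelledDigraph
    model_id: str
    component_index: int

    @property
    def network_id(self) -> str:
        return f"{self.model_id}#{self.component_index}"


@dataclass
class NetworkSet:
    """An ordered collection of connected networks (one mining transaction each)."""

    networks: list[Network] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self) -> Iterator[Network]:
        return iter(self.networks)

    def extend(self, other: "NetworkSet") -> None:
        self.networks.extend(other.networks)

    def model_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for net in self.networks:
            seen.setdefault(net.model_id, None)
        return list(seen)

    def by_model(self) -> dict[str, list[Network]]:
        out: dict[str, list[Network]] = {}
        for net in self.networks:
            out.setdefault(net.model_id, []).append(net)
        return out


def orient_edges(tuples: Iterable[tuple[str, str, str]]) -> LabelledDigraph:
    """Turn export three-tuples ``(reaction, role, species)`` into a labelled digraph.

    ``HAS_REACTANT`` and ``HAS_MODIFIER`` flip to species->reaction edges
    labelled ``IS_REACTANT`` / ``IS_MODIFIER``; ``HAS_PRODUCT`` keeps the
    reaction->species orientation.  Node labels follow tuple position.
    """
    g = LabelledDigraph()
    for reaction_id, role, species_id in tuples:
        reaction_id, species_id = str(reaction_id), str(species_id)
        if role not in EXPORT_ROLES:
            raise DataError(f"unknown participant role: {role!r}")
        g.add_node(reaction_id, REACTION_LABEL)
        g.add_node(species_id, SPECIES_LABEL)
        if role == HAS_REACTANT:
            g.edges.add((species_id, reaction_id, IS_REACTANT))
        elif role == HAS_MODIFIER:
            g.edges.add((species_id, reaction_id, IS_MODIFIER))
        else:
            g.edges.add((reaction_id, species_id, HAS_PRODUCT))
    g._validate()
    return g


def split_components(g: LabelledDigraph, model_id: str = "model") -> NetworkSet:
    """Split a graph into its weakly connected components.

    Each component becomes its own :class:`Network`; direction is ignored
    for connectivity (a species joins the reactions producing it to those
    consuming it).  Components are ordered by their smallest node id for
    determinism.
    """
    if g.n_nodes == 0:
        return NetworkSet()
    und = nx.Graph()
    und.add_nodes_from(g.nodes)
    und.add_edges_from((s, t) for s, t, _ in g.edges)
    comps = sorted(nx.connected_components(und), key=lambda c: min(c))
    nets = []
    for idx, comp in enumerate(comps, start=1):
        sub_nodes = {n: g.nodes[n] for n in comp}
        sub_edges = {e for e in g.edges if e[0] in comp}
        nets.append(Network(LabelledDigraph(sub_nodes, sub_edges), model_id, idx))
    return NetworkSet(nets)


def apply_sbo_labels(g: LabelledDigraph, terms: dict[str, str]) -> LabelledDigraph:
    """Return a copy of *g* whose node labels carry SBO terms from *terms*."""
    nodes = {
        nid: NodeLabel(lab.kind, terms.get(nid)) for nid, lab in g.nodes.items()
    }
    return LabelledDigraph(nodes, set(g.edges))
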