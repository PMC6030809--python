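"""Frequent connected subgraph mining over sets of reaction networks.

Given a set of networks and a support interval ``[min_support,
max_support]``, :func:`mine` returns *every* connected labelled
subgraph — including single nodes and every subgraph of a larger
frequent pattern — occurring in at least ``min_support`` and at most
``max_support`` of the graphs.  Support counts each graph once no
matter how many embeddings it contains.  Support may be counted per
network (each weakly connected component is one transaction) or per
model (a model counts once if any of its networks embeds the pattern).

The search is extension-based in the gSpan tradition: it starts from
frequent node labels, grows one edge at a time, uses the minimum DFS
code (:mod:`.dfscode`) as the canonical form that de-duplicates
isomorphic candidates, and prunes with the anti-monotonicity of
support (a pattern's support never exceeds its subgraphs').  Patterns
above ``max_support`` are withheld from the output but still extended,
since their extensions may fall back inside the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .dfscode import DFSCode, graph_from_code, minimum_dfs_code
from .errors import CapacityError, ConfigError
from .graphs import (
    EDGE_LABEL_ORDER,
    HAS_PRODUCT,
    IS_MODIFIER,
    IS_REACTANT,
    REACTION,
    SPECIES,
    LabelledDigraph,
    NetworkSet,
    NodeLabel,
)
from .match import supports

STRUCTURAL = "structural"
SBO = "sbo"

SUPPORT_NETWORK = "network"
SUPPORT_MODEL = "model"


@dataclass
class MiningConfig:
    """Mining parameters.

    min_support / max_support are absolute graph counts (the mining
    interval); max_support defaults to the corpus size.  max_edges caps
    pattern size; mining beyond it raises :class:`CapacityError` only
    through max_patterns, the guard against pattern-lattice explosion.
    """

    min_support: int
    max_support: Optional[int] = None
    max_edges: int = 10
    support_unit: str = SUPPORT_NETWORK
    mode: str = STRUCTURAL
    max_patterns: int = 200_000

    def validate(self, n_units: int) -> tuple[int, int]:
        if self.min_support < 1:
            raise ConfigError("min_support must be a positive graph count")
        max_sup = self.max_support if self.max_support is not None else n_units
        if self.max_support is not None and self.min_support > self.max_support:
            raise ConfigError(
                f"min_support ({self.min_support}) exceeds max_support ({max_sup})"
            )
        if self.max_edges < 0:
            raise ConfigError("max_edges must be non-negative")
        if self.support_unit not in (SUPPORT_NETWORK, SUPPORT_MODEL):
            raise ConfigError(f"unknown support_unit: {self.support_unit!r}")
        if self.mode not in (STRUCTURAL, SBO):
            raise ConfigError(f"unknown mode: {self.mode!r}")
        return self.min_support, max_sup


@dataclass
class Pattern:
    """A mined frequent connected subgraph.

    ``graph`` uses canonical ``Node_k`` identifiers in DFS discovery
    order.  ``support`` is counted in the configured unit;
    ``supporting_ids`` are the network ids and ``supporting_models``
    the distinct model ids containing at least one embedding.
    """

    graph: LabelledDigraph
    support: int
    supporting_ids: list[str]
    supporting_models: list[str]
    pattern_id: str = ""
    code: DFSCode = field(default=(), repr=False)

    @property
    def n_entities(self) -> int:
        return self.graph.n_nodes

    @property
    def n_edges(self) -> int:
        return self.graph.n_edges

    @property
    def model_support(self) -> int:
        return len(self.supporting_models)


def _candidate_node_labels(
    pattern: LabelledDigraph, frequent_labels: Iterable[NodeLabel]
) -> list[tuple[str, str, NodeLabel, str, bool]]:
    """One-edge extension descriptors for *pattern*.

    Each descriptor is ``(anchor_node, role, new_label, internal_node,
    is_internal)``: either attach a fresh node with ``new_label`` to
    ``anchor_node`` via ``role``, or add a ``role`` edge between two
    existing nodes.  Bipartiteness fixes which kinds may pair and the
    edge direction, so the candidate space stays small.
    """
    out = []
    labels = list(frequent_labels)
    for nid, lab in pattern.nodes.items():
        opposite = SPECIES if lab.kind == REACTION else REACTION
        for new_lab in labels:
            if new_lab.kind != opposite:
                continue
            for role in (IS_REACTANT, IS_MODIFIER, HAS_PRODUCT):
                out.append((nid, role, new_lab, "", False))
    # Internal edges between existing species/reaction pairs.
    for sid, slab in pattern.nodes.items():
        if slab.kind != SPECIES:
            continue
        for rid, rlab in pattern.nodes.items():
            if rlab.kind != REACTION:
                continue
            for role in (IS_REACTANT, IS_MODIFIER, HAS_PRODUCT):
                src, tgt = ((rid, sid) if role == HAS_PRODUCT else (sid, rid))
                if (src, tgt, role) not in pattern.edges:
                    out.append((sid, role, rlab, rid, True))
    return out


def _apply_extension(
    pattern: LabelledDigraph, ext: tuple[str, str, NodeLabel, str, bool]
) -> LabelledDigraph:
    anchor, role, new_lab, other, internal = ext
    g = pattern.copy()
    if internal:
        sid, rid = anchor, other
    else:
        fresh = f"X{len(g.nodes)}"
        g.nodes[fresh] = new_lab
        if new_lab.kind == SPECIES:
            sid, rid = fresh, anchor
        else:
            sid, rid = anchor, fresh
    src, tgt = ((rid, sid) if role == HAS_PRODUCT else (sid, rid))
    g.edges.add((src, tgt, role))
    g._validate()
    return g


def mine(networks: NetworkSet, config: MiningConfig) -> list[Pattern]:
    """Mine all frequent connected subgraphs of *networks* under *config*.

    Returns patterns in a deterministic order: ascending edge count,
    then canonical code.  ``pattern_id`` is ``"<support>_<k>"`` with k
    disambiguating equal supports in output order.
    """
    nets = list(networks)
    # Transactions: (unit_id, [graphs], model_id)
    if config.support_unit == SUPPORT_MODEL:
        grouped = networks.by_model()
        units = [(mid, [n.graph for n in group], mid) for mid, group in grouped.items()]
    else:
        units = [(n.network_id, [n.graph], n.model_id) for n in nets]
    min_sup, max_sup = config.validate(len(units))
    if not units:
        return []

    # Frequent node labels seed the search (frequent 1-entity patterns).
    label_units: dict[NodeLabel, list[int]] = {}
    for ui, (_, graphs, _) in enumerate(units):
        seen: set[NodeLabel] = set()
        for g in graphs:
            seen.update(g.nodes.values())
        for lab in seen:
            label_units.setdefault(lab, []).append(ui)
    frequent_labels = sorted(
        (lab for lab, us in label_units.items() if len(us) >= min_sup),
        key=lambda lab: lab.sort_key,
    )

    results: dict[DFSCode, Pattern] = {}
    frontier: list[tuple[DFSCode, LabelledDigraph, list[int]]] = []
    for lab in frequent_labels:
        g = LabelledDigraph({"Node_0": lab})
        code = minimum_dfs_code(g)
        sup_units = label_units[lab]
        results[code] = _make_pattern(g, code, sup_units, units)
        frontier.append((code, g, sup_units))

    n_found = len(results)
    while frontier:
        next_frontier: list[tuple[DFSCode, LabelledDigraph, list[int]]] = []
        for code, pat, sup_units in sorted(frontier, key=lambda t: t[0]):
            if pat.n_edges >= config.max_edges:
                continue
            for ext in _candidate_node_labels(pat, frequent_labels):
                cand = _apply_extension(pat, ext)
                cand_code = minimum_dfs_code(cand)
                if cand_code in results:
                    continue
                canonical = graph_from_code(cand_code)
                cand_sup = [
                    ui for ui in sup_units
                    if any(supports(canonical, g) for g in units[ui][1])
                ]
                if len(cand_sup) < min_sup:
                    continue
                results[cand_code] = _make_pattern(canonical, cand_code, cand_sup, units)
                n_found += 1
                if n_found > config.max_patterns:
                    raise CapacityError(
                        f"more than {config.max_patterns} frequent patterns; "
                        "raise min_support or lower max_edges"
                    )
                next_frontier.append((cand_code, canonical, cand_sup))
        frontier = next_frontier

    emitted = [
        p for p in results.values() if min_sup <= p.support <= max_sup
    ]
    emitted.sort(key=lambda p: (p.n_edges, p.code))
    by_support: dict[int, int] = {}
    for p in emitted:
        k = by_support.get(p.support, 0) + 1
        by_support[p.support] = k
        p.pattern_id = f"{p.support}_{k}"
    return emitted


def _make_pattern(
    g: LabelledDigraph,
    code: DFSCode,
    sup_units: list[int],
    units: list[tuple[str, list[LabelledDigraph], str]],
) -> Pattern:
    ids = [units[ui][0] for ui in sup_units]
    models: dict[str, None] = {}
    for ui in sup_units:
        models.setdefault(units[ui][2], None)
    return Pattern(
        graph=g,
        support=len(sup_units),
        supporting_ids=ids,
        supporting_models=list(models),
        code=code,
    )
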