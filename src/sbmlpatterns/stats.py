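"""Quantitative corpus analysis: node/edge totals and reaction classes.

A *reaction class* is the participation signature of a single reaction
node — how many distinct species act as reactants, modifiers and
products.  The class histogram over a corpus shows which reaction
shapes dominate (in curated repositories, two reactants / one product
and one reactant / one product are the most common).  Counts use
distinct species per role, consistent with the deduplicated edge
model; signatures with more than ``overflow`` species in a role are
pooled into an overflow bucket for reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

from .graphs import IS_MODIFIER, IS_REACTANT, REACTION
from .ingest import IngestedModel


@dataclass(frozen=True, order=True)
class ReactionClass:
    """Distinct-species participation signature of one reaction."""

    n_reactants: int
    n_modifiers: int
    n_products: int

    @property
    def n_participants(self) -> int:
        return self.n_reactants + self.n_modifiers + self.n_products

    def text(self) -> str:
        return f"{self.n_reactants}r{self.n_modifiers}m{self.n_products}p"


@dataclass
class CorpusStats:
    """Corpus totals, per-model means and the reaction-class histogram."""

    models_total: int = 0
    models_with_species: int = 0
    models_with_reactions: int = 0
    total_reaction_nodes: int = 0
    total_species_nodes: int = 0
    mean_species_per_model: float = 0.0
    mean_reactions_per_model: float = 0.0
    #: participation totals (reactant, modifier, product) over all networks
    role_totals: tuple[int, int, int] = (0, 0, 0)
    class_histogram: dict[ReactionClass, int] = field(default_factory=dict)
    networks_total: int = 0

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "models_total": self.models_total,
            "models_with_species": self.models_with_species,
            "models_with_reactions": self.models_with_reactions,
            "total_reaction_nodes": self.total_reaction_nodes,
            "total_species_nodes": self.total_species_nodes,
            "mean_species_per_model": round(self.mean_species_per_model, 1),
            "mean_reactions_per_model": round(self.mean_reactions_per_model, 1),
            "role_totals": {
                "reactant": self.role_totals[0],
                "modifier": self.role_totals[1],
                "product": self.role_totals[2],
            },
            "networks_total": self.networks_total,
            "class_histogram": {
                rc.text(): n for rc, n in sorted(self.class_histogram.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def corpus_statistics(models: Sequence[IngestedModel]) -> CorpusStats:
    """Compute deterministic corpus statistics from ingested models.

    Species/reaction node counts come from the models' networks (so
    entities connected only by rules are excluded, matching the graph
    model); means are over all models in the corpus.
    """
    stats = CorpusStats(models_total=len(models))
    n_reactant = n_modifier = n_product = 0
    for m in models:
        # Node totals use the *declared* element sets: a species defined in a
        # model counts even if no reaction connects it into a network.
        species_nodes = set(m.species_ids)
        reaction_nodes = set(m.reaction_ids)
        for net in m.networks:
            stats.networks_total += 1
            per_reaction: dict[str, list[int]] = {}
            for src, tgt, label in net.graph.edges:
                if label == IS_REACTANT:
                    per_reaction.setdefault(tgt, [0, 0, 0])[0] += 1
                    n_reactant += 1
                elif label == IS_MODIFIER:
                    per_reaction.setdefault(tgt, [0, 0, 0])[1] += 1
                    n_modifier += 1
                else:
                    per_reaction.setdefault(src, [0, 0, 0])[2] += 1
                    n_product += 1
            for rid, lab in net.graph.nodes.items():
                if lab.kind != REACTION:
                    continue
                r, mo, p = per_reaction.get(rid, [0, 0, 0])
                rc = ReactionClass(r, mo, p)
                stats.class_histogram[rc] = stats.class_histogram.get(rc, 0) + 1
        if species_nodes:
            stats.models_with_species += 1
        if reaction_nodes:
            stats.models_with_reactions += 1
        stats.total_species_nodes += len(species_nodes)
        stats.total_reaction_nodes += len(reaction_nodes)
    stats.role_totals = (n_reactant, n_modifier, n_product)
    if models:
        stats.mean_species_per_model = stats.total_species_nodes / len(models)
        stats.mean_reactions_per_model = stats.total_reaction_nodes / len(models)
    return stats


def class_histogram_csv(stats: CorpusStats, path: Union[str, Path], overflow: int = 6) -> None:
    """Write the reaction-class histogram as CSV, pooling classes whose
    participant count exceeds *overflow* into an ``overflow`` row."""
    lines = ["n_reactants,n_modifiers,n_products,count"]
    pooled = 0
    for rc, n in sorted(stats.class_histogram.items()):
        if rc.n_participants > overflow:
            pooled += n
        else:
            lines.append(f"{rc.n_reactants},{rc.n_modifiers},{rc.n_products},{n}")
    if pooled:
        lines.append(f"overflow,overflow,overflow,{pooled}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
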