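"""Synthetic reaction-network corpora with known ground truth.

Generates random bipartite species/reaction networks shaped like small
curated biochemical models — by default 3–11 species and 3–12 reactions
per model, each reaction drawing 1–4 participants whose roles are
sampled per participation (reactants and products dominate; modifiers
are rarer) — optionally annotated from an SBO vocabulary, optionally
with copies of given patterns planted into a fraction of the models.
Every generated corpus comes with a ledger recording, per model, the
exact edge list and each planted pattern copy, so parsers, miners and
counters can be tested against construction ground truth.  Models can
be serialised as SBML Level 3 documents to exercise the ingest round
trip.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from lxml import etree

from .errors import ConfigError
from .graphs import (
    HAS_MODIFIER,
    HAS_PRODUCT,
    HAS_REACTANT,
    REACTION,
    SPECIES,
    LabelledDigraph,
    NetworkSet,
    orient_edges,
    split_components,
)
from .ingest import IngestedModel, ModelRecord, SboAnnotation

SBML_L3_NS = "http://www.sbml.org/sbml/level3/version2/core"


@dataclass
class SynthConfig:
    """Parameters of the synthetic corpus.

    Defaults emulate the size profile of small curated models: most
    models have 3–11 species and 3–12 reactions; each reaction has 1–4
    participating species; per participation the role is reactant with
    probability .45, modifier .10, product .45.  ``planted`` maps
    pattern graphs to the fraction of models that receive one copy.
    """

    n_models: int = 30
    species_range: tuple[int, int] = (3, 11)
    reactions_range: tuple[int, int] = (3, 12)
    participants_range: tuple[int, int] = (1, 4)
    role_probs: tuple[float, float, float] = (0.45, 0.10, 0.45)
    sbo_vocabulary: Optional[Sequence[tuple[str, str, float]]] = None
    #: each entry: (pattern graph, fraction of models receiving one copy)
    planted: Sequence[tuple[LabelledDigraph, float]] = ()
    #: probability that a planted copy fuses one species with an existing node
    fuse_probability: float = 0.5
    seed: int = 0
    id_prefix: str = "SYN"

    def validate(self) -> None:
        if self.n_models < 0:
            raise ConfigError("n_models must be non-negative")
        if abs(sum(self.role_probs) - 1.0) > 1e-9:
            raise ConfigError("role probabilities must sum to 1")
        for lo, hi in (self.species_range, self.reactions_range, self.participants_range):
            if not (0 < lo <= hi):
                raise ConfigError("ranges must satisfy 0 < low <= high")
        if self.participants_range[0] > self.species_range[1]:
            raise ConfigError("participants per reaction exceed available species")
        for _, frac in self.planted:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("planted fractions must lie in [0, 1]")


@dataclass
class CorpusLedger:
    """Construction ground truth: edge lists, labels and planted copies per model."""

    edge_lists: dict[str, set[tuple[str, str, str]]] = field(default_factory=dict)
    sbo_terms: dict[str, dict[str, str]] = field(default_factory=dict)
    #: model_id -> list of (pattern index, node mapping pattern->model)
    planted_copies: dict[str, list[tuple[int, dict[str, str]]]] = field(
        default_factory=dict
    )

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "edge_lists": {m: sorted(map(list, t)) for m, t in self.edge_lists.items()},
            "sbo_terms": self.sbo_terms,
            "planted_copies": {
                m: [[i, mapping] for i, mapping in copies]
                for m, copies in self.planted_copies.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


_ROLES = (HAS_REACTANT, HAS_MODIFIER, HAS_PRODUCT)


def _plant_pattern(
    rng: random.Random,
    pattern: LabelledDigraph,
    tuples: set[tuple[str, str, str]],
    species: list[str],
    model_idx: int,
    copy_idx: int,
    fuse_probability: float,
) -> dict[str, str]:
    """Wire one fresh copy of *pattern* into a model's tuple set.

    Pattern species/reaction nodes become fresh model nodes; with
    ``fuse_probability`` one pattern species is fused onto an existing
    model species, embedding the copy in context.
    """
    mapping: dict[str, str] = {}
    pat_species = [n for n, lab in pattern.nodes.items() if lab.kind == SPECIES]
    fused: Optional[str] = None
    if species and pat_species and rng.random() < fuse_probability:
        fused = rng.choice(pat_species)
    for pn, lab in sorted(pattern.nodes.items()):
        if pn == fused:
            mapping[pn] = rng.choice(species)
        elif lab.kind == SPECIES:
            mapping[pn] = f"PS{model_idx}_{copy_idx}_{pn}"
        else:
            mapping[pn] = f"PR{model_idx}_{copy_idx}_{pn}"
    for src, tgt, label in pattern.edges:
        if label == HAS_PRODUCT:
            tuples.add((mapping[src], HAS_PRODUCT, mapping[tgt]))
        elif label == "IS_REACTANT":
            tuples.add((mapping[tgt], HAS_REACTANT, mapping[src]))
        else:
            tuples.add((mapping[tgt], HAS_MODIFIER, mapping[src]))
    return mapping


def generate_corpus(config: SynthConfig) -> tuple[list[IngestedModel], CorpusLedger]:
    """Generate a reproducible corpus of models with its ground-truth ledger."""
    config.validate()
    rng = random.Random(config.seed)
    ledger = CorpusLedger()
    models: list[IngestedModel] = []
    sbo_mode = config.sbo_vocabulary is not None

    planted_assignment: dict[int, set[int]] = {}
    for pi, (_, frac) in enumerate(config.planted):
        k = round(frac * config.n_models)
        chosen = rng.sample(range(config.n_models), k) if k else []
        planted_assignment[pi] = set(chosen)

    for mi in range(config.n_models):
        model_id = f"{config.id_prefix}{mi:04d}"
        n_species = rng.randint(*config.species_range)
        n_reactions = rng.randint(*config.reactions_range)
        species = [f"S{mi}_{k}" for k in range(n_species)]
        tuples: set[tuple[str, str, str]] = set()
        for rj in range(n_reactions):
            rid = f"R{mi}_{rj}"
            k = rng.randint(*config.participants_range)
            k = min(k, n_species)
            chosen = rng.sample(species, k)
            for sp in chosen:
                role = rng.choices(_ROLES, weights=config.role_probs)[0]
                tuples.add((rid, role, sp))
        copies: list[tuple[int, dict[str, str]]] = []
        for pi, (pattern, _) in enumerate(config.planted):
            if mi in planted_assignment[pi]:
                mapping = _plant_pattern(
                    rng, pattern, tuples, species, mi, pi, config.fuse_probability
                )
                copies.append((pi, mapping))

        annotations: set[SboAnnotation] = set()
        terms: dict[str, str] = {}
        if sbo_mode:
            vocab = list(config.sbo_vocabulary or ())
            sp_terms = [(t, w) for t, kind, w in vocab if kind == SPECIES]
            rx_terms = [(t, w) for t, kind, w in vocab if kind == REACTION]
            node_ids = {n for t in tuples for n in (t[0], t[2])}
            for nid in sorted(node_ids):
                pool = rx_terms if any(t[0] == nid for t in tuples) else sp_terms
                if not pool:
                    continue
                term = rng.choices([t for t, _ in pool], weights=[w for _, w in pool])[0]
                terms[nid] = term
                annotations.add(SboAnnotation(nid, term))

        record = ModelRecord(model_id, f"synthetic model {mi}", f"<synthetic:{model_id}>")
        graph = orient_edges(tuples)
        networks = split_components(graph, model_id=model_id)
        if sbo_mode:
            from .graphs import apply_sbo_labels
            from .graphs import Network

            networks = NetworkSet(
                [
                    Network(
                        apply_sbo_labels(net.graph, terms), net.model_id, net.component_index
                    )
                    for net in networks
                ]
            )
        declared_species = set(species) | {t[2] for t in tuples}
        declared_reactions = {f"R{mi}_{rj}" for rj in range(n_reactions)} | {
            t[0] for t in tuples
        }
        models.append(
            IngestedModel(
                record, tuples, annotations, networks, declared_species, declared_reactions
            )
        )
        ledger.edge_lists[model_id] = set(tuples)
        ledger.sbo_terms[model_id] = terms
        ledger.planted_copies[model_id] = copies
    return models, ledger


def write_sbml(model: IngestedModel, path: Union[str, Path]) -> None:
    """Serialise a generated model as an SBML Level 3 document.

    Participation tuples become speciesReference / modifierSpeciesReference
    entries; SBO annotations become ``sboTerm`` attributes.
    """
    nsmap = {None: SBML_L3_NS}
    root = etree.Element(f"{{{SBML_L3_NS}}}sbml", nsmap=nsmap, level="3", version="2")
    mdl = etree.SubElement(
        root,
        f"{{{SBML_L3_NS}}}model",
        id=model.record.model_id,
        name=model.record.model_name,
    )
    terms = model.sbo_terms
    species_ids = sorted({t[2] for t in model.tuples})
    reactions: dict[str, dict[str, list[str]]] = {}
    for rid, role, sid in sorted(model.tuples):
        reactions.setdefault(rid, {r: [] for r in _ROLES})[role].append(sid)

    if species_ids:
        los = etree.SubElement(mdl, f"{{{SBML_L3_NS}}}listOfSpecies")
        for sid in species_ids:
            sp = etree.SubElement(
                los, f"{{{SBML_L3_NS}}}species", id=sid, constant="false"
            )
            if sid in terms:
                sp.set("sboTerm", terms[sid])
    if reactions:
        lor = etree.SubElement(mdl, f"{{{SBML_L3_NS}}}listOfReactions")
        for rid in sorted(reactions):
            rx = etree.SubElement(
                lor, f"{{{SBML_L3_NS}}}reaction", id=rid, reversible="false"
            )
            if rid in terms:
                rx.set("sboTerm", terms[rid])
            for list_tag, role, ref_tag in (
                ("listOfReactants", HAS_REACTANT, "speciesReference"),
                ("listOfProducts", HAS_PRODUCT, "speciesReference"),
                ("listOfModifiers", HAS_MODIFIER, "modifierSpeciesReference"),
            ):
                members = reactions[rid][role]
                if not members:
                    continue
                lst = etree.SubElement(rx, f"{{{SBML_L3_NS}}}{list_tag}")
                for sid in members:
                    ref = etree.SubElement(
                        lst, f"{{{SBML_L3_NS}}}{ref_tag}", species=sid
                    )
                    if ref_tag == "speciesReference":
                        ref.set("constant", "true")
    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def two_species_cycle() -> LabelledDigraph:
    """The smallest biologically meaningful cycle: two species and two
    reactions, each species the reactant of one reaction and the product
    of the other (production/degradation, feedback motifs)."""
    from .graphs import NodeLabel

    g = LabelledDigraph(
        {
            "S1": NodeLabel(SPECIES),
            "S2": NodeLabel(SPECIES),
            "R1": NodeLabel(REACTION),
            "R2": NodeLabel(REACTION),
        },
        {
            ("S1", "R1", "IS_REACTANT"),
            ("R1", "S2", HAS_PRODUCT),
            ("S2", "R2", "IS_REACTANT"),
            ("R2", "S1", HAS_PRODUCT),
        },
    )
    return g
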