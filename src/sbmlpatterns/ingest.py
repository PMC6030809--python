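"""SBML model ingestion.

Reads SBML Level 2/3 documents and reduces each to the participation
tuples that define its reaction network: one ``(reaction, role,
species)`` three-tuple per distinct reactant, modifier or product
relation.  Everything else in the model — kinetics, compartments,
units, events, and notably *rules* (which connect entities only
implicitly) — is ignored: the workflow mines explicitly connected
entities only.

For the semantics-aware mode the ``sboTerm`` attributes of species and
reactions are collected and normalised to ``SBO:0000NNN`` accessions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from lxml import etree

from .errors import DataError, FormatError
from .graphs import (
    HAS_MODIFIER,
    HAS_PRODUCT,
    HAS_REACTANT,
    LabelledDigraph,
    NetworkSet,
    apply_sbo_labels,
    orient_edges,
    split_components,
)

SBO_PATTERN = re.compile(r"^SBO:\d{7}$")


@dataclass(frozen=True)
class ModelRecord:
    """Identity of one ingested model: id, display name, source file."""

    model_id: str
    model_name: str
    source_path: str


@dataclass(frozen=True)
class SboAnnotation:
    """An SBO accession attached to a species or reaction node."""

    element_id: str
    term: str

    def __post_init__(self) -> None:
        if not SBO_PATTERN.match(self.term):
            raise DataError(f"malformed SBO term {self.term!r} on {self.element_id}")


def normalize_sbo_term(raw: str, element_id: str = "?") -> str:
    """Normalise an ``sboTerm`` attribute value to the ``SBO:0000NNN`` accession.

    SBML allows both the full accession and a bare integer.
    """
    raw = raw.strip()
    if SBO_PATTERN.match(raw):
        return raw
    if raw.isdigit():
        return f"SBO:{int(raw):07d}"
    raise DataError(f"malformed sboTerm {raw!r} on element {element_id}")


def extract_sbo_term(element: etree._Element) -> Optional[SboAnnotation]:
    """Extract the SBO annotation of a parsed SBML species or reaction.

    Returns None when the element carries no ``sboTerm`` attribute.
    Raises :class:`DataError` on malformed term text.
    """
    raw = element.get("sboTerm")
    if raw is None:
        return None
    element_id = element.get("id") or element.get("name") or "?"
    return SboAnnotation(element_id, normalize_sbo_term(raw, element_id))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _children(element: etree._Element, name: str) -> list[etree._Element]:
    return [c for c in element if isinstance(c.tag, str) and _local(c.tag) == name]


def _find(element: etree._Element, name: str) -> Optional[etree._Element]:
    found = _children(element, name)
    return found[0] if found else None


def parse_sbml_model(
    path: Union[str, Path],
) -> tuple[ModelRecord, set[tuple[str, str, str]], set[SboAnnotation]]:
    """Parse one SBML file into its participation tuples and SBO annotations.

    Returns ``(record, tuples, annotations)`` where ``tuples`` holds one
    ``(reaction_id, role, species_id)`` entry per distinct participation.
    Repeated listings of one species in the same role of one reaction
    (stoichiometry, duplicated references) collapse to a single tuple;
    the same species in *different* roles yields one tuple per role.
    Models defining entities only through rules produce an empty set.
    """
    record, tuples, annotations, _, _ = _parse_sbml(path)
    return record, tuples, annotations


def _parse_sbml(
    path: Union[str, Path],
) -> tuple[
    ModelRecord,
    set[tuple[str, str, str]],
    set[SboAnnotation],
    set[str],
    set[str],
]:
    """Full parse: also returns the declared species and reaction id sets."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise FormatError(f"cannot parse SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise FormatError(f"{path}: root element is <{_local(root.tag)}>, not <sbml>")
    model = _find(root, "model")
    if model is None:
        raise FormatError(f"{path}: no <model> element")

    model_id = model.get("id") or model.get("metaid") or path.stem
    model_name = model.get("name") or path.stem
    record = ModelRecord(model_id, model_name, str(path))

    annotations: set[SboAnnotation] = set()
    species_ids: set[str] = set()
    list_of_species = _find(model, "listOfSpecies")
    if list_of_species is not None:
        for sp in _children(list_of_species, "species"):
            sid = sp.get("id")
            if sid is None:
                raise FormatError(f"{path}: species without id")
            species_ids.add(sid)
            ann = extract_sbo_term(sp)
            if ann is not None:
                annotations.add(ann)

    tuples: set[tuple[str, str, str]] = set()
    reaction_ids: set[str] = set()
    list_of_reactions = _find(model, "listOfReactions")
    if list_of_reactions is not None:
        for rx in _children(list_of_reactions, "reaction"):
            rid = rx.get("id")
            if rid is None:
                raise FormatError(f"{path}: reaction without id")
            reaction_ids.add(rid)
            if rid in species_ids:
                raise DataError(
                    f"{path}: identifier {rid!r} used for both a species and a reaction"
                )
            ann = extract_sbo_term(rx)
            if ann is not None:
                annotations.add(ann)
            for list_name, role in (
                ("listOfReactants", HAS_REACTANT),
                ("listOfModifiers", HAS_MODIFIER),
                ("listOfProducts", HAS_PRODUCT),
            ):
                participants = _find(rx, list_name)
                if participants is None:
                    continue
                for ref in participants:
                    if not isinstance(ref.tag, str):
                        continue
                    if _local(ref.tag) not in (
                        "speciesReference",
                        "modifierSpeciesReference",
                    ):
                        continue
                    species = ref.get("species")
                    if species is None:
                        raise FormatError(
                            f"{path}: species reference without 'species' in {rid}"
                        )
                    tuples.add((rid, role, species))
    return record, tuples, annotations, species_ids, reaction_ids


@dataclass
class IngestedModel:
    """A parsed model with its connected reaction networks.

    ``species_ids`` / ``reaction_ids`` are the *declared* element sets;
    entities without any participation appear there but in no network.
    """

    record: ModelRecord
    tuples: set[tuple[str, str, str]]
    annotations: set[SboAnnotation]
    networks: NetworkSet
    species_ids: set[str] = None  # type: ignore[assignment]
    reaction_ids: set[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.species_ids is None:
            self.species_ids = {t[2] for t in self.tuples}
        if self.reaction_ids is None:
            self.reaction_ids = {t[0] for t in self.tuples}

    @property
    def sbo_terms(self) -> dict[str, str]:
        return {a.element_id: a.term for a in self.annotations}

    def is_fully_sbo_annotated(self) -> bool:
        """True iff every node of every network carries an SBO term."""
        terms = self.sbo_terms
        return all(
            nid in terms
            for net in self.networks
            for nid in net.graph.nodes
        )


def ingest_model(path: Union[str, Path], sbo_mode: bool = False) -> IngestedModel:
    """Parse an SBML file and build its connected labelled networks.

    In SBO mode node labels additionally carry the SBO accessions.
    """
    record, tuples, annotations, species_ids, reaction_ids = _parse_sbml(path)
    graph = orient_edges(tuples)
    networks = split_components(graph, model_id=record.model_id)
    if sbo_mode:
        terms = {a.element_id: a.term for a in annotations}
        networks = NetworkSet(
            [
                type(net)(apply_sbo_labels(net.graph, terms), net.model_id, net.component_index)
                for net in networks
            ]
        )
    return IngestedModel(record, tuples, annotations, networks, species_ids, reaction_ids)


def ingest_directory(
    directory: Union[str, Path],
    sbo_mode: bool = False,
    require_full_annotation: bool = True,
) -> list[IngestedModel]:
    """Ingest every ``.xml``/``.sbml`` file in *directory* (sorted by name).

    In SBO mode, models whose networks are not fully annotated are
    dropped by default (the strictest reading of a "valid" model);
    pass ``require_full_annotation=False`` to keep them, with
    unannotated nodes labelled by kind only.
    """
    directory = Path(directory)
    models = []
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in (".xml", ".sbml"):
            continue
        model = ingest_model(path, sbo_mode=sbo_mode)
        if sbo_mode and require_full_annotation and not model.is_fully_sbo_annotated():
            continue
        models.append(model)
    seen: set[str] = set()
    for m in models:
        if m.record.model_id in seen:
            raise DataError(f"duplicate model id {m.record.model_id!r} in {directory}")
        seen.add(m.record.model_id)
    return models


def combined_networks(models: list[IngestedModel]) -> NetworkSet:
    """Concatenate all models' networks into one mining corpus."""
    out = NetworkSet()
    for m in models:
        out.extend(m.networks)
    return out
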