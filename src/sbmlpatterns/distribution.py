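"""Pattern distribution across models: feature matrix and query export.

For every mined pattern and every model, the number of injective
embeddings of the pattern into the model's networks is counted; the
resulting model × pattern table of counts is the feature matrix, whose
rows serve as structural feature vectors for the models.  Counting is
the raw assignment count — pairwise-distinct nodes, automorphic
re-assignments counted separately — matching the row count of the
generated graph-database query, whose WHERE clause enforces exactly the
pairwise node inequalities.

Each pattern is additionally rendered as query text in the Cypher
dialect of the original graph database (MaSyMoS), anchored at the
model/document pair so the query returns (model id, file name, count)
triples.  No database connection is made; the text is an output format.
"""

from __future__ import annotations

import json
from itertools import combinations
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .errors import ContractError, DataError
from .graphs import LabelledDigraph, REACTION
from .ingest import IngestedModel
from .match import count_embeddings, count_orbits
from .mining import Pattern


def build_feature_matrix(
    models: Sequence[IngestedModel],
    patterns: Sequence[Pattern],
    orbit_counts: bool = False,
) -> pd.DataFrame:
    """Count pattern embeddings per model into a feature matrix.

    The first two columns identify the model (id and name); the
    remaining columns are patterns ordered by descending frequency,
    ties broken by pattern id.  With ``orbit_counts`` the raw counts
    are divided by the pattern's automorphism count (distinct
    occurrences instead of query rows).
    """
    ids = [m.record.model_id for m in models]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate model ids in feature-matrix input")
    pids = [p.pattern_id for p in patterns]
    if len(set(pids)) != len(pids):
        raise DataError("duplicate pattern ids")
    ordered = sorted(patterns, key=lambda p: (-p.support, p.pattern_id))
    counter = count_orbits if orbit_counts else count_embeddings
    rows = []
    for m in models:
        nets = [net.graph for net in m.networks]
        row: dict[str, object] = {
            "model_id": m.record.model_id,
            "model_name": m.record.model_name,
        }
        for p in ordered:
            row[p.pattern_id] = counter(p.graph, nets)
        rows.append(row)
    columns = ["model_id", "model_name"] + [p.pattern_id for p in ordered]
    return pd.DataFrame(rows, columns=columns)


def write_feature_matrix(matrix: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the feature matrix as a UTF-8 comma-separated file with header."""
    matrix.to_csv(path, index=False, encoding="utf-8")


def write_distribution_json(
    matrix: pd.DataFrame, pattern_id: str, path: Union[str, Path]
) -> None:
    """Write one pattern's per-model result set: (id, name, count) triples,
    models without an embedding omitted, descending count order — the shape
    a distribution query would return."""
    rows = [
        {
            "model_id": r["model_id"],
            "model_name": r["model_name"],
            "count": int(r[pattern_id]),
        }
        for _, r in matrix.iterrows()
        if r[pattern_id] > 0
    ]
    rows.sort(key=lambda r: (-r["count"], r["model_id"]))
    Path(path).write_text(json.dumps(rows, indent=1), encoding="utf-8")


def pattern_to_graph_query(pattern: Union[Pattern, LabelledDigraph]) -> str:
    """Emit the distribution query for *pattern* in the MaSyMoS Cypher dialect.

    The MATCH clause anchors the model and document nodes and lists one
    relationship term per pattern edge; the WHERE clause holds all
    pairwise node inequalities (injectivity); the RETURN reports
    distinct model id, file name and embedding count in descending
    order.  Node identifiers are the pattern's canonical ``Node_k``
    names.
    """
    graph = pattern.graph if isinstance(pattern, Pattern) else pattern
    if graph.n_nodes == 0:
        raise ContractError("cannot build a query for an empty pattern")
    nodes = sorted(graph.nodes, key=lambda n: (len(n), n))
    anchor = nodes[0]
    anchor_rel = (
        "HAS_REACTION" if graph.nodes[anchor].kind == REACTION else "HAS_SPECIES"
    )
    match_terms = [
        "(m: SBML_MODEL)-->(d: DOCUMENT)",
        f"m-[{anchor_rel}]->{anchor}",
    ]
    for src, tgt, label in sorted(graph.edges):
        match_terms.append(f"{src}-[: {label}]->{tgt}")
    where_terms = [f"{a}<>{b}" for a, b in combinations(nodes, 2)]
    lines = ["MATCH " + ", ".join(match_terms)]
    if where_terms:
        lines.append("WHERE " + " AND ".join(where_terms))
    lines.append(f"RETURN DISTINCT ID(m), d.FILENAME, COUNT({anchor}) AS sum")
    lines.append("ORDER BY sum DESC")
    return "\n".join(lines)


def write_queries(
    patterns: Sequence[Pattern], directory: Union[str, Path]
) -> list[Path]:
    """Write one ``<pattern_id>.cypher`` query file per pattern."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in patterns:
        path = directory / f"{p.pattern_id}.cypher"
        path.write_text(pattern_to_graph_query(p) + "\n", encoding="utf-8")
        paths.append(path)
    return paths
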