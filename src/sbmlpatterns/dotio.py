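"""Readers and writers for the workflow's exchange dialects.

Two text formats travel between workflow steps:

* a JSON edge list — an object with ``"columns" = ["ID(reaction)",
  "TYPE(edge)", "ID(species)"]`` and ``"data"`` an array of
  three-element arrays, one per participation;
* a narrow Graphviz DOT dialect — one ``digraph`` per connected
  reaction network, node statements ``id [label = KIND]`` and edge
  statements ``a -> b [label = ROLE]``.  Mined-pattern files use the
  same syntax with ``Node_k`` identifiers, quoted labels and a trailing
  frequency comment ``}#=> <frequency>[id, id,]`` after each digraph.

The reader is deliberately tolerant (quotes optional, both label
casings accepted, semicolons optional); the writer emits one canonical
form per dialect.  General DOT (subgraphs, ports, HTML labels) is out
of scope.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

from .errors import FormatError
from .graphs import (
    EXPORT_ROLES,
    LabelledDigraph,
    Network,
    NetworkSet,
    parse_node_label,
)

EDGE_JSON_COLUMNS = ["ID(reaction)", "TYPE(edge)", "ID(species)"]

_NODE_RE = re.compile(
    r'^\s*"?(?P<id>[\w.:-]+)"?\s*\[\s*label\s*=\s*'
    r'["‘’“”]?(?P<label>[\w.:-]+)["‘’“”]?\s*\]\s*;?\s*$'
)
_EDGE_RE = re.compile(
    r'^\s*"?(?P<src>[\w.:-]+)"?\s*->\s*"?(?P<tgt>[\w.:-]+)"?\s*\[\s*label\s*=\s*'
    r'["‘’“”]?(?P<label>[\w.:-]+)["‘’“”]?\s*\]\s*;?\s*$'
)
_DIGRAPH_RE = re.compile(r'^\s*digraph(\s+["‘’]?(?P<name>[\w.-]*)["‘’]?)?\s*\{\s*$')
_FREQ_RE = re.compile(
    r"^\}\s*#\s*=>\s*(?P<freq>\d+)\s*(\[(?P<ids>[^\]]*)\])?\s*$"
)


def write_edge_json(
    tuples: Iterable[tuple[str, str, str]], path: Union[str, Path]
) -> None:
    """Write export three-tuples in the JSON edge-list dialect."""
    payload = {
        "columns": EDGE_JSON_COLUMNS,
        "data": [[r, role, s] for r, role, s in sorted(tuples)],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_edge_json(path: Union[str, Path]) -> set[tuple[str, str, str]]:
    """Read a JSON edge list into a set of ``(reaction, role, species)`` tuples."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "columns" not in payload or "data" not in payload:
        raise FormatError(f"{path}: expected an object with 'columns' and 'data'")
    cols = [re.sub(r"[‘’]", "", str(c)) for c in payload["columns"]]
    if cols != EDGE_JSON_COLUMNS:
        raise FormatError(
            f"{path}: columns {cols!r} do not match {EDGE_JSON_COLUMNS!r}"
        )
    out: set[tuple[str, str, str]] = set()
    for row in payload["data"]:
        if not isinstance(row, (list, tuple)) or len(row) != 3:
            raise FormatError(f"{path}: malformed data row {row!r}")
        reaction, role, species = (str(x).strip("‘’' ") for x in row)
        if role not in EXPORT_ROLES:
            raise FormatError(f"{path}: unknown edge type {role!r}")
        out.add((reaction, role, species))
    return out


# Network files use the mixed-case node labels of the intermediate
# dialect; pattern files use the miner's uppercase labels.
_MIXED_CASE = {"SBML_REACTION": "SBML_Reaction", "SBML_SPECIES": "SBML_Species"}


def _format_graph(
    g: LabelledDigraph,
    name: str = "",
    quote_labels: bool = False,
    rename: Optional[dict[str, str]] = None,
    mixed_case: bool = False,
) -> list[str]:
    q = '"' if quote_labels else ""
    name_part = f' "{name}"' if name else ""
    lines = [f"digraph{name_part} {{"]
    rename = rename or {}
    for nid in g.node_ids():
        rid = rename.get(nid, nid)
        text = g.nodes[nid].text()
        if mixed_case:
            kind, _, rest = text.partition(":")
            text = _MIXED_CASE.get(kind, kind) + (f":{rest}" if rest else "")
        lines.append(f"  {rid} [label = {q}{text}{q}];")
    for src, tgt, label in sorted(g.edges):
        lines.append(
            f"  {rename.get(src, src)} -> {rename.get(tgt, tgt)} [label = {q}{label}{q}];"
        )
    return lines


def write_networks_dot(networks: NetworkSet, path: Union[str, Path]) -> None:
    """Write connected reaction networks, one digraph per network."""
    lines: list[str] = []
    for idx, net in enumerate(networks, start=1):
        lines.append(f"# connected reaction network {idx} ({net.network_id})")
        lines.extend(_format_graph(net.graph, mixed_case=True))
        lines.append("}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def write_patterns_dot(patterns: Sequence, path: Union[str, Path]) -> None:
    """Write mined patterns with their trailing frequency comments.

    Each pattern becomes ``digraph "<n_edges>" { ... }#=> freq[ids,]``;
    node identifiers are already canonical ``Node_k`` names.
    """
    lines: list[str] = []
    for pat in patterns:
        lines.extend(
            _format_graph(pat.graph, name=str(pat.graph.n_edges), quote_labels=True)
        )
        ids = ", ".join(pat.supporting_ids)
        lines.append(f"}}#=> {pat.support}[{ids},]")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_dot(path: Union[str, Path]) -> list[tuple[LabelledDigraph, Optional[int], list[str]]]:
    """Parse a DOT file of either dialect.

    Returns one ``(graph, frequency, supporting_ids)`` triple per
    digraph; frequency is None for plain network files.  Raises
    :class:`FormatError` with a line number on malformed statements.
    """
    path = Path(path)
    graphs: list[tuple[LabelledDigraph, Optional[int], list[str]]] = []
    current: Optional[LabelledDigraph] = None
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or (line.startswith("#") and current is None):
                continue
            if current is None:
                if _DIGRAPH_RE.match(line):
                    current = LabelledDigraph()
                    continue
                raise FormatError(f"{path}:{lineno}: expected 'digraph {{', got {line!r}")
            freq_m = _FREQ_RE.match(line)
            if line == "}" or freq_m:
                freq = int(freq_m.group("freq")) if freq_m else None
                ids = []
                if freq_m and freq_m.group("ids"):
                    ids = [
                        s.strip() for s in freq_m.group("ids").split(",") if s.strip()
                    ]
                graphs.append((current, freq, ids))
                current = None
                continue
            node_m = _NODE_RE.match(line)
            if node_m:
                try:
                    current.add_node(
                        node_m.group("id"), parse_node_label(node_m.group("label"))
                    )
                except Exception as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
                continue
            edge_m = _EDGE_RE.match(line)
            if edge_m:
                try:
                    current.add_edge(
                        edge_m.group("src"), edge_m.group("tgt"), edge_m.group("label")
                    )
                except Exception as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
                continue
            raise FormatError(f"{path}:{lineno}: unrecognised DOT statement {line!r}")
    if current is not None:
        raise FormatError(f"{path}: unterminated digraph at end of file")
    return graphs


def read_networks_dot(path: Union[str, Path], model_id: str = "dot") -> NetworkSet:
    """Read a networks DOT file into a :class:`NetworkSet`."""
    nets = [
        Network(g, model_id, idx)
        for idx, (g, _, _) in enumerate(read_dot(path), start=1)
    ]
    return NetworkSet(nets)
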