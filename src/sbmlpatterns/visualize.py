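"""SBGN Process Description styled rendering of mined patterns.

Patterns are drawn with the standard process-description glyphs rather
than textual labels: a rounded rectangle for a species (entity pool), a
small square for a reaction (process), a plain line for the reactant
arc, a filled arrow for the product arc and a circle-headed line for
the modifier arc.  In semantics-aware mode the SBO term text is drawn
inside the glyph.

Two artefacts are produced per pattern: a *styled DOT* file in which
shape and arrowhead attributes encode the glyph choices (a pure
function of pattern and style, asserted byte-identically in tests) and
a rendered PNG/PDF image drawn with matplotlib on a layered
left-to-right layout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle, FancyArrowPatch, FancyBboxPatch, Rectangle

from .dotio import read_dot, write_patterns_dot
from .errors import ContractError, FormatError
from .graphs import (
    HAS_PRODUCT,
    IS_MODIFIER,
    IS_REACTANT,
    SPECIES,
    LabelledDigraph,
)
from .mining import Pattern

_ARROWHEADS = {IS_REACTANT: "none", IS_MODIFIER: "odot", HAS_PRODUCT: "normal"}


@dataclass(frozen=True)
class RenderStyle:
    """Glyph and arc styling for SBGN-PD pattern images."""

    species_shape: str = "box"          # rounded rectangle
    reaction_shape: str = "square"      # small process square
    image_format: str = "png"           # png (default) or pdf
    show_sbo_terms: bool = True         # draw SBO text inside glyphs when present
    node_color: str = "white"
    edge_color: str = "black"

    def __post_init__(self) -> None:
        if self.image_format not in ("png", "pdf"):
            raise ContractError(f"unsupported image format {self.image_format!r}")


def split_pattern_file(
    patterns_path: Union[str, Path], out_dir: Union[str, Path]
) -> list[Path]:
    """Split a mined-patterns DOT file into one file per pattern.

    File names are ``<frequency>_<identifier>.dot`` with the identifier
    disambiguating equal frequencies in file order.  Content round-trips
    through the DOT reader.
    """
    patterns_path = Path(patterns_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = read_dot(patterns_path)
    counters: dict[int, int] = {}
    written = []
    for graph, freq, ids in entries:
        if freq is None:
            raise FormatError(
                f"{patterns_path}: digraph without '#=> frequency' comment"
            )
        counters[freq] = counters.get(freq, 0) + 1
        path = out_dir / f"{freq}_{counters[freq]}.dot"
        shim = Pattern(
            graph=graph,
            support=freq,
            supporting_ids=ids,
            supporting_models=[],
            pattern_id=f"{freq}_{counters[freq]}",
        )
        write_patterns_dot([shim], path)
        written.append(path)
    return written


def styled_dot(
    pattern: Union[Pattern, LabelledDigraph], style: RenderStyle = RenderStyle()
) -> str:
    """Render a pattern as styled DOT text encoding the SBGN-PD glyphs.

    Node statements carry shape attributes (rounded box / small square),
    edge statements carry arrowhead attributes; textual labels are
    suppressed in structural mode and show the SBO term in semantics
    mode.  Deterministic: a pure function of (pattern, style).
    """
    graph = pattern.graph if isinstance(pattern, Pattern) else pattern
    if graph.n_nodes == 0:
        raise ContractError("cannot render an empty pattern")
    lines = ["digraph pattern {", "  rankdir = LR;"]
    for nid in graph.node_ids():
        lab = graph.nodes[nid]
        text = lab.sbo_term if (style.show_sbo_terms and lab.sbo_term) else ""
        if lab.kind == SPECIES:
            attrs = (
                f'shape = {style.species_shape}, style = rounded, '
                f'label = "{text}"'
            )
        else:
            attrs = (
                f"shape = {style.reaction_shape}, fixedsize = true, "
                f'width = 0.25, height = 0.25, label = "{text}"'
            )
        lines.append(f"  {nid} [{attrs}];")
    for src, tgt, label in sorted(graph.edges):
        lines.append(
            f"  {src} -> {tgt} [arrowhead = {_ARROWHEADS[label]}, "
            f'color = {style.edge_color}, xlabel = ""];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def _layered_layout(graph: LabelledDigraph) -> dict[str, tuple[float, float]]:
    """Simple deterministic left-to-right layered layout along edge direction."""
    layer: dict[str, int] = {n: 0 for n in graph.nodes}
    for _ in range(graph.n_nodes):
        changed = False
        for src, tgt, _lab in sorted(graph.edges):
            if layer[tgt] < layer[src] + 1 and layer[src] + 1 <= graph.n_nodes:
                layer[tgt] = layer[src] + 1
                changed = True
        if not changed:
            break
    columns: dict[int, list[str]] = {}
    for n in sorted(graph.nodes):
        columns.setdefault(layer[n], []).append(n)
    pos = {}
    for x, col in enumerate(sorted(columns)):
        members = columns[col]
        for y, n in enumerate(members):
            pos[n] = (float(x), -(y - (len(members) - 1) / 2.0))
    return pos


def render_pattern(
    pattern: Union[Pattern, LabelledDigraph],
    out_base: Union[str, Path],
    style: RenderStyle = RenderStyle(),
) -> tuple[Path, Optional[Path]]:
    """Write styled DOT and a rendered image for one pattern.

    Returns ``(dot_path, image_path)``; the image is ``out_base`` with
    the style's format extension.  The styled DOT is always written
    first, so a failing image backend still leaves the DOT artefact.
    """
    graph = pattern.graph if isinstance(pattern, Pattern) else pattern
    out_base = Path(out_base)
    dot_path = out_base.with_suffix(".styled.dot")
    dot_path.parent.mkdir(parents=True, exist_ok=True)
    dot_path.write_text(styled_dot(pattern, style), encoding="utf-8")

    pos = _layered_layout(graph)
    fig, ax = plt.subplots(figsize=(2 + 1.3 * len({p[0] for p in pos.values()}), 3))
    ax.set_aspect("equal")
    ax.axis("off")
    for nid, (x, y) in pos.items():
        lab = graph.nodes[nid]
        text = lab.sbo_term if (style.show_sbo_terms and lab.sbo_term) else ""
        if lab.kind == SPECIES:
            ax.add_patch(
                FancyBboxPatch(
                    (x - 0.32, y - 0.16), 0.64, 0.32,
                    boxstyle="round,pad=0.02,rounding_size=0.08",
                    facecolor=style.node_color, edgecolor=style.edge_color,
                )
            )
        else:
            ax.add_patch(
                Rectangle(
                    (x - 0.11, y - 0.11), 0.22, 0.22,
                    facecolor=style.node_color, edgecolor=style.edge_color,
                )
            )
        if text:
            ax.text(x, y, text, ha="center", va="center", fontsize=5)
    for src, tgt, label in sorted(graph.edges):
        (x1, y1), (x2, y2) = pos[src], pos[tgt]
        arrowstyle = {"IS_REACTANT": "-", "IS_MODIFIER": "-", "HAS_PRODUCT": "-|>"}[label]
        ax.add_patch(
            FancyArrowPatch(
                (x1, y1), (x2, y2),
                arrowstyle=arrowstyle, mutation_scale=12,
                color=style.edge_color, shrinkA=14, shrinkB=14,
            )
        )
        if label == IS_MODIFIER:
            # circle head near the target (the modified reaction)
            cx = x2 + (x1 - x2) * 0.22
            cy = y2 + (y1 - y2) * 0.22
            ax.add_patch(
                Circle((cx, cy), 0.045, facecolor="white", edgecolor=style.edge_color)
            )
    xs = [p[0] for p in pos.values()]
    ys = [p[1] for p in pos.values()]
    ax.set_xlim(min(xs) - 0.8, max(xs) + 0.8)
    ax.set_ylim(min(ys) - 0.8, max(ys) + 0.8)
    image_path = out_base.with_suffix(f".{style.image_format}")
    try:
        fig.savefig(image_path, dpi=150, bbox_inches="tight")
    finally:
        plt.close(fig)
    return dot_path, image_path


def render_all(
    patterns: Sequence[Pattern],
    out_dir: Union[str, Path],
    style: RenderStyle = RenderStyle(),
) -> list[Path]:
    """Render every pattern into *out_dir*, named by pattern id."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = []
    for p in patterns:
        _, img = render_pattern(p, out_dir / p.pattern_id, style)
        images.append(img)
    return images


def count_style_statements(dot_text: str) -> tuple[int, int]:
    """Count glyph (shape) and arc (arrowhead) statements in styled DOT."""
    glyphs = len(re.findall(r"shape\s*=", dot_text))
    arcs = len(re.findall(r"arrowhead\s*=", dot_text))
    return glyphs, arcs
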