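"""Render mined patterns as SBGN process-description images.

Draws the species-as-modifier pattern — one species acting as modifier
of one reaction and reactant of another — as a rounded entity rectangle
with a circle-headed arc into one process square and a plain arc into
the other.  The styled DOT encodes the same glyph choices textually.
"""

from pathlib import Path

from sbmlpatterns import (
    IS_MODIFIER,
    IS_REACTANT,
    LabelledDigraph,
    NodeLabel,
    REACTION,
    SPECIES,
    render_pattern,
    styled_dot,
)

pattern = LabelledDigraph(
    {
        "Node_0": NodeLabel(SPECIES),
        "Node_1": NodeLabel(REACTION),
        "Node_2": NodeLabel(REACTION),
    },
    {
        ("Node_0", "Node_1", IS_MODIFIER),
        ("Node_0", "Node_2", IS_REACTANT),
    },
)

print("styled DOT (glyphs as shape/arrowhead attributes, no text labels):\n")
print(styled_dot(pattern))

out = Path("scratch/images")
out.mkdir(parents=True, exist_ok=True)
dot_path, image_path = render_pattern(pattern, out / "species_as_modifier")
print(f"wrote {dot_path} and {image_path}")
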