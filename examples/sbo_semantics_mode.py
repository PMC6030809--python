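"""Semantics-aware mining with Systems Biology Ontology terms.

In SBO mode node labels carry the ontology term as well as the kind, so
two structurally identical patterns separate when their biology differs:
a biochemical reaction (SBO:0000176) between simple chemicals
(SBO:0000247) is a different pattern from a phosphorylation
(SBO:0000216) of a polypeptide chain (SBO:0000252).
"""

from collections import Counter

from sbmlpatterns import (
    MiningConfig,
    REACTION,
    SPECIES,
    SynthConfig,
    combined_networks,
    generate_corpus,
    mine,
)

vocabulary = [
    ("SBO:0000247", SPECIES, 0.7),   # simple chemical
    ("SBO:0000252", SPECIES, 0.3),   # polypeptide chain
    ("SBO:0000176", REACTION, 0.6),  # biochemical reaction
    ("SBO:0000216", REACTION, 0.25),  # phosphorylation
    ("SBO:0000330", REACTION, 0.15),  # dephosphorylation
]

models, _ = generate_corpus(
    SynthConfig(n_models=20, sbo_vocabulary=vocabulary, seed=5)
)
patterns = mine(
    combined_networks(models),
    MiningConfig(min_support=12, max_edges=4, support_unit="model", mode="sbo"),
)
print(f"{len(patterns)} semantics-aware patterns shared by >= 12 of 20 models\n")
label_mix = Counter(
    tuple(sorted({lab.sbo_term for lab in p.graph.nodes.values()}))
    for p in patterns if p.n_edges >= 1
)
for terms, n in sorted(label_mix.items(), key=lambda kv: -kv[1])[:5]:
    print(f"  {n} patterns over terms {', '.join(terms)}")
# Splitting labels by ontology term thins each pattern's support, so
# fewer, more specific patterns pass the same threshold.
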