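"""Mine frequent patterns from a synthetic 30-model corpus.

Generates models shaped like small curated biochemical models (3-11
species, 3-12 reactions each), then mines every connected subgraph
occurring in at least 20 of the 30 models.  Support counts each model
once, no matter how often a pattern repeats inside it.
"""

from collections import Counter

from sbmlpatterns import (
    MiningConfig,
    SynthConfig,
    combined_networks,
    generate_corpus,
    mine,
)

models, ledger = generate_corpus(SynthConfig(n_models=30, seed=1))
networks = combined_networks(models)
print(f"{len(models)} models -> {len(networks)} connected reaction networks")

patterns = mine(
    networks,
    MiningConfig(min_support=20, max_edges=10, support_unit="model"),
)
print(f"{len(patterns)} frequent patterns (support interval [20, 30])\n")

sizes = Counter(p.n_entities for p in patterns)
print("pattern sizes (entities -> count):", dict(sorted(sizes.items())))

print("\nmost widely shared patterns:")
for p in sorted(patterns, key=lambda p: -p.support)[:5]:
    print(
        f"  {p.pattern_id}: {p.n_entities} entities, {p.n_edges} edges, "
        f"shared by {p.support} models"
    )
# Single nodes are shared by every model; larger chains through shared
# species are frequent in fewer models, and support never increases as
# patterns grow (anti-monotonicity).
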