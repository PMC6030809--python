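"""Quantitative corpus analysis: totals, means and reaction classes.

Computes, for a generated corpus, the node-type totals, per-model means
and the reaction-class histogram — how many reactions have a given
(reactants, modifiers, products) participation signature.  In curated
repositories the 2-reactants/1-product and 1-reactant/1-product classes
dominate.
"""

from sbmlpatterns import SynthConfig, corpus_statistics, generate_corpus

models, _ = generate_corpus(SynthConfig(n_models=30, seed=1))
stats = corpus_statistics(models)

print(f"models: {stats.models_total}")
print(f"  with species:   {stats.models_with_species}")
print(f"  with reactions: {stats.models_with_reactions}")
print(f"species nodes: {stats.total_species_nodes} "
      f"(mean {stats.mean_species_per_model:.1f}/model)")
print(f"reaction nodes: {stats.total_reaction_nodes} "
      f"(mean {stats.mean_reactions_per_model:.1f}/model)")
r, m, p = stats.role_totals
print(f"participations: {r} reactant, {m} modifier, {p} product")

print("\nmost common reaction classes (reactants/modifiers/products):")
top = sorted(stats.class_histogram.items(), key=lambda kv: -kv[1])[:5]
for rc, n in top:
    print(f"  {rc.text()}: {n} reactions")
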