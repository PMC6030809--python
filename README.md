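# sbmlpatterns

Frequent structural pattern mining in SBML-encoded biochemical reaction
networks.

Computational models of cell biology are published by the hundreds in the
Systems Biology Markup Language (SBML), and most of them are, at heart,
reaction networks: species and reactions connected by reactant, modifier
and product roles. Researchers comparing such models want to know which
substructures recur — which reaction shapes are common, whether postulated
motifs (production/degradation cycles, feedback loops) are actually
encoded, and which models share structure. `sbmlpatterns` answers these
questions by frequent subgraph mining: it extracts each model's reaction
networks as labelled bipartite digraphs and finds **every** connected
subgraph that occurs in at least *min* and at most *max* of them.

## The graph model and the mining semantics

Each model becomes one or more weakly connected digraphs with

* node labels `SBML_SPECIES` / `SBML_REACTION` (optionally refined by an
  SBO ontology term in semantics-aware mode), and
* edge labels `IS_REACTANT`, `IS_MODIFIER` (species → reaction) and
  `HAS_PRODUCT` (reaction → species).

A pattern `P` *occurs* in a graph `G` if an injective, label- and
direction-preserving map `P → G` exists (a non-induced embedding). The
support of `P` is the number of graphs — networks, or models — containing
at least one embedding; multiplicity inside a graph does not count.
Mining is extension-based in the gSpan tradition: starting from frequent
node labels, patterns grow one edge at a time, and the **minimum DFS
code** — extended with a direction flag ordered after the edge label —
serves as the canonical form that de-duplicates isomorphic candidates.
Anti-monotonicity of support prunes the search. Mined patterns can then
be rendered as SBGN process-description glyphs, exported as Cypher
queries for a graph database, and counted per model into a model ×
pattern feature matrix whose rows are structural feature vectors.

## Worked example

The smallest interesting input is one species that is the product of one
reaction and the reactant of another:

```python
from sbmlpatterns import orient_edges, split_components

tuples = {("100233", "HAS_PRODUCT", "100186"),
          ("100229", "HAS_REACTANT", "100186")}
networks = split_components(orient_edges(tuples), model_id="cdc2k")
```

Running `python examples/worked_example.py` prints

```
oriented edges (reactants/modifiers point into the reaction):
  100186 -> 100229  [IS_REACTANT]
  100233 -> 100186  [HAS_PRODUCT]

connected reaction networks: 1
  network cdc2k#1: 3 nodes, 2 edges
```

The `HAS_REACTANT` tuple was re-oriented to point into its reaction; the
two edges share species 100186, so they form a single connected network.

Mining a 30-model synthetic corpus (`python
examples/mine_synthetic_corpus.py`) at support interval [20, 30]:

```
30 models -> 33 connected reaction networks
56 frequent patterns (support interval [20, 30])

pattern sizes (entities -> count): {1: 2, 2: 3, 3: 9, 4: 15, 5: 18, 6: 9}
```

Every subgraph of a frequent pattern appears too (anti-monotonicity), so
the inventory runs from the two single-node patterns shared by all 30
models down to five- and six-entity chains shared by exactly 20.

The other scripts in `examples/` demonstrate the feature matrix and
query export, SBGN-style rendering, semantics-aware (SBO) mining and the
corpus statistics report. The same stages are scriptable from a shell via
the `sbmlpatterns` command (`extract`, `mine`, `render`, `distribute`,
`stats`, `simulate`).

## Scope

The package emits query text in the Cypher dialect of the MaSyMoS graph
database but does not connect to one; model retrieval from repositories,
CellML support, and similarity/clustering on top of the feature matrix
are out of scope.
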