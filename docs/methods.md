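# Methods

## Graph extraction

SBML Level 2/3 documents are reduced to participation three-tuples
`(reaction, role, species)` with roles `HAS_REACTANT`, `HAS_MODIFIER`,
`HAS_PRODUCT`. Only explicitly connected entities count: SBML rules
relate entities implicitly and are ignored, so a rules-only model
contributes no network. Repeated listings of a species in one role of
one reaction (stoichiometry > 1, duplicated references) collapse to one
tuple — the graph model carries no multiplicity — while the same species
in two roles of one reaction keeps both tuples, giving parallel edges
with distinct labels. Orientation follows the flow of matter and
influence: reactant and modifier edges run species → reaction, product
edges reaction → species. Components are split under *weak*
connectivity (direction ignored), since a species must join the
reactions producing it to those consuming it. Unconnected networks from
one model stay separate for mining; their shared model identity is kept
only as provenance for model-level support and the feature matrix.

SBML parsing and writing are implemented directly over `lxml`,
restricted to the handful of elements the workflow reads
(`listOfSpecies`, `listOfReactions`, species references, `sboTerm`);
namespace handling is local-name based so Level 2 and Level 3 documents
parse identically. The DOT dialect used for networks and patterns is
similarly narrow by design (plain node/edge statements with a `label`
attribute, a trailing `#=> frequency[ids,]` comment per pattern), and
the package ships its own tolerant reader and canonical writer for it;
general DOT features are out of scope. Connected-component splitting
uses `networkx`.

## Semantics-aware mode

In SBO mode a node label is the pair (kind, SBO accession); equality of
labels — hence pattern isomorphism — requires both to match. `sboTerm`
attributes are normalised to `SBO:0000NNN` (SBML also allows the bare
integer). A model enters the SBO corpus only if every node of every one
of its networks carries a term: the strictest reading of an "annotated"
model, chosen because partial annotation would make one pattern's
support depend on an arbitrary mix of labelled and unlabelled nodes.
The filter is a flag (`require_full_annotation`) for corpora where a
looser rule is wanted. In network/pattern DOT files an SBO-refined
label is written `KIND:SBO:0000NNN`.

## Canonical form

Two patterns are the same if a label-preserving digraph isomorphism
relates them. The canonical form is the minimum DFS code: the
lexicographically smallest edge sequence over all depth-first
traversals, computed by the simultaneous-embedding search (grow all
embeddings realising the current minimal prefix; append the globally
minimal valid extension each round). The classic construction is
undirected; reaction networks are directed, so each code edge carries a
direction flag — 0 when the stored edge runs from the earlier discovery
index to the later — ordered *after* the edge label in comparisons.
The label orders are fixed for reproducibility: `SBML_REACTION` <
`SBML_SPECIES` (SBO-refined labels lexicographic on (kind, term)) and
`IS_REACTANT` < `IS_MODIFIER` < `HAS_PRODUCT`. Any fixed order yields a
valid canonical form; this one is simply documented. Single-node
graphs, which plain edge-based codes cannot express, get the degenerate
code `("N", label)`.

## Mining

`mine()` returns **all** frequent connected subgraphs — not only maximal
ones — within the support interval `[min_support, max_support]`, up to
`max_edges` edges. Search is level-wise: single-node patterns are
seeded from frequent node labels (required because one-entity patterns
are legitimate results; edge-seeded gSpan would miss them), then each
frequent pattern is extended by one edge. The bipartite direction rules
make the extension alphabet small: a fresh opposite-kind neighbour via
one of three roles, or one additional role edge between an existing
species/reaction pair. Candidates are de-duplicated by minimum DFS
code, and support is evaluated only on the parent's supporting set
(anti-monotone pruning). Completeness follows because every frequent
(k+1)-edge pattern loses either a spanning-tree leaf edge or a cycle
edge to a connected frequent k-edge sub-pattern, of which it is a
one-edge extension. Patterns whose support exceeds `max_support` are
withheld from output but still extended, since their extensions may
drop back into the interval.

Support is existence-based per transaction; a transaction is either one
connected network (default — frequency is then "number of reaction
networks containing the pattern") or one model (a model counts once if
any of its networks embeds the pattern). Both units are first-class
because result tables over model corpora are naturally phrased per
model while the mining definition is per network; network-unit patterns
also report the derived model support.

Subgraph isomorphism is NP-complete, and the all-subgraphs output can
grow combinatorially at low thresholds, so two caps guard the search:
`max_edges` (default 10, i.e. patterns up to 11 entities) bounds
pattern size, and `max_patterns` (default 200 000) raises an explicit
capacity error rather than exhausting memory. The embedding matcher is
a backtracking search over label- and degree-filtered candidates,
ordered to keep the matched frontier connected; it is authored
in-package because it must handle parallel differently-labelled edges
and sits in the miner's inner loop. The test suite cross-checks it
against exhaustive assignment enumeration and against networkx's VF2
monomorphism, and checks the miner against an independent
exhaustive-enumeration miner with a permutation-minimal canonical form.

## Pattern distribution

`count_embeddings` reports the raw number of injective assignments —
automorphic re-assignments count separately — because that is exactly
the row count of the emitted graph-database query, whose WHERE clause
lists all pairwise node inequalities. (Cypher additionally enforces
relationship uniqueness per MATCH, but under full node-inequality
constraints the two semantics coincide for these patterns.) An orbit
option divides by the pattern's automorphism count for users who want
distinct occurrences: the planted two-species/two-reaction cycle, for
instance, has |Aut| = 2, so one copy contributes a raw count of 2 and an
orbit count of 1. The feature matrix has one row per model (id, name)
and one column per pattern, ordered by descending frequency with ties
broken by pattern id. Queries anchor at the model/document pair via
`HAS_REACTION` when the pattern's first node is a reaction and
`HAS_SPECIES` when it is a species.

## Rendering

Visual correctness is asserted at the styled-DOT level — shape and
arrowhead attributes encoding the SBGN-PD glyph choices (rounded
rectangle entity, small square process, plain reactant arc, filled
product arrow, circle-headed modifier arc) — because raster output
varies across rendering backends. Styled DOT is a pure function of
(pattern, style). Images are drawn with matplotlib on a deterministic
layered left-to-right layout; PNG is the default format, PDF optional.
Structural mode draws no text; SBO mode writes the term inside the
glyph. Colours and stroke widths are package defaults, not prescribed
by any standard.

## Synthetic corpora

The generator emulates the size profile of small curated models: per
model, species and reaction counts uniform on 3–11 and 3–12, each
reaction drawing 1–4 distinct participants, each participation's role
sampled as reactant/modifier/product with probabilities .45/.10/.45.
The role split reflects that typical curated models are
reactant/product dominated; corpus-wide modifier excesses in real
repositories are driven by a few semi-automatically generated outlier
models, which this generator does not imitate. Patterns can be planted
into a chosen fraction of models — fresh nodes wired per the pattern,
optionally fusing one species onto an existing node (probability 0.5)
so copies embed in context — and every copy is recorded in a ground
truth ledger along with each model's exact edge list and SBO
assignment.

What the generator deliberately does *not* reproduce: cross-model
sharing of long pathway chains. Real curated models reuse common
mechanisms, so a real 30-model corpus supports frequent patterns up to
11 entities; independently sampled random models share only short
subgraphs (the 30-model experiment typically tops out at 5–7 entities
at support 20/30). Passing tests therefore demonstrate correctness of
extraction, mining, counting and rendering — not that random corpora
statistically resemble any particular repository.

## Problem sizes and numerics

Test and acceptance workloads are sized for a single CPU: oracle
comparisons use 20 networks of ≤ 10 nodes with patterns to 5 edges,
invariant sweeps 200 random corpora, embedding cross-checks 200 cases
on ≤ 8-node graphs, and the corpus experiment 30 models at the default
ranges — the whole surface recomputes in well under a minute. All
randomness flows from explicit seeds; mining output order is fully
deterministic (ascending edge count, then canonical code), and ties in
pattern naming are broken by that order. Degenerate inputs have defined
behaviour: empty corpora mine to empty lists, a support threshold above
the corpus size yields no patterns rather than an error, empty graphs
split into empty network sets, and empty patterns are rejected where an
anchor is required (queries, rendering).
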