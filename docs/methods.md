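# Methods

This note documents the models and procedures pathscape implements, the
parameters that matter, the numerical and design choices made where the
design was genuinely open, what the synthetic-data generators do and do not
emulate, and known limitations.

## The visualization model

The core container is a *compound graph*: entities (protein, gene, RNA,
compound, complex, family, pathway) can be nested inside groups with
semantics (complex, family, pathway, reaction co-factor satellite, generic,
star).  The hierarchy is a forest — every component has at most one parent,
cycles are rejected at construction, depth is unbounded.  Reactions are
hyperedges `(substrates, products, catalysts, co-factors, reversible)`;
a co-factor must itself be a substrate or product — it is a participant
*flagged* for satellite placement or hiding, not an extra role.  Binary
edges carry a relation type (activation, inhibition, phosphorylation,
binding, generic) and a direction flag.

**Stars.**  A star is a degenerate group with a designated hub member;
rendering attaches the remaining members radially to the hub with undirected
edges.  This construct is isolated behind one constructor
(`NetworkModel.add_star`) so a different reading can replace it without
touching anything else.

**Property layers.**  Appearance is resolved through four stacked layers:
built-in defaults (including per-kind shapes), a visual style (bundles keyed
by entity kind, expanded per component), user overrides, and projections.
Projections sit on top of user overrides — applied last so data always
shows; clearing the projection layer restores the override exactly.  The
canonical property names are label, shape, size, fill_color, stroke_color,
line_width, font, visible; one extra property, `direction`
(forward/reverse), supports the reaction-direction projection target.
Resolution is total: every (component, property) query returns a value.

**Collapse semantics.**  Collapsing a group only flips a flag and marks the
component topologically dirty; the re-attachment of member edges to the
group node happens at render time, so the model's own edge set is never
rewritten and expand is an exact inverse.  Parallel re-attached edges merge
into one aggregate edge whose integer multiplicity is the number of original
external member edges; the relation type survives when all merged edges
agree and degrades to `generic` otherwise.  Edges that end up inside one
collapsed node are hidden, not drawn as self-loops.  A collapsed
`reaction_cofactors` group hides its members entirely (that is the point of
the construct); when it is expanded, the co-factors and their edges rejoin
the parental layout.

**Aliasing.**  An entity with alias instances is drawn only through its
instances.  An edge that names an instance id attaches to that instance; an
edge that names the entity attaches to the lexicographically first instance
(deterministic, documented, and revisitable).  Merging aliases re-attaches
edges to the surviving instance and folds duplicates into multiplicities.

## Rendering

Rendering is three ordered steps: (1) topology — flatten the hierarchy into
drawable nodes/edges under the current collapse/visibility/alias state, with
reactions expanded into bipartite stars (substrate → reaction node →
product, catalyst — reaction, dashed); (2) attributes — resolve the full
property set of every element through the layer stack; (3) layout.  Model
mutations mark components dirty as topological, visual or layout changes.
`incremental_update` re-runs: all three steps on topological dirt, step 2
for affected elements only on visual dirt (plus a layout pass, since a size
change moves geometry), step 3 on layout dirt.  Its defining contract —
checked over a thousand randomized edit scripts — is deep equality with a
from-scratch render.  Dirty granularity is per component; a dirty member of
a collapsed group affects the group's render node.

SVG output is built with fixed two-decimal coordinate formatting and sorted
element order, so a fixed input and seed yield byte-identical files.
Time-series glyphs are drawn as mini bar/line charts in a fixed 48×32 px box
replacing the node shape, annotated with min/max tick labels.  Compartment
bands (when the layered engine ran) are drawn as alternating background
strips labeled with layer names.

## Layouts

All engines emit node center positions plus edge routes (straight,
quadratic, orthogonal polyline), break ties by lexicographic node id, and
use pixel coordinates with the origin top-left and y growing downward.
A deterministic minimum-separation post-pass pushes overlapping node bodies
apart (hinted KEGG nodes are never moved; in layered mode separation is
horizontal only, preserving bands).

**Layered (Sugiyama).**  Layer assignment comes from subcellular
compartments: an ordered layer list (default extracellular,
plasma_membrane, cytoplasm, nuclear_membrane, nucleus — extracellular
topmost) plus a term-alias map, loadable from YAML.  A node with several
mapped terms takes the *topmost* layer; its ambiguity count is the number of
distinct mapped layers; unannotated nodes land in a configured fallback
(default cytoplasm).  Full gene-ontology traversal is deliberately reduced
to this flat ordered model — the alias map is where ontology knowledge goes.
Crossing reduction is iterative barycenter with 8 alternating sweeps
(adequate for desk-scale graphs); the best ordering seen is kept, so the
result never has more crossings than the initial lexicographic order.
Edges spanning several bands run through internal dummy nodes and are
emitted as polylines.  Band height is 120 px, in-band spacing 90 px.

**Force.**  Fruchterman–Reingold via networkx with a fixed seed, then a
rescaling so the median edge length equals a target (default 80 px) —
layouts stay readable instead of stretching to the canvas.  Above 1500
nodes, pairwise repulsion being quadratic, the engine switches to seeded
random placement refined by ten vectorized neighbor-averaging sweeps
(linear in the edge count); the switch is a documented size-dependent
setting, and determinism is preserved.  After placement, each reaction's
co-factors are re-placed on an arc (default radius 60 px) around the
reaction node: consumed co-factors on the incoming side of the
substrate→product flow vector, produced ones on the outgoing side.

**KEGG.**  Hinted nodes keep their KGML coordinates verbatim (checked
exactly); un-hinted nodes are force-laid and scaled into the hinted bounding
box.  Routes are straight unless the segment would cross a third node's
body (Liang–Barsky segment/rectangle clipping, 1 px padding); then two-bend
orthogonal candidates (horizontal-vertical-horizontal and
vertical-horizontal-vertical, with ±30/±60 px mid-line shifts) are tried in
a fixed order and the first collision-free one wins; if none clears, the
straight route is kept rather than inventing an arbitrary detour.  Reaction
arrows are quadratic Bézier curves with an 18% perpendicular bulge.

## Projection

Series rows are keyed by identifier *sets*; a row maps to every entity whose
id or xref accessions intersect the set, optionally expanded through a
two-column mapping table.  Matching is case-sensitive and exact.  Multiple
rows mapping to one entity are averaged before scaling — the same convention
as multi-sample selection, where the temporary sample is the per-row mean
over non-missing values (a row missing everywhere stays missing).

The formula evaluator parses `+ - * / ^` (caret right-associative), unary
minus, parentheses and calls, row-wise over sample columns.  Built-ins:
`mean` (missing-skipping, so `mean(...)` is exactly the mean-sample
operation — a cross-checked equivalence), `log2`, `log10`, `abs`, `min`,
`max`, `zscore` (over the rows of its argument, population ddof=0, matching
the scipy convention).  Arithmetic operators propagate missing values;
division by zero yields missing with a warning; non-positive log arguments
yield missing.  `register_function` lets callers plug in arbitrary callables
per function name, which is the hook through which an external statistics
engine can serve user-defined functions.

Projection targets: fill color through a three-anchor diverging scale
(default blue `#0000FF` – white – red `#FF0000`, domain symmetric about 0;
linear per RGB channel, exact at the anchors, clamped outside); node size
and line width through a linear size scale; visibility through a threshold
predicate (optionally on |value|); time-series glyphs (one group-mean per
ordered group); compartment coloring (red `#FF0000` for exactly one
annotated compartment, rose `#FFC0CB` for several, white for none — the
values are package defaults and configurable); and reaction direction,
where a negative projected value flips a *reversible* reaction's rendered
arrows (irreversible reactions are never flipped).  The missing-value
policy defaults to leaving the lower-layer appearance untouched; `hide` and
`neutral_color` are available.  Projections never mutate the series or the
model's lower layers.

## Analysis

Flattening policies make the hierarchy explicit: families either split into
members (each inheriting every family edge) or stay single nodes; complexes
stay single, expand to pairwise bidirectional binding edges (a clique — an
approximation, documented as such), or keep the complex node with a star to
members; reactions stay bipartite or contract to one substrate→product edge
per pair (reversible reactions also get the reverse edges); aliases merge
or stay separate; co-factor participation edges can be dropped.  The flat
graph is a simple digraph — parallel edges fold into a multiplicity count
while path weights stay 1 per edge unless a weight hook overwrites them.
Origin maps record the model components behind every flat node and edge.

k shortest loopless paths use Yen's algorithm over a Dijkstra whose heap key
is the full deterministic ordering `(total weight, hop count, lexicographic
node sequence)`, so results are totally ordered and reproducible; the
independent test oracle is exhaustive simple-path enumeration sorted by the
same key.  BFS distances respect edge direction by default with an
undirected option.  Back-projection paints every origin component of result
nodes/edges into a projection-scope layer (paths: one highlight color;
distance maps: a dark-to-light sequential scale with distance 0 darkest);
it refuses to run if the model's topology changed after flattening
(a revision counter detects staleness).

## Synthetic data

The generators exist so every code path is testable offline; they emulate
structural and statistical shape, not biology.

- `gen_ppi_sif(n_nodes, n_edges, seed)` — connected preferential-attachment
  interaction networks (`pp` relation), exact unique edge counts, scaling to
  the 100,000-edge regime used in the acceptance run (20,000 nodes).
- `gen_metabolic_kgml(n_reactions, seed)` — a chain-with-branches reaction
  network; every entry carries graphics on an 80 px grid; ATP/ADP-analog
  currency metabolites participate in about half the reactions and are
  returned as a side list to exercise co-factor strategies.
- `gen_regulatory_model(n, cm, seed)` — receptors at the plasma membrane,
  kinases in the cytoplasm, transcription factors in the nucleus, edges
  oriented strictly downward; exactly 10% of entities get a second
  (ambiguous) compartment and 10% none, covering the red/rose/white cases.
- `gen_omics_series(ids, n_samples, n_groups, effects, seed)` — log-normal
  baseline (log-mean 3.0, sigma 0.8), per-group log2 shifts ramped linearly
  across groups, Gaussian log-space noise (sd 0.25), 5% missing values, and
  a truth table for recovery tests.

What passing tests on these fixtures shows: the machinery is correct under
known structure.  What it does not show: robustness to real-world identifier
chaos, heavy-tailed degree distributions beyond preferential attachment, or
biologically meaningful layouts — those need real data.

## Numerical and design choices

- Determinism everywhere: seeded RNGs, sorted iteration, lexicographic
  tie-breaks, fixed float formatting in SVG.  Identical inputs and seed give
  byte-identical SVG.
- Auto-generated component ids use a monotone counter with a fixed prefix.
- SIF complex-membership and co-factor lines key their groups by the line's
  source identifier (the dialect has no explicit grouping construct).
- The project JSON schema is versioned (currently 1); a version mismatch is
  an explicit error naming both versions, and a truncated file is a parse
  error with no partial model.
- Acceptance-scale problem sizes: the scale run uses 20,000 nodes /
  100,000 edges; incremental-vs-full uses 1000 edit scripts over models of
  5–12 entities; path oracles use 500 random digraphs of ≤ 8 nodes (small
  enough for exhaustive enumeration to stay an independent oracle).

## Limitations

- No GUI, no interactivity, no animation — this is a library plus CLI.
- BioPAX and full SBML (rules, events, FBC) are out of scope; the SIF and
  SBML-core paths cover network import testably.
- The SOFT dialect is the minimal sample-table form; full GEO semantics are
  not parsed.
- The clique flattening of complexes overstates connectivity (documented
  approximation).
- Large-graph force layout trades repulsion accuracy for linear cost above
  1500 nodes; it guarantees completion and determinism, not aesthetics.
- Orthogonal routing is used only for KEGG edge avoidance, not as a general
  layout style.
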