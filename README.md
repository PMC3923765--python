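# pathscape

A headless Python toolkit for drawing biological networks the way
biochemistry textbooks do, and for analyzing omics data in their context.
It is aimed at computational biologists who need reproducible,
publication-quality network figures and scriptable analyses — without a GUI.

## What it does

Biological networks are not plain graphs.  Protein complexes, families and
pathways group entities hierarchically; a biochemical reaction is a
*hyperedge* joining substrates, products and catalysts; ubiquitous currency
metabolites (ATP, NAD⁺, …) clutter drawings unless treated as satellites or
hidden; and one compound may need several visual instances (aliases) in
different pathway contexts.  pathscape models all of this directly:

- **Hierarchical model** — entities, collapsible groups, reaction
  hyperedges, binary regulatory edges, aliasing, and a four-level property
  stack (`default < style < user override < projection`) so projected data
  always wins and can be removed without losing manual styling.
- **Three-step rendering** — (1) topology construction (collapsed groups
  become single nodes with aggregate edges carrying multiplicity counts;
  reactions expand into bipartite stars), (2) attribute resolution,
  (3) layout.  Edits mark components dirty as *topological*, *visual* or
  *layout* changes, and incremental re-rendering re-runs only the steps a
  change requires — with the contract that the result deep-equals a
  from-scratch render.
- **Layouts** — force-directed with co-factor orbit placement along the
  reaction flow; Sugiyama layered layout whose bands are subcellular
  compartments (extracellular at the top, nucleus at the bottom), so
  signaling cascades read downward; and a KEGG-style layout that keeps KGML
  coordinates verbatim and computes the missing edge routes.
- **Omics projection** — tabular series (CSV/TSV, minimal SOFT) with grouped
  samples, identifier mapping, derived samples via a formula evaluator
  (`log2(treated/control)`, `zscore(...)`, pluggable user functions), and
  projection targets from fill color through visibility thresholds to
  per-node time-series glyph charts.  Subcellular-location certainty renders
  as red (one compartment), rose (ambiguous) or white (no annotation).
- **Analysis** — configurable flattening of the hierarchy into a simple
  digraph (split families into members, contract reactions to
  substrate→product edges, merge aliases, drop co-factors), Yen's k shortest
  loopless paths with deterministic tie-breaking, BFS distances, and
  back-projection of results onto the drawing as highlights.
- **IO** — SIF (Cytoscape dialect, configurable relation translation), KGML,
  an SBML core subset, GraphML export, and a versioned JSON project format
  with lossless round trips.  Output is deterministic SVG 1.1.

## Worked example

Generate a small synthetic metabolic pathway (KGML with grid coordinates and
ATP/ADP currency metabolites), project a two-condition omics series onto
compound colors, and render a KEGG-style SVG:

```python
from pathscape.fixtures import gen_metabolic_kgml, gen_omics_series
from pathscape.io import read_kgml
from pathscape.model import Kind
from pathscape.projection import (ColorScale, ProjectionSpec,
                                  map_rows_to_entities, project)
from pathscape import rendering

xml, cofactors = gen_metabolic_kgml(5, seed=8)
model, hints = read_kgml(xml)
compounds = sorted(e for e, ent in model.entities.items()
                   if ent.kind is Kind.COMPOUND)
series, _ = gen_omics_series(compounds, 4, 2, seed=8, missing_fraction=0.0)

spec = ProjectionSpec(
    series_name=series.name,
    formula="log2(mean(g1_r0, g1_r1) / mean(g0_r0, g0_r1))",
    target="fill_color", scale=ColorScale(domain=(-2, 0, 2)))
row_map = map_rows_to_entities(series, model)
layer = project(model, series, spec, row_map)

rg = rendering.full_render(model, "kegg", {"hints": hints, "seed": 1})
svg = rendering.render_svg(rg)
```

This prints/produces, deterministically:

```
entities: 13  reactions: 5  layout hints: 13  currency metabolites: ['1', '2']
mapped rows: 8 of 8
  1   cpd:ATP     {'fill_color': '#E5E5FF'}
  10  cpd:C0003   {'fill_color': '#D9D9FF'}
  13  cpd:C0004   {'fill_color': '#D5D5FF'}
render nodes: 18  edges: 23  svg bytes: 6243
```

All 13 hinted entries keep their KGML pixel coordinates exactly; the five
reactions are drawn as bipartite stars with quadratic-curve arrows; the pale
blue fills are the log2 fold changes of each compound passed through the
blue–white–red diverging scale (values near zero give near-white).

The same pipeline is available from the shell:

```sh
pathscape gen kgml --reactions 5 --seed 8 --out pathway.xml
pathscape render pathway.xml --projection spec.yaml --data omics.tsv \
    --out figure.svg --seed 1
pathscape analyze paths net.sif --source A --target C -k 2 --out paths.json
```

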