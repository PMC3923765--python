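"""GraphML export/import for flattened graphs (networkx-backed).

Node attributes ``label`` and edge attributes ``relation``, ``weight`` and
``multiplicity`` are declared as GraphML keys; round trips preserve graph
structure and attribute values.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Union

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from ..analysis import FlatGraph


def write_graphml(flat: Union["FlatGraph", nx.Graph]) -> str:
    g = flat.graph if hasattr(flat, "node_origin") else flat
    out = nx.generate_graphml(g, named_key_ids=True)
    return "\n".join(out) + "\n"


def read_graphml(text: str) -> nx.DiGraph:
    g = nx.parse_graphml(text, node_type=str)
    if not g.is_directed():
        g = g.to_directed()
    return g
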