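"""Synthetic-data generators.

Every reader, layout and projection in the package can be exercised without
any download: protein-protein interaction SIF files of arbitrary size,
KGML-style metabolic chains with grid coordinates and currency metabolites,
regulatory cascade models with subcellular-compartment annotation, and omics
series with known group effects.  All generators are deterministic per seed
and emit exactly the dialects the readers consume.
"""

from __future__ import annotations

import random

import numpy as np

from .errors import ParameterError
from .layouts import CompartmentModel
from .model import Edge, Entity, Kind, NetworkModel, Relation
from .series import DataSeries


def gen_ppi_sif(n_nodes: int, n_edges: int, seed: int = 0) -> str:
    """Connected preferential-attachment PPI network as SIF text.

    Relation type is ``pp``; exactly ``n_edges`` unique unordered pairs.
    Node count must allow that many distinct pairs and edges must suffice to
    connect the graph.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ParameterError(
            f"{n_edges} edges impossible with {n_nodes} nodes (max {max_edges})")
    if n_edges < n_nodes - 1:
        raise ParameterError(
            f"{n_edges} edges cannot connect {n_nodes} nodes")
    rng = random.Random(seed)
    width = len(str(n_nodes - 1))
    names = [f"P{i:0{width}d}" for i in range(n_nodes)]

    # spanning tree by preferential attachment
    edges: set[tuple[int, int]] = set()
    endpoints: list[int] = [0]
    for i in range(1, n_nodes):
        j = endpoints[rng.randrange(len(endpoints))]
        edges.add((min(i, j), max(i, j)))
        endpoints += [i, j]
    # extra edges, still degree-biased
    attempts = 0
    while len(edges) < n_edges:
        i = endpoints[rng.randrange(len(endpoints))]
        j = endpoints[rng.randrange(len(endpoints))]
        attempts += 1
        if i == j:
            continue
        pair = (min(i, j), max(i, j))
        if pair in edges:
            # dense regimes: fall back to uniform sampling to finish
            if attempts > 20 * n_edges:
                i, j = rng.randrange(n_nodes), rng.randrange(n_nodes)
                if i == j:
                    continue
                pair = (min(i, j), max(i, j))
                if pair in edges:
                    continue
            else:
                continue
        edges.add(pair)
        endpoints += [pair[0], pair[1]]

    lines = [f"{names[i]}\tpp\t{names[j]}" for i, j in sorted(edges)]
    return "\n".join(lines) + "\n"


def gen_metabolic_kgml(n_reactions: int, seed: int = 0) -> tuple[str, list[str]]:
    """KGML text for a chain-with-branches reaction network, plus the ids of
    its currency metabolites (ATP/ADP analogs) for co-factor strategies.

    Every entry carries graphics coordinates on an 80-px grid.
    """
    if n_reactions < 1:
        raise ParameterError("need at least one reaction")
    rng = random.Random(seed)
    entries: list[str] = []
    reactions: list[str] = []
    grid = 80

    next_id = [1]

    def new_id() -> str:
        i = next_id[0]
        next_id[0] += 1
        return str(i)

    def entry(eid: str, name: str, etype: str, x: int, y: int,
              reaction: str = "") -> None:
        rattr = f' reaction="{reaction}"' if reaction else ""
        entries.append(
            f'  <entry id="{eid}" name="{name}" type="{etype}"{rattr}>\n'
            f'    <graphics name="{name}" x="{x}" y="{y}" width="46" '
            f'height="17" type="rectangle"/>\n'
            f'  </entry>'
        )

    # currency metabolites shared across reactions
    atp, adp = new_id(), new_id()
    entry(atp, "cpd:ATP", "compound", grid, grid * 6)
    entry(adp, "cpd:ADP", "compound", grid * 2, grid * 6)
    cofactor_ids = [atp, adp]

    compounds = [new_id()]
    entry(compounds[0], "cpd:C0000", "compound", grid, grid)
    for r in range(n_reactions):
        col = (r + 1) * 2
        substrate = compounds[-1] if rng.random() < 0.8 or len(compounds) < 2 \
            else compounds[rng.randrange(len(compounds))]
        product = new_id()
        entry(product, f"cpd:C{r + 1:04d}", "compound", grid * (col + 1), grid)
        rname = f"rn:R{r + 1:05d}"
        enzyme = new_id()
        entry(enzyme, f"ec:1.1.1.{r + 1}", "enzyme", grid * col, grid * 3,
              reaction=rname)
        use_currency = rng.random() < 0.5
        subs = [f'    <substrate id="{substrate}" name="s"/>']
        prods = [f'    <product id="{product}" name="p"/>']
        if use_currency:
            subs.append(f'    <substrate id="{atp}" name="cpd:ATP"/>')
            prods.append(f'    <product id="{adp}" name="cpd:ADP"/>')
        rtype = "reversible" if rng.random() < 0.3 else "irreversible"
        reactions.append(
            f'  <reaction id="{new_id()}" name="{rname}" type="{rtype}">\n'
            + "\n".join(subs + prods) + "\n  </reaction>"
        )
        compounds.append(product)

    xml = (
        '<?xml version="1.0"?>\n'
        '<pathway name="path:syn00001" org="syn" number="00001" '
        'title="synthetic chain">\n'
        + "\n".join(entries) + "\n" + "\n".join(reactions) + "\n</pathway>\n"
    )
    return xml, cofactor_ids


def gen_regulatory_model(
    n_entities: int,
    compartment_model: CompartmentModel | None = None,
    seed: int = 0,
) -> NetworkModel:
    """Signaling-cascade model: receptors at the plasma membrane, kinases in
    the cytoplasm, transcription factors in the nucleus; edges oriented
    membrane -> nucleus.

    10% of entities receive a second compartment (ambiguous annotation) and
    10% none at all, exercising the red/rose/white certainty coloring.
    """
    cm = compartment_model or CompartmentModel()
    rng = random.Random(seed)
    model = NetworkModel(name="regulatory")
    tiers = ["plasma_membrane", "cytoplasm", "nucleus"]
    tier_prefix = {"plasma_membrane": "REC", "cytoplasm": "KIN", "nucleus": "TF"}
    members: dict[str, list[str]] = {t: [] for t in tiers}

    n_amb = max(1, round(0.10 * n_entities)) if n_entities >= 3 else 0
    n_none = max(1, round(0.10 * n_entities)) if n_entities >= 3 else 0
    statuses = (["ambiguous"] * n_amb + ["none"] * n_none
                + ["plain"] * (n_entities - n_amb - n_none))
    rng.shuffle(statuses)

    for i in range(n_entities):
        tier = tiers[min(i * len(tiers) // n_entities, len(tiers) - 1)]
        eid = f"{tier_prefix[tier]}{i:04d}"
        status = statuses[i]
        if status == "none":
            compartments = []
        elif status == "ambiguous":
            other = rng.choice([t for t in tiers if t != tier])
            compartments = [tier, other]
        else:
            compartments = [tier]
        model.add_entity(Entity(eid, kind=Kind.PROTEIN, compartments=compartments))
        members[tier].append(eid)

    # edges always point from an upper tier to the same or a lower tier
    eid_counter = 0
    for hi, lo in (("plasma_membrane", "cytoplasm"), ("cytoplasm", "nucleus")):
        for src in members[hi]:
            if not members[lo]:
                continue
            for tgt in rng.sample(members[lo], k=min(2, len(members[lo]))):
                eid_counter += 1
                relation = rng.choice(
                    [Relation.ACTIVATION, Relation.INHIBITION,
                     Relation.PHOSPHORYLATION])
                model.add_edge(Edge(f"reg{eid_counter:05d}", src, tgt,
                                    relation=relation))
    model.clear_dirty()
    return model


def gen_omics_series(
    entity_ids: list[str],
    n_samples: int,
    n_groups: int,
    effect_spec: dict[str, float] | None = None,
    seed: int = 0,
    missing_fraction: float = 0.05,
    noise_sd: float = 0.25,
) -> tuple[DataSeries, dict[str, list[float]]]:
    """Log-normal expression matrix with additive group effects.

    ``effect_spec`` maps entity id -> log2 effect applied linearly across
    groups (group g gets ``effect * g / (n_groups - 1)``); unlisted entities
    have no effect.  Returns the series and a truth table of each row's
    per-group true log2 shift for recovery tests.
    """
    if n_samples % n_groups:
        raise ParameterError("n_samples must be divisible by n_groups")
    effect_spec = effect_spec or {}
    rng = np.random.default_rng(seed)
    per_group = n_samples // n_groups
    groups = {f"g{g}": [f"g{g}_r{r}" for r in range(per_group)]
              for g in range(n_groups)}
    samples = [s for g in sorted(groups) for s in groups[g]]

    baseline = rng.lognormal(mean=3.0, sigma=0.8, size=len(entity_ids))
    truth: dict[str, list[float]] = {}
    matrix = np.empty((len(entity_ids), n_samples))
    for i, eid in enumerate(entity_ids):
        effect = float(effect_spec.get(eid, 0.0))
        shifts = [effect * g / max(n_groups - 1, 1) for g in range(n_groups)]
        truth[eid] = shifts
        col = 0
        for g in range(n_groups):
            vals = baseline[i] * 2.0 ** (
                shifts[g] + rng.normal(0.0, noise_sd, size=per_group))
            matrix[i, col:col + per_group] = vals
            col += per_group
    mask = rng.random(matrix.shape) < missing_fraction
    matrix[mask] = np.nan

    series = DataSeries(
        name=f"synthetic-omics-{seed}",
        row_ids=[frozenset([e]) for e in entity_ids],
        samples=samples,
        matrix=matrix,
        groups=groups,
    )
    return series, truth
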