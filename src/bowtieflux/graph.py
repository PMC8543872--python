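"""Graph-based bow-tie analysis with ranked currency-pair removal.

Each reaction contributes directed substrate->product links between its
carbon-containing participants (CO2, HCO3 and the acyl carrier protein
are never endpoints).  Currency pairs - co-substrate/co-product couples
that carry a chemical group (NADH/NAD, ATP/ADP, glutamate/2-oxoglutarate,
...) - are removed in rank order, stopping as soon as a single connected
pair would remain, which guarantees at least one link per carbon
reaction.  The bow-tie is then the largest strongly connected component
plus the reachability domains of any of its nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import cobra
import networkx as nx

from .bowtie import BowTiePartition
from .config import (
    DEFAULT_CURRENCY_PAIRS,
    DEFAULT_EXCLUDED_ENDPOINTS,
    CurrencyPair,
    split_compartment,
)
from .model_prep import _has_defined_formula

logger = logging.getLogger(__name__)

__all__ = ["MetaboliteGraph", "link_reaction", "build_graph", "bowtie_from_graph"]


def _eligible(met: cobra.Metabolite, excluded: Sequence[str]) -> bool:
    if not _has_defined_formula(met):
        return False
    if int(met.elements.get("C", 0)) < 1:
        return False
    base, _ = split_compartment(met.id, met.compartment)
    return base not in excluded


def _by_base(mets: Iterable[cobra.Metabolite]) -> dict[str, dict[str, str]]:
    """base id -> {compartment -> full id}."""
    out: dict[str, dict[str, str]] = {}
    for met in mets:
        base, comp = split_compartment(met.id, met.compartment)
        out.setdefault(base, {})[met.id if comp is None else comp] = met.id
    return out


def link_reaction(
    reaction: cobra.Reaction,
    currency_pairs: Sequence[CurrencyPair] = DEFAULT_CURRENCY_PAIRS,
    excluded: Sequence[str] = DEFAULT_EXCLUDED_ENDPOINTS,
) -> set[tuple[str, str]]:
    """Directed main-metabolite links contributed by one reaction.

    Starting from all substrate x product combinations of eligible
    carbon species, matched currency pairs are deleted in rank order;
    a deletion that would leave no pair is skipped and processing stops
    (the at-least-one-link guarantee).  Reversible reactions contribute
    both directions.
    """
    subs = {m for m, c in reaction.metabolites.items() if c < 0 and _eligible(m, excluded)}
    prods = {m for m, c in reaction.metabolites.items() if c > 0 and _eligible(m, excluded)}
    sub_ids = {m.id for m in subs}
    prod_ids = {m.id for m in prods}

    for pair in sorted(currency_pairs, key=lambda p: p.rank):
        if len(sub_ids) * len(prod_ids) <= 1:
            break
        hit = pair.in_reaction(_by_base(subs), _by_base(prods))
        if hit is None:
            continue
        s_id, p_id = hit
        if s_id not in sub_ids or p_id not in prod_ids:
            continue
        if (len(sub_ids) - 1) * (len(prod_ids) - 1) < 1:
            break  # removal would orphan the reaction: keep the pair, stop
        sub_ids.discard(s_id)
        prod_ids.discard(p_id)
        subs = {m for m in subs if m.id in sub_ids}
        prods = {m for m in prods if m.id in prod_ids}

    links = {(s, p) for s in sub_ids for p in prod_ids if s != p}
    if reaction.reversibility:
        links |= {(p, s) for s, p in links}
    return links


@dataclass
class MetaboliteGraph:
    """Directed metabolite graph after currency-pair removal.

    Parallel links from different reactions are merged; each edge keeps
    the list of contributing reactions, and ``raw_link_count`` is the
    pre-deduplication total.
    """

    graph: nx.DiGraph
    raw_link_count: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def contributors(self, source: str, target: str) -> list[str]:
        return self.graph.edges[source, target]["reactions"]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tn_reactions\treaction_ids\n")
            for s, t, data in sorted(self.graph.edges(data=True)):
                rids = data["reactions"]
                fh.write(f"{s}\t{t}\t{len(rids)}\t{','.join(rids)}\n")


def build_graph(
    model: cobra.Model,
    currency_pairs: Sequence[CurrencyPair] = DEFAULT_CURRENCY_PAIRS,
    excluded: Sequence[str] = DEFAULT_EXCLUDED_ENDPOINTS,
) -> MetaboliteGraph:
    """Union of link_reaction over all original (non-boundary,
    non-pseudo) reactions; nodes are all eligible carbon metabolites."""
    g = nx.DiGraph()
    for met in model.metabolites:
        if _eligible(met, excluded):
            g.add_node(met.id)
    raw = 0
    for rxn in model.reactions:
        if rxn.boundary:
            continue
        if (rxn.notes or {}).get("bowtieflux_kind") in {
            "sink", "demand", "energy_balance",
        }:
            continue
        for s, t in sorted(link_reaction(rxn, currency_pairs, excluded)):
            raw += 1
            if g.has_edge(s, t):
                g.edges[s, t]["reactions"].append(rxn.id)
            else:
                g.add_edge(s, t, reactions=[rxn.id])
    return MetaboliteGraph(graph=g, raw_link_count=raw)


def bowtie_from_graph(metgraph: MetaboliteGraph | nx.DiGraph) -> BowTiePartition:
    """Bow-tie partition of the metabolite graph.

    GSC = the largest strongly connected component (ties broken toward
    the lexicographically smallest member set, with a warning); IN/OUT =
    ancestors/descendants of any GSC node outside the GSC; IS = rest.
    The result does not depend on which GSC node is used.
    """
    g = metgraph.graph if isinstance(metgraph, MetaboliteGraph) else metgraph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    components = sorted(
        (sorted(c) for c in nx.strongly_connected_components(g)),
        key=lambda c: (-len(c), c),
    )
    if len(components) > 1 and len(components[0]) == len(components[1]):
        logger.warning(
            "tie for largest strongly connected component (size %d); "
            "choosing the lexicographically smallest", len(components[0]),
        )
    gsc = frozenset(components[0])
    anchor = components[0][0]
    out = frozenset(nx.descendants(g, anchor)) - gsc
    in_ = frozenset(nx.ancestors(g, anchor)) - gsc
    iso = frozenset(g.nodes) - gsc - out - in_
    return BowTiePartition(
        method="gba", sets={"GSC": gsc, "IN": in_, "OUT": out, "IS": iso}
    )
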