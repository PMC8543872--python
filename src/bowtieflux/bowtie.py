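"""Comprehensive sweep and FBA-based bow-tie classification.

The sweep exploits pathway transitivity: connectivity of the whole
mutually-interconvertible core is represented by one seed metabolite,
chosen from the biosynthetic precursors of central metabolism.  Every
carbon metabolite is then solved against the seed in both directions
and classified:

* GSC - producible from and consumable to the seed,
* IN  - consumable only,
* OUT - producible only,
* IS  - neither.

A pathway only counts when its carbon yield reaches the threshold tau
(default 20%), which filters out conversions where the nominal target
is a trace by-product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .model_prep import PreparedModel
from .pathways import PathwaySolution, _build_sink, solve_pathway

logger = logging.getLogger(__name__)

__all__ = [
    "PrecursorGrid",
    "ConnectivityTable",
    "BowTiePartition",
    "precursor_matrix",
    "select_seed",
    "sweep_connectivity",
    "classify_bowtie",
    "is_substructure",
]

CLASSES = ("GSC", "IN", "OUT", "IS")


@dataclass
class BowTiePartition:
    """Disjoint GSC/IN/OUT/IS cover of the carbon metabolites."""

    method: str                      # "fba" | "gba"
    sets: dict[str, frozenset[str]]
    seed: Optional[str] = None

    def __post_init__(self):
        if set(self.sets) != set(CLASSES):
            raise ValueError(f"partition must define exactly {CLASSES}")
        total = sum(len(s) for s in self.sets.values())
        union = frozenset().union(*self.sets.values())
        if total != len(union):
            raise ValueError("bow-tie subsets overlap")

    def __getitem__(self, cls: str) -> frozenset[str]:
        return self.sets[cls]

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset().union(*self.sets.values())

    @property
    def counts(self) -> dict[str, int]:
        return {cls: len(self.sets[cls]) for cls in CLASSES}

    def class_of(self, met_id: str) -> str:
        for cls in CLASSES:
            if met_id in self.sets[cls]:
                return cls
        raise KeyError(met_id)

    def to_frame(self) -> pd.DataFrame:
        records = [
            {"metabolite": mid, "class": cls}
            for cls in CLASSES
            for mid in sorted(self.sets[cls])
        ]
        return pd.DataFrame.from_records(records)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class PrecursorGrid:
    """All ordered precursor-pair pathway solutions."""

    precursors: tuple[str, ...]
    solutions: dict[tuple[str, str], PathwaySolution]

    @property
    def yields(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            0.0, index=list(self.precursors), columns=list(self.precursors)
        )
        for (s, t), sol in self.solutions.items():
            frame.loc[s, t] = sol.carbon_yield
        return frame

    @property
    def n_feasible(self) -> int:
        return sum(sol.feasible for sol in self.solutions.values())

    def feasibility_graph(self, tau: float = 0.0) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.precursors)
        for (s, t), sol in self.solutions.items():
            if sol.feasible and sol.carbon_yield >= tau - 1e-12:
                g.add_edge(s, t)
        return g


def precursor_matrix(
    prepared: PreparedModel,
    precursors: Optional[Sequence[str]] = None,
) -> PrecursorGrid:
    """Solve all ordered pairs among the configured precursors
    (n*(n-1) LPs).  Precursors absent from the model are dropped with a
    warning."""
    wanted = list(precursors if precursors is not None else prepared.config.precursors)
    present = [p for p in wanted if p in prepared.carbon]
    missing = sorted(set(wanted) - set(present))
    if missing:
        logger.warning("precursors absent from model, dropped: %s", ", ".join(missing))
    solutions: dict[tuple[str, str], PathwaySolution] = {}
    for s in present:
        for t in present:
            if s == t:
                continue
            solutions[(s, t)] = solve_pathway(prepared, s, t)
    return PrecursorGrid(tuple(present), solutions)


def select_seed(grid: PrecursorGrid) -> str:
    """Pick the seed metabolite from the precursor feasibility digraph.

    Fully strongly connected: pyruvate if present, else the first
    precursor in lexicographic order.  Otherwise: the lexicographically
    first member of the largest strongly connected component.
    """
    if not grid.precursors:
        raise ValueError("empty precursor grid; supply a seed manually")
    g = grid.feasibility_graph()
    if grid.solutions and not any(s.feasible for s in grid.solutions.values()):
        raise ValueError("no precursor pair is connected; supply a seed manually")
    if len(grid.precursors) == 1:
        return grid.precursors[0]
    if nx.is_strongly_connected(g):
        return "pyr_c" if "pyr_c" in g else sorted(g.nodes)[0]
    components = sorted(
        (sorted(c) for c in nx.strongly_connected_components(g)),
        key=lambda c: (-len(c), c),
    )
    return components[0][0]


@dataclass
class ConnectivityTable:
    """Per-metabolite producibility/consumability relative to the seed.

    Raw feasibility and yields are recorded pre-threshold; the
    producible/consumable flags used for classification apply tau.
    """

    seed: str
    tau: float
    frame: pd.DataFrame   # index: metabolite id

    def producible(self, tau: Optional[float] = None, thresholded: bool = True) -> pd.Series:
        if not thresholded:
            return self.frame["feasible_from_seed"]
        tau = self.tau if tau is None else tau
        return self.frame["feasible_from_seed"] & (
            self.frame["yield_from_seed"] >= tau - 1e-12
        )

    def consumable(self, tau: Optional[float] = None, thresholded: bool = True) -> pd.Series:
        if not thresholded:
            return self.frame["feasible_to_seed"]
        tau = self.tau if tau is None else tau
        return self.frame["feasible_to_seed"] & (
            self.frame["yield_to_seed"] >= tau - 1e-12
        )

    def raw_counts(self) -> tuple[int, int]:
        """(produced, consumed) counts before the yield threshold,
        excluding the seed itself."""
        others = self.frame.index != self.seed
        return (
            int(self.frame.loc[others, "feasible_from_seed"].sum()),
            int(self.frame.loc[others, "feasible_to_seed"].sum()),
        )

    def write_tsv(self, path: str | Path, partition: Optional[BowTiePartition] = None) -> None:
        out = self.frame.copy()
        if partition is not None:
            out["class"] = [partition.class_of(m) for m in out.index]
        out.to_csv(path, sep="\t", index_label="metabolite")


def sweep_connectivity(
    prepared: PreparedModel,
    seed: str,
    tau: Optional[float] = None,
    metabolites: Optional[Iterable[str]] = None,
) -> ConnectivityTable:
    """Solve seed->x and x->seed for every carbon metabolite x.

    Per-pair solver errors are logged and recorded as infeasible so a
    long sweep survives isolated numerical failures.
    """
    if seed not in prepared.carbon:
        raise KeyError(f"seed {seed} is not a carbon metabolite of the model")
    tau = prepared.config.yield_threshold if tau is None else tau
    ids = sorted(metabolites) if metabolites is not None else sorted(prepared.carbon)
    rows = []
    for mid in ids:
        if mid == seed:
            rows.append((mid, True, True, 1.0, 1.0, ""))
            continue
        rec = []
        for s, t in ((seed, mid), (mid, seed)):
            try:
                sol = solve_pathway(prepared, s, t)
                rec.append((sol.feasible, sol.carbon_yield, ""))
            except Exception as exc:  # pragma: no cover - defensive
                logger.error("pair %s->%s failed: %s", s, t, exc)
                rec.append((False, 0.0, str(exc)))
        (p_ok, p_y, p_err), (c_ok, c_y, c_err) = rec
        rows.append((mid, p_ok, c_ok, p_y, c_y, (p_err + " " + c_err).strip()))
    frame = pd.DataFrame.from_records(
        rows,
        columns=[
            "metabolite", "feasible_from_seed", "feasible_to_seed",
            "yield_from_seed", "yield_to_seed", "error",
        ],
    ).set_index("metabolite")
    return ConnectivityTable(seed=seed, tau=tau, frame=frame)


def classify_bowtie(
    table: ConnectivityTable,
    tau: Optional[float] = None,
    thresholded: bool = True,
) -> BowTiePartition:
    """Partition all swept metabolites into GSC/IN/OUT/IS."""
    prod = table.producible(tau, thresholded)
    cons = table.consumable(tau, thresholded)
    gsc = frozenset(table.frame.index[prod & cons])
    in_ = frozenset(table.frame.index[cons & ~prod])
    out = frozenset(table.frame.index[prod & ~cons])
    iso = frozenset(table.frame.index[~prod & ~cons])
    return BowTiePartition(
        method="fba",
        sets={"GSC": gsc, "IN": in_, "OUT": out, "IS": iso},
        seed=table.seed,
    )


def is_substructure(
    prepared: PreparedModel,
    partition: BowTiePartition,
    tau: Optional[float] = None,
) -> tuple[frozenset[str], frozenset[str]]:
    """Probe the isolated subset's one-sided connections.

    Returns (producible_from_IN, consumable_to_OUT): IS members that can
    be made with all IN members simultaneously available as substrates,
    and IS members that, as sole substrate, can feed the OUT demands.
    Yields are measured against total moiety-carbon uptake and must
    reach tau.
    """
    tau = prepared.config.yield_threshold if tau is None else tau
    eps = prepared.config.feasibility_tol
    iso = sorted(partition["IS"])
    in_members = sorted(partition["IN"])
    out_members = sorted(partition["OUT"])

    producible: set[str] = set()
    if iso and in_members:
        with prepared.model as m:
            sinks = []
            for mid in in_members:
                sink = _build_sink(prepared, mid)
                sinks.append((sink, mid))
            m.add_reactions([s for s, _ in sinks])
            for mid in iso:
                m.objective = prepared.demand_reaction(mid)
                m.objective_direction = "max"
                sol = m.optimize()
                if sol.status != "optimal":
                    continue
                r_p = float(sol.fluxes[prepared.demand_of[mid]])
                if r_p <= eps:
                    continue
                uptake_c = sum(
                    -float(sol.fluxes[sink.id]) * prepared.moiety_carbons(src)
                    for sink, src in sinks
                )
                if uptake_c <= eps:
                    continue
                y = r_p * prepared.moiety_carbons(mid) / uptake_c
                if y >= tau - 1e-12:
                    producible.add(mid)

    consumable: set[str] = set()
    if iso and out_members:
        # objective: moiety-carbon-weighted sum of OUT demand fluxes
        for mid in iso:
            with prepared.model as m:
                sink = _build_sink(prepared, mid)
                m.add_reactions([sink])
                m.objective = {
                    prepared.demand_reaction(o): float(prepared.moiety_carbons(o))
                    for o in out_members
                }
                m.objective_direction = "max"
                sol = m.optimize()
                if sol.status != "optimal":
                    continue
                carbon_out = sum(
                    float(sol.fluxes[prepared.demand_of[o]]) * prepared.moiety_carbons(o)
                    for o in out_members
                )
                r_s = -float(sol.fluxes[sink.id])
                if carbon_out <= eps or r_s <= eps:
                    continue
                y = carbon_out / (r_s * prepared.moiety_carbons(mid))
                if y >= tau - 1e-12:
                    consumable.add(mid)

    return frozenset(producible), frozenset(consumable)
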