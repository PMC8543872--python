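"""Single source->target pathway solves with parsimonious FBA.

A pathway problem supplies one substrate through a sink reaction
(lower bound -10 mmol/gDCW/h by default) and maximises the demand flux
of the target; the parsimonious step then minimises total absolute flux
at the fixed optimum.  Pathways are scored by carbon yield

    Y_C = (r_p * C_p) / (r_s * C_s)

with moiety carbons used for carrier-bound species, and can be bounded
a priori by the degree-of-reduction balance.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Union

from cobra import Reaction
from cobra.flux_analysis import pfba as _pfba

from .model_prep import MetaboliteInfo, PreparedModel, parse_formula

logger = logging.getLogger(__name__)

__all__ = [
    "PathwaySolution",
    "ReductionDegree",
    "attach_sink",
    "solve_pathway",
    "carbon_yield",
    "degree_of_reduction",
    "yield_upper_bound",
    "steady_state_residual",
]

#: Available-electron equivalents contributed per atom.
_GAMMA_WEIGHTS = {"C": 4, "H": 1, "O": -2, "N": -3, "P": 5, "S": 6}


@dataclass(frozen=True)
class ReductionDegree:
    """Degree of reduction: available electron equivalents per mole
    (``total``) and per gram-atom carbon (``per_carbon``)."""

    total: float
    per_carbon: float


def degree_of_reduction(
    formula: Union[str, Mapping[str, int]], charge: int = 0
) -> ReductionDegree:
    """gamma = 4C + H - 2O - 3N + 5P + 6S - charge, and gamma per carbon.

    Defined only for carbon-containing species; an element outside the
    CHONPS set raises, naming the offender.
    """
    elements = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    n_c = elements.get("C", 0)
    if n_c < 1:
        raise ValueError("degree of reduction requires >= 1 carbon atom")
    total = -float(charge)
    for el, n in elements.items():
        try:
            total += _GAMMA_WEIGHTS[el] * n
        except KeyError:
            raise ValueError(f"unknown element in degree-of-reduction weights: {el}")
    return ReductionDegree(total=total, per_carbon=total / n_c)


def yield_upper_bound(source: MetaboliteInfo, target: MetaboliteInfo) -> float:
    """Maximal carbon yield allowed by the degree-of-reduction balance:
    min(1, gamma_C(source) / gamma_C(target))."""
    g_s = degree_of_reduction(source.formula, source.charge).per_carbon
    g_t = degree_of_reduction(target.formula, target.charge).per_carbon
    if g_t <= 0:
        raise ValueError(f"{target.id}: non-positive per-carbon degree of reduction")
    return min(1.0, g_s / g_t)


@dataclass
class PathwaySolution:
    """Result of one source->target pFBA solve."""

    source: str
    target: str
    status: str                       # "feasible" | "infeasible"
    r_s: float                        # substrate supply rate, mmol/gDCW/h
    r_p: float                        # target demand rate, mmol/gDCW/h
    carbon_yield: float
    flux_map: dict[str, float] = field(default_factory=dict)
    sink_id: str = ""
    sink_stoich: dict[str, float] = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        return self.status == "feasible"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "source": self.source,
            "target": self.target,
            "status": self.status,
            "r_s": self.r_s,
            "r_p": self.r_p,
            "carbon_yield": self.carbon_yield,
            "fluxes": self.flux_map,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    def to_text(self, path: str | Path, prepared: PreparedModel) -> None:
        """Human-readable reaction list of the pathway."""
        lines = [
            f"# pathway {self.source} -> {self.target}: {self.status}",
            f"# r_s = {self.r_s:.6g}  r_p = {self.r_p:.6g}  carbon yield = {self.carbon_yield:.4f}",
        ]
        for rid, v in sorted(self.flux_map.items(), key=lambda kv: -abs(kv[1])):
            if rid == self.sink_id:
                eq = " + ".join(f"{c:g} {m}" for m, c in self.sink_stoich.items())
                lines.append(f"{rid}\t{v:.6g}\t(sink) {eq}")
            else:
                rxn = prepared.model.reactions.get_by_id(rid)
                lines.append(f"{rid}\t{v:.6g}\t{rxn.build_reaction_string()}")
        Path(path).write_text("\n".join(lines) + "\n")


def _build_sink(prepared: PreparedModel, source: str) -> Reaction:
    info = prepared.info(source)  # raises for non-carbon species
    sink = Reaction(
        f"SK_{source}_btf",
        lower_bound=prepared.config.sink_lower_bound,
        upper_bound=0.0,
    )
    stoich = {source: -1.0}
    free_id = prepared.free_carrier_id(source)
    if info.carrier is not None and free_id is not None:
        # carrier -> source under negative flux: only the moiety is supplied
        stoich[free_id] = 1.0
    sink.add_metabolites(
        {prepared.model.metabolites.get_by_id(k): v for k, v in stoich.items()}
    )
    sink.notes["bowtieflux_kind"] = "sink"
    return sink


@contextmanager
def attach_sink(prepared: PreparedModel, source: str) -> Iterator[Reaction]:
    """Temporarily attach the substrate sink for ``source``; the model is
    restored on exit."""
    with prepared.model as m:
        sink = _build_sink(prepared, source)
        m.add_reactions([sink])
        yield sink


def carbon_yield(solution: PathwaySolution, prepared: PreparedModel) -> float:
    """(r_p x moiety carbons of target) / (r_s x moiety carbons of source)."""
    if not solution.feasible:
        return 0.0
    c_s = prepared.moiety_carbons(solution.source)
    c_p = prepared.moiety_carbons(solution.target)
    if solution.r_s <= prepared.config.feasibility_tol:
        raise RuntimeError(
            f"{solution.source}->{solution.target}: positive production with zero "
            "substrate uptake (carbon created; preprocessing breached)"
        )
    return (solution.r_p * c_p) / (solution.r_s * c_s)


def solve_pathway(
    prepared: PreparedModel,
    source: str,
    target: str,
    parsimonious: bool = True,
) -> PathwaySolution:
    """Maximise the target demand from a single substrate sink.

    With ``parsimonious=True`` (default) the reported flux map is the
    pFBA solution: the demand optimum is preserved while total absolute
    flux is minimised.  Status is feasible iff r_p exceeds the
    configured tolerance.
    """
    if source == target:
        raise ValueError("source and target must differ")
    eps = prepared.config.feasibility_tol
    demand = prepared.demand_reaction(target)

    with prepared.model as m:
        sink = _build_sink(prepared, source)
        m.add_reactions([sink])
        m.objective = demand
        m.objective_direction = "max"
        if parsimonious:
            sol = _pfba(m)
        else:
            sol = m.optimize()
            if sol.status not in ("optimal",):
                raise RuntimeError(
                    f"LP solver returned {sol.status} for {source}->{target} "
                    f"(objective {demand.id})"
                )
        r_p = float(sol.fluxes[demand.id])
        r_s = -float(sol.fluxes[sink.id])
        feasible = r_p > eps
        flux_map = {}
        if feasible:
            cutoff = prepared.config.flux_report_tol
            flux_map = {
                rid: float(v) for rid, v in sol.fluxes.items() if abs(v) > cutoff
            }
        solution = PathwaySolution(
            source=source,
            target=target,
            status="feasible" if feasible else "infeasible",
            r_s=r_s if feasible else 0.0,
            r_p=r_p if feasible else 0.0,
            carbon_yield=0.0,
            flux_map=flux_map,
            sink_id=sink.id,
            sink_stoich={k.id: v for k, v in sink.metabolites.items()},
        )
    if solution.feasible:
        solution.carbon_yield = carbon_yield(solution, prepared)
    return solution


def steady_state_residual(prepared: PreparedModel, solution: PathwaySolution) -> float:
    """max_m |sum_r S_mr v_r| over the reported flux map (the detached
    sink's stoichiometry is folded back in)."""
    balance: dict[str, float] = {}
    for rid, v in solution.flux_map.items():
        if rid == solution.sink_id:
            stoich = solution.sink_stoich.items()
        else:
            stoich = (
                (met.id, coef)
                for met, coef in prepared.model.reactions.get_by_id(rid).metabolites.items()
            )
        for mid, coef in stoich:
            balance[mid] = balance.get(mid, 0.0) + coef * v
    # species with open boundary/demand terms already appear as reactions
    return max((abs(x) for x in balance.values()), default=0.0)
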