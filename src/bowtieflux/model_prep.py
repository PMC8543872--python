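"""Model loading, balance auditing and preprocessing for pathway analysis.

The preprocessing transforms a genome-scale model into the form used by
the pathway sweep:

* all exchange uptake of carbon (including CO2/HCO3) is closed, so the
  only carbon entering any LP is the substrate sink attached per solve;
* a reversible, balanced energy dissipation/generation reaction
  ``atp + h2o <=> adp + pi + h`` decouples carbon routing from ATP
  production;
* every free carrier species (CoA, THF, ...) and every carbon-containing
  metabolite receives an irreversible demand reaction so reaction
  co-products can be balanced at steady state; demands of carrier-bound
  metabolites release the free carrier (``acyl-CoA -> CoA``) so only the
  moiety has to be synthesised.

Original reactions are never modified or removed; everything added is
recorded in a registry on the returned :class:`PreparedModel`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import cobra
from cobra import Metabolite, Reaction
from cobra.core.formula import Formula

from .config import AnalysisConfig, CarrierSpec, split_compartment

logger = logging.getLogger(__name__)

__all__ = [
    "MetaboliteInfo",
    "BalanceReport",
    "PreparedModel",
    "load_model",
    "check_mass_balance",
    "carbon_metabolites",
    "detect_carriers",
    "preprocess",
]

#: Formula placeholders that denote undefined/macromolecular parts
#: (generic R-groups, tRNA stubs ...); reactions touching them are
#: skipped by the balance audit rather than reported as imbalanced.
PLACEHOLDER_ELEMENTS = frozenset({"R", "X", "Z"})


def parse_formula(formula: str) -> dict[str, int]:
    """Element -> count map for a Hill-notation formula string."""
    elements = Formula(formula).elements
    return {el: int(n) for el, n in elements.items()}


def _has_defined_formula(met: Metabolite) -> bool:
    if not met.formula:
        return False
    try:
        elements = met.elements
    except Exception:
        return False
    if not elements:
        return False
    if PLACEHOLDER_ELEMENTS & elements.keys():
        return False
    return all(float(n) == int(n) for n in elements.values())


@dataclass(frozen=True)
class MetaboliteInfo:
    """Per-species record used throughout the analysis."""

    id: str
    name: str
    formula: dict[str, int]
    charge: int
    compartment: str
    carbon_count: int
    carrier: Optional[str] = None        # carrier tag, e.g. "CoA"
    moiety_carbons: int = 0              # carbons that count for yields

    def __post_init__(self):
        if self.moiety_carbons < 0:
            raise ValueError(
                f"{self.id}: moiety carbons negative (carrier larger than species)"
            )


@dataclass
class BalanceReport:
    """Outcome of the elemental/charge audit of all model reactions."""

    imbalanced: dict[str, dict[str, float]] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    @property
    def n_imbalanced(self) -> int:
        return len(self.imbalanced)

    def to_records(self) -> list[tuple[str, str, float]]:
        return [
            (rid, element, delta)
            for rid, deltas in sorted(self.imbalanced.items())
            for element, delta in sorted(deltas.items())
        ]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction_id\telement\tdelta\n")
            for rid, element, delta in self.to_records():
                fh.write(f"{rid}\t{element}\t{delta:g}\n")
            for rid in self.skipped:
                fh.write(f"{rid}\tskipped\tNA\n")


def load_model(path: str | Path) -> cobra.Model:
    """Read an SBML (Level 3 + FBC; Level 2 converted) model.

    Metabolites without a parseable formula are logged; they are later
    excluded from the carbon set and route reactions to the audit's
    skipped list.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"model file not found: {path}")
    model = cobra.io.read_sbml_model(str(path))
    missing = [m.id for m in model.metabolites if not _has_defined_formula(m)]
    if missing:
        logger.warning(
            "%d metabolites lack a defined formula (first few: %s)",
            len(missing), ", ".join(missing[:5]),
        )
    return model


def _is_pseudo(reaction: Reaction) -> bool:
    """Boundary or bookkeeping reactions exempt from the balance audit."""
    if reaction.boundary:
        return True
    kind = (reaction.notes or {}).get("bowtieflux_kind")
    return kind in {"sink", "demand", "energy_balance", "exchange"}


def check_mass_balance(model: cobra.Model, tol: float = 1e-6) -> BalanceReport:
    """Audit element and charge balance of every non-pseudo reaction.

    Reactions involving species with undefined or placeholder formulas
    (macromolecules such as tRNAs, generic R-groups) are listed as
    skipped, not imbalanced.
    """
    report = BalanceReport()
    for rxn in model.reactions:
        if _is_pseudo(rxn):
            continue
        if any(not _has_defined_formula(met) for met in rxn.metabolites):
            report.skipped.append(rxn.id)
            continue
        deltas = rxn.check_mass_balance()
        deltas = {el: d for el, d in deltas.items() if abs(d) > tol}
        if deltas:
            report.imbalanced[rxn.id] = deltas
    return report


def detect_carriers(
    model: cobra.Model,
    carriers: Iterable[CarrierSpec],
) -> dict[str, CarrierSpec]:
    """Map carrier-bound metabolites to their carrier group.

    A species is bound to a carrier when its base id matches the
    carrier's id pattern AND its formula minus the carrier's formula is
    element-wise non-negative.  Free carrier species themselves are
    never mapped.  A species matching two carriers raises (an override
    table entry is then required).
    """
    carriers = list(carriers)
    mapping: dict[str, CarrierSpec] = {}
    for met in model.metabolites:
        if not _has_defined_formula(met):
            continue
        base, _ = split_compartment(met.id, met.compartment)
        hits = []
        for spec in carriers:
            if not spec.matches(base):
                continue
            try:
                carrier_elements = parse_formula(spec.formula)
            except Exception:
                continue
            met_elements = met.elements
            if all(
                met_elements.get(el, 0) >= n for el, n in carrier_elements.items()
            ):
                hits.append(spec)
        if len(hits) > 1:
            raise ValueError(
                f"{met.id} matches multiple carriers: "
                + ", ".join(h.tag for h in hits)
                + " (add an override entry)"
            )
        if hits:
            mapping[met.id] = hits[0]
    return mapping


def carbon_metabolites(
    model: cobra.Model,
    carrier_map: Optional[Mapping[str, CarrierSpec]] = None,
) -> dict[str, MetaboliteInfo]:
    """All metabolites with >= 1 carbon atom, one entry per compartmented
    species.  Species with unparseable formulas are excluded with a
    warning."""
    carrier_map = carrier_map or {}
    out: dict[str, MetaboliteInfo] = {}
    for met in model.metabolites:
        if not _has_defined_formula(met):
            if met.formula:
                logger.warning("excluding %s: unparseable formula %r", met.id, met.formula)
            continue
        n_c = int(met.elements.get("C", 0))
        if n_c < 1:
            continue
        spec = carrier_map.get(met.id)
        if spec is not None:
            carrier_c = parse_formula(spec.formula).get("C", 0)
            moiety = n_c - carrier_c
            tag = spec.tag
        else:
            moiety = n_c
            tag = None
        out[met.id] = MetaboliteInfo(
            id=met.id,
            name=met.name or met.id,
            formula={el: int(n) for el, n in met.elements.items()},
            charge=int(met.charge or 0),
            compartment=met.compartment or "",
            carbon_count=n_c,
            carrier=tag,
            moiety_carbons=moiety,
        )
    return out


@dataclass
class PreparedModel:
    """A model plus the registry of pseudo-reactions added for analysis."""

    model: cobra.Model
    config: AnalysisConfig
    carbon: dict[str, MetaboliteInfo]
    carrier_map: dict[str, CarrierSpec]
    registry: dict[str, list[str]]       # kind -> reaction ids added/reused
    demand_of: dict[str, str]            # metabolite id -> demand reaction id

    def info(self, met_id: str) -> MetaboliteInfo:
        try:
            return self.carbon[met_id]
        except KeyError:
            raise KeyError(f"{met_id} is not a carbon metabolite of this model")

    def moiety_carbons(self, met_id: str) -> int:
        return self.info(met_id).moiety_carbons

    def demand_reaction(self, met_id: str) -> Reaction:
        return self.model.reactions.get_by_id(self.demand_of[met_id])

    def free_carrier_id(self, met_id: str) -> Optional[str]:
        """Id of the free carrier species in the same compartment as a
        carrier-bound metabolite, if the model contains one."""
        spec = self.carrier_map.get(met_id)
        if spec is None:
            return None
        met = self.model.metabolites.get_by_id(met_id)
        candidate = f"{spec.free_base_id}_{met.compartment}"
        if candidate in self.model.metabolites:
            return candidate
        for other in self.model.metabolites:
            base, _ = split_compartment(other.id, other.compartment)
            if base.lower() == spec.free_base_id.lower() and other.compartment == met.compartment:
                return other.id
        return None

    @property
    def n_added(self) -> int:
        return sum(len(v) for v in self.registry.values())


def _exchange_coefficient(rxn: Reaction) -> Optional[tuple[Metabolite, float]]:
    if len(rxn.metabolites) != 1:
        return None
    (met, coef), = rxn.metabolites.items()
    return met, coef


def _close_carbon_uptake(model: cobra.Model) -> list[str]:
    """Forbid net import of carbon through every boundary reaction."""
    touched = []
    for rxn in model.boundary:
        pair = _exchange_coefficient(rxn)
        if pair is None:
            continue
        met, coef = pair
        if not _has_defined_formula(met) or int(met.elements.get("C", 0)) < 1:
            continue
        if coef < 0 and rxn.lower_bound < 0:
            rxn.lower_bound = 0.0
            touched.append(rxn.id)
        elif coef > 0 and rxn.upper_bound > 0:
            rxn.upper_bound = 0.0
            touched.append(rxn.id)
    return touched


_ENERGY_STOICH = {"atp": -1, "h2o": -1, "adp": 1, "pi": 1, "h": 1}


def _find_energy_equivalent(model: cobra.Model, ids: dict[str, str]) -> Optional[Reaction]:
    want = {ids[base]: coef for base, coef in _ENERGY_STOICH.items()}
    for rxn in model.reactions:
        stoich = {m.id: c for m, c in rxn.metabolites.items()}
        if stoich == want or stoich == {k: -v for k, v in want.items()}:
            if rxn.reversibility:
                return rxn
    return None


def preprocess(
    model: cobra.Model,
    config: Optional[AnalysisConfig] = None,
    copy: bool = True,
) -> PreparedModel:
    """Apply the full preprocessing workflow and return a PreparedModel.

    Idempotent: preprocessing an already prepared model's underlying
    cobra model registers the existing pseudo-reactions instead of
    adding new ones.
    """
    config = config or AnalysisConfig()
    work = model.copy() if copy else model
    registry: dict[str, list[str]] = {
        "exchange_closed": [], "energy_balance": [], "carrier_demand": [], "demand": [],
    }

    registry["exchange_closed"] = _close_carbon_uptake(work)

    carrier_map = detect_carriers(work, config.carriers)
    carbon = carbon_metabolites(work, carrier_map)

    # energy balance reaction (atp + h2o <=> adp + pi + h), added once
    comp = config.energy_compartment
    energy_ids = {base: f"{base}_{comp}" for base in config.energy_species}
    if all(mid in work.metabolites for mid in energy_ids.values()):
        existing = _find_energy_equivalent(work, energy_ids)
        if existing is None:
            ebal = Reaction(f"EBAL_{comp}", lower_bound=-1000.0, upper_bound=1000.0)
            ebal.add_metabolites(
                {work.metabolites.get_by_id(energy_ids[b]): c for b, c in _ENERGY_STOICH.items()}
            )
            ebal.notes["bowtieflux_kind"] = "energy_balance"
            work.add_reactions([ebal])
            registry["energy_balance"].append(ebal.id)
        else:
            registry["energy_balance"].append(existing.id)
    else:
        logger.warning(
            "energy-balance step skipped: species %s not all present",
            sorted(energy_ids.values()),
        )

    new_reactions: list[Reaction] = []
    demand_of: dict[str, str] = {}
    existing_ids = set(work.reactions.list_attr("id"))

    def _register_demand(met_id: str, stoich: dict[str, float], kind: str) -> None:
        rid = f"DM_{met_id}"
        if rid in existing_ids:
            rxn = work.reactions.get_by_id(rid)
            have = {m.id: c for m, c in rxn.metabolites.items()}
            if have == stoich and rxn.lower_bound >= 0:
                demand_of[met_id] = rid
                registry[kind].append(rid)
                logger.debug("reusing existing demand %s", rid)
                return
            rid = f"DM_{met_id}_btf"
            if rid in existing_ids:
                demand_of[met_id] = rid
                registry[kind].append(rid)
                return
        rxn = Reaction(rid, lower_bound=0.0, upper_bound=1000.0)
        rxn.add_metabolites({work.metabolites.get_by_id(k): v for k, v in stoich.items()})
        rxn.notes["bowtieflux_kind"] = "demand"
        new_reactions.append(rxn)
        existing_ids.add(rid)
        demand_of[met_id] = rid
        registry[kind].append(rid)

    # free-carrier demands so carrier groups can always leave the system
    free_carrier_ids = set()
    for met in work.metabolites:
        base, _ = split_compartment(met.id, met.compartment)
        for spec in config.carriers:
            if base.lower() == spec.free_base_id.lower():
                free_carrier_ids.add(met.id)
    for mid in sorted(free_carrier_ids):
        _register_demand(mid, {mid: -1.0}, "carrier_demand")

    # demands for every carbon metabolite; carrier-bound species release
    # the free carrier so only the moiety must be made
    prepared_stub = PreparedModel(work, config, carbon, carrier_map, registry, demand_of)
    for mid in sorted(carbon):
        if mid in demand_of:
            continue
        stoich: dict[str, float] = {mid: -1.0}
        free_id = prepared_stub.free_carrier_id(mid)
        if carrier_map.get(mid) is not None:
            if free_id is not None:
                stoich[free_id] = 1.0
            else:
                logger.warning(
                    "%s: carrier %s has no free species in compartment; plain demand used",
                    mid, carrier_map[mid].tag,
                )
        _register_demand(mid, stoich, "demand")

    if new_reactions:
        work.add_reactions(new_reactions)

    return PreparedModel(
        model=work,
        config=config,
        carbon=carbon,
        carrier_map=carrier_map,
        registry=registry,
        demand_of=demand_of,
    )
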