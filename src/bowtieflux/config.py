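"""Analysis configuration: carriers, currency pairs, thresholds.

All rates are in mmol/gDCW/h. Species identifiers follow the BiGG
convention ``<base>_<compartment>`` (e.g. ``pyr_c``); carrier and
currency tables are matched on the *base* identifier so that pairs are
compartment-local (atp_c/adp_c is a pair, atp_c/adp_p is transport).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "CarrierSpec",
    "CurrencyPair",
    "AnalysisConfig",
    "DEFAULT_CARRIERS",
    "DEFAULT_CURRENCY_PAIRS",
    "DEFAULT_PRECURSORS",
    "split_compartment",
    "read_carrier_table",
    "read_currency_table",
]

#: The 12 biosynthetic precursors of central carbon metabolism used to
#: probe core connectivity before choosing a seed metabolite.
DEFAULT_PRECURSORS = (
    "e4p_c", "pep_c", "r5p_c", "oaa_c", "3pg_c", "pyr_c",
    "akg_c", "accoa_c", "f6p_c", "g6p_c", "g3p_c", "succoa_c",
)


def split_compartment(met_id: str, compartment: Optional[str] = None) -> tuple[str, str]:
    """Split a BiGG-style species id into (base, compartment).

    If the metabolite's compartment is known it is stripped as a suffix;
    otherwise the text after the last underscore is taken as compartment.
    """
    if compartment and met_id.endswith("_" + compartment):
        return met_id[: -len(compartment) - 1], compartment
    if "_" in met_id:
        base, _, comp = met_id.rpartition("_")
        return base, comp
    return met_id, ""


@dataclass(frozen=True)
class CarrierSpec:
    """A carrier group (CoA, ACP, THF, nucleotide diphosphates ...).

    Only the moiety attached to the carrier counts as pathway carbon;
    the carrier itself is recycled via its own demand reaction.
    """

    tag: str                  # short label, e.g. "CoA"
    free_base_id: str         # base id of the free carrier species, e.g. "coa"
    formula: str              # formula of the free carrier
    charge: int
    pattern: str              # regex on the bound species' base id

    def matches(self, base_id: str) -> bool:
        if base_id.lower() == self.free_base_id.lower():
            return False
        return re.search(self.pattern, base_id, flags=re.IGNORECASE) is not None


DEFAULT_CARRIERS: tuple[CarrierSpec, ...] = (
    CarrierSpec("CoA", "coa", "C21H32N7O16P3S", -4, r"coa"),
    CarrierSpec("ACP", "ACP", "C11H21N2O7PRS", -1, r"acp"),
    CarrierSpec("THF", "thf", "C19H21N7O6", -2, r"thf"),
    CarrierSpec("UDP", "udp", "C9H11N2O12P2", -3, r"^udp."),
    CarrierSpec("ADP", "adp", "C10H12N5O10P2", -3, r"^adp."),
    CarrierSpec("CDP", "cdp", "C9H12N3O11P2", -3, r"^cdp."),
)


@dataclass(frozen=True)
class CurrencyPair:
    """A ranked co-substrate/co-product pair carrying a chemical group."""

    rank: int
    base_a: str
    base_b: str
    group: str

    def in_reaction(self, sub_bases: dict, prod_bases: dict) -> Optional[tuple[str, str]]:
        """Return the (substrate_id, product_id) instance of this pair in a
        reaction, matched compartment-locally, or None."""
        for x, y in ((self.base_a, self.base_b), (self.base_b, self.base_a)):
            for comp, sid in sub_bases.get(x, {}).items():
                pid = prod_bases.get(y, {}).get(comp)
                if pid is not None:
                    return sid, pid
        return None


# Ranked group-transfer pairs: hydride < phosphate < amine < one-carbon
# < acetyl < CoA-thioester.  Genome-scale link counts are sensitive to
# the exact pair list; a custom ranked table can be swapped in via TSV.
DEFAULT_CURRENCY_PAIRS: tuple[CurrencyPair, ...] = (
    CurrencyPair(1, "nad", "nadh", "hydride"),
    CurrencyPair(2, "nadp", "nadph", "hydride"),
    CurrencyPair(3, "fad", "fadh2", "hydride"),
    CurrencyPair(4, "q8", "q8h2", "hydride"),
    CurrencyPair(5, "mqn8", "mql8", "hydride"),
    CurrencyPair(6, "atp", "adp", "phosphate"),
    CurrencyPair(7, "adp", "amp", "phosphate"),
    CurrencyPair(8, "atp", "amp", "phosphate"),
    CurrencyPair(9, "gtp", "gdp", "phosphate"),
    CurrencyPair(10, "utp", "udp", "phosphate"),
    CurrencyPair(11, "ctp", "cdp", "phosphate"),
    CurrencyPair(12, "glu__L", "akg", "amine"),
    CurrencyPair(13, "ala__L", "pyr", "amine"),
    CurrencyPair(14, "asp__L", "oaa", "amine"),
    CurrencyPair(15, "gln__L", "glu__L", "amine"),
    CurrencyPair(16, "methf", "thf", "one-carbon"),
    CurrencyPair(17, "mlthf", "thf", "one-carbon"),
    CurrencyPair(18, "10fthf", "thf", "one-carbon"),
    CurrencyPair(19, "5mthf", "thf", "one-carbon"),
    CurrencyPair(20, "amet", "ahcys", "one-carbon"),
    CurrencyPair(21, "accoa", "ac", "acetyl"),
    CurrencyPair(22, "succoa", "succ", "CoA-thioester"),
)

#: Species never used as graph endpoints (base ids): fixed carbon sinks
#: and the acyl-carrier protein, following the graph-construction rule.
DEFAULT_EXCLUDED_ENDPOINTS = ("co2", "hco3", "ACP", "acp")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the whole pipeline.

    sink_lower_bound
        Lower flux bound of the substrate sink, mmol/gDCW/h (< 0: supply).
    yield_threshold
        Minimum carbon yield tau for a pathway to count in classification.
    feasibility_tol
        Production rate epsilon below which a pathway is "absent".
    """

    sink_lower_bound: float = -10.0
    yield_threshold: float = 0.20
    feasibility_tol: float = 1e-6
    flux_report_tol: float = 1e-9
    precursors: Sequence[str] = DEFAULT_PRECURSORS
    carriers: Sequence[CarrierSpec] = DEFAULT_CARRIERS
    currency_pairs: Sequence[CurrencyPair] = DEFAULT_CURRENCY_PAIRS
    excluded_endpoints: Sequence[str] = DEFAULT_EXCLUDED_ENDPOINTS
    energy_species: tuple[str, str, str, str, str] = ("atp", "adp", "pi", "h2o", "h")
    energy_compartment: str = "c"
    max_imbalanced: int = 5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.yield_threshold <= 1.0):
            raise ValueError("yield_threshold must be in [0, 1]")
        if self.sink_lower_bound >= 0:
            raise ValueError("sink_lower_bound must be negative (a supply)")
        if self.feasibility_tol <= 0:
            raise ValueError("feasibility_tol must be positive")

    def with_threshold(self, tau: float) -> "AnalysisConfig":
        return replace(self, yield_threshold=tau)


def read_carrier_table(path: str | Path) -> tuple[CarrierSpec, ...]:
    """Read a carrier TSV: carrier_tag, free_species_id, formula, charge, id_pattern."""
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                CarrierSpec(
                    rec["carrier_tag"],
                    rec["free_species_id"],
                    rec["formula"],
                    int(rec["charge"]),
                    rec["id_pattern"],
                )
            )
    return tuple(rows)


def read_currency_table(path: str | Path) -> tuple[CurrencyPair, ...]:
    """Read a currency-pair TSV: rank, species_a_pattern, species_b_pattern, group."""
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                CurrencyPair(
                    int(rec["rank"]),
                    rec["species_a_pattern"],
                    rec["species_b_pattern"],
                    rec.get("group", ""),
                )
            )
    ranks = [p.rank for p in rows]
    if len(set(ranks)) != len(ranks):
        raise ValueError("currency-pair ranks must be unique")
    return tuple(sorted(rows, key=lambda p: p.rank))
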