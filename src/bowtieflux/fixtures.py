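"""Deterministic miniature metabolic models with known bow-tie truth.

Each case is a small, element- and charge-balanced SBML-writable model
that reproduces one connectivity phenomenon of real genome-scale
networks:

``linear``
    A plain conversion chain; degenerate bow-tie.
``coa_carrier``
    Acetyl-CoA metabolism: the 21-carbon CoA carrier must be recycled,
    not synthesised, for acyl pathways to exist.
``chorismate_branch``
    Chorismate pyruvate-lyase: pyruvate is a co-product and the other
    branch (4-hydroxybenzoate) must be drained by a demand reaction.
``arbutin_ed``
    Arbutin degradation through the Entner-Doudoroff route; the
    hydroquinone co-product needs a demand, and the overall carbon
    yield to pyruvate is exactly 50%.
``false_gba_link``
    Lysine -> cadaverine dead end: graph analysis walks a co-substrate
    link (cadaverine -> S-methyl-5'-thioadenosine) that transfers no
    carbon, wrongly placing lysine upstream of pyruvate.
``double_transport``
    A citrate/oxaloacetate antiporter used in both directions by graph
    analysis, wrongly closing a pyruvate -> PEP cycle that flux balance
    forbids.
``cosubstrate``
    An aspartate co-substrate that cannot be produced from the nominal
    substrate (5aizc), so no stoichiometrically balanced pathway exists
    despite a graph path.

Where a real reaction would drag large redox cofactors into a tiny
model, balanced lumped variants are used (e.g. a malic-enzyme lump
emitting H2); names carry an ``_L`` suffix or a note.  All expected
partitions were derived by hand from the stoichiometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import cobra
from cobra import Metabolite, Model, Reaction

__all__ = ["FixtureSpec", "CASES", "make_fixture", "write_fixture"]


@dataclass
class FixtureSpec:
    """A fixture model plus its hand-derived ground truth."""

    name: str
    model: Model
    seed: str
    precursors: tuple[str, ...]
    expected_fba: dict[str, frozenset[str]]
    expected_gba: dict[str, frozenset[str]]
    # (source, target) -> carbon yield, or None when no pathway exists
    expected_yields: dict[tuple[str, str], Optional[float]] = field(default_factory=dict)
    expected_is_links: Optional[tuple[frozenset[str], frozenset[str]]] = None
    notes: str = ""

    def truth_payload(self) -> dict:
        return {
            "seed": self.seed,
            "precursors": list(self.precursors),
            "fba": {k: sorted(v) for k, v in self.expected_fba.items()},
            "gba": {k: sorted(v) for k, v in self.expected_gba.items()},
            "yields": {
                f"{s}->{t}": y for (s, t), y in sorted(self.expected_yields.items())
            },
            "notes": self.notes,
        }


def _species(model: Model, table: list[tuple[str, str, int, str]]) -> None:
    mets = [
        Metabolite(mid, formula=formula, charge=charge, compartment=comp,
                   name=mid.rsplit("_", 1)[0])
        for mid, formula, charge, comp in table
    ]
    model.add_metabolites(mets)


def _reaction(
    model: Model, rid: str, stoich: dict[str, float], reversible: bool = False
) -> None:
    rxn = Reaction(rid, lower_bound=-1000.0 if reversible else 0.0, upper_bound=1000.0)
    rxn.add_metabolites({model.metabolites.get_by_id(k): v for k, v in stoich.items()})
    model.add_reactions([rxn])


def _exchanges(model: Model, met_ids: list[str]) -> None:
    for mid in met_ids:
        rxn = Reaction(f"EX_{mid}", lower_bound=-1000.0, upper_bound=1000.0)
        rxn.add_metabolites({model.metabolites.get_by_id(mid): -1})
        model.add_reactions([rxn])


def _sets(gsc=(), in_=(), out=(), iso=()) -> dict[str, frozenset[str]]:
    return {
        "GSC": frozenset(gsc), "IN": frozenset(in_),
        "OUT": frozenset(out), "IS": frozenset(iso),
    }


def _linear() -> FixtureSpec:
    m = Model("fixture_linear")
    _species(m, [(f"{x}_c", "C3H6O3", 0, "c") for x in "ABCDE"])
    chain = list("ABCDE")
    for i, (a, b) in enumerate(zip(chain, chain[1:]), start=1):
        _reaction(m, f"R{i}", {f"{a}_c": -1, f"{b}_c": 1})
    part = _sets(gsc={"A_c"}, out={"B_c", "C_c", "D_c", "E_c"})
    return FixtureSpec(
        name="linear", model=m, seed="A_c", precursors=("A_c", "B_c"),
        expected_fba=part, expected_gba=part,
        expected_yields={("A_c", "B_c"): 1.0, ("B_c", "A_c"): None},
        expected_is_links=(frozenset(), frozenset()),
        notes="pure chain of isomerisations; seed fixed to the head",
    )


def _coa_carrier() -> FixtureSpec:
    m = Model("fixture_coa_carrier")
    _species(m, [
        ("pyr_c", "C3H3O3", -1, "c"),
        ("coa_c", "C21H32N7O16P3S", -4, "c"),
        ("accoa_c", "C23H34N7O17P3S", -4, "c"),
        ("ac_c", "C2H3O2", -1, "c"),
        ("for_c", "CHO2", -1, "c"),
        ("h2o_c", "H2O", 0, "c"),
        ("h_c", "H", 1, "c"),
    ])
    # pyruvate formate-lyase and acetyl-CoA hydrolase
    _reaction(m, "PFL", {"pyr_c": -1, "coa_c": -1, "accoa_c": 1, "for_c": 1})
    _reaction(m, "ACOAH", {"accoa_c": -1, "h2o_c": -1, "ac_c": 1, "coa_c": 1, "h_c": 1})
    _exchanges(m, ["h2o_c", "h_c"])
    return FixtureSpec(
        name="coa_carrier", model=m, seed="pyr_c", precursors=("pyr_c", "accoa_c"),
        expected_fba=_sets(gsc={"pyr_c"}, out={"accoa_c", "ac_c", "for_c"}, iso={"coa_c"}),
        expected_gba=_sets(gsc={"accoa_c", "coa_c"}, in_={"pyr_c"}, out={"ac_c", "for_c"}),
        expected_yields={
            ("pyr_c", "accoa_c"): 2 / 3,   # moiety carbons only
            ("accoa_c", "ac_c"): 1.0,      # CoA recycled through sink/demand
            ("accoa_c", "pyr_c"): None,
        },
        notes="acetyl moiety (2 C) vs whole acetyl-CoA (23 C) accounting",
    )


def _chorismate_branch() -> FixtureSpec:
    m = Model("fixture_chorismate_branch")
    _species(m, [
        ("chor_c", "C10H8O6", -2, "c"),
        ("4hb_c", "C7H5O3", -1, "c"),
        ("pyr_c", "C3H3O3", -1, "c"),
    ])
    # chorismate pyruvate-lyase
    _reaction(m, "CHRPL", {"chor_c": -1, "4hb_c": 1, "pyr_c": 1})
    return FixtureSpec(
        name="chorismate_branch", model=m, seed="pyr_c", precursors=("pyr_c",),
        expected_fba=_sets(gsc={"pyr_c"}, in_={"chor_c"}, iso={"4hb_c"}),
        expected_gba=_sets(gsc={"4hb_c"}, in_={"chor_c"}, iso={"pyr_c"}),
        expected_yields={
            ("chor_c", "pyr_c"): 0.30,
            ("chor_c", "4hb_c"): 0.70,
        },
        notes="pyruvate is a co-product; 4-hydroxybenzoate must be drained",
    )


def _arbutin_ed() -> FixtureSpec:
    m = Model("fixture_arbutin_ed")
    _species(m, [
        ("arbt_c", "C12H16O7", 0, "c"),
        ("hqn_c", "C6H6O2", 0, "c"),
        ("glc__D_c", "C6H12O6", 0, "c"),
        ("g6p_c", "C6H11O9P", -2, "c"),
        ("6pgl_c", "C6H9O9P", -2, "c"),
        ("6pgc_c", "C6H10O10P", -3, "c"),
        ("2ddg6p_c", "C6H8O9P", -3, "c"),
        ("g3p_c", "C3H5O6P", -2, "c"),
        ("13dpg_c", "C3H4O10P2", -4, "c"),
        ("3pg_c", "C3H4O7P", -3, "c"),
        ("2pg_c", "C3H4O7P", -3, "c"),
        ("pep_c", "C3H2O6P", -3, "c"),
        ("pyr_c", "C3H3O3", -1, "c"),
        ("atp_c", "C10H12N5O13P3", -4, "c"),
        ("adp_c", "C10H12N5O10P2", -3, "c"),
        ("nad_c", "C21H26N7O14P2", -1, "c"),
        ("nadh_c", "C21H27N7O14P2", -2, "c"),
        ("pi_c", "HPO4", -2, "c"),
        ("h_c", "H", 1, "c"),
        ("h2o_c", "H2O", 0, "c"),
        ("o2_c", "O2", 0, "c"),
    ])
    _reaction(m, "AB_HL", {"arbt_c": -1, "h2o_c": -1, "hqn_c": 1, "glc__D_c": 1})
    _reaction(m, "HEX1", {"glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1})
    _reaction(m, "G6PDH", {"g6p_c": -1, "nad_c": -1, "6pgl_c": 1, "nadh_c": 1, "h_c": 1})
    _reaction(m, "PGL", {"6pgl_c": -1, "h2o_c": -1, "6pgc_c": 1, "h_c": 1})
    _reaction(m, "EDD", {"6pgc_c": -1, "2ddg6p_c": 1, "h2o_c": 1})
    _reaction(m, "EDA", {"2ddg6p_c": -1, "g3p_c": 1, "pyr_c": 1})
    _reaction(m, "GAPD", {"g3p_c": -1, "nad_c": -1, "pi_c": -1,
                          "13dpg_c": 1, "nadh_c": 1, "h_c": 1})
    _reaction(m, "PGK", {"13dpg_c": -1, "adp_c": -1, "3pg_c": 1, "atp_c": 1})
    _reaction(m, "PGM", {"3pg_c": -1, "2pg_c": 1}, reversible=True)
    _reaction(m, "ENO", {"2pg_c": -1, "pep_c": 1, "h2o_c": 1})
    _reaction(m, "PYK", {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1})
    _reaction(m, "NOX", {"nadh_c": -2, "o2_c": -1, "h_c": -2, "nad_c": 2, "h2o_c": 2})
    _exchanges(m, ["pi_c", "h_c", "h2o_c", "o2_c"])
    upstream = {"arbt_c", "glc__D_c", "g6p_c", "6pgl_c", "6pgc_c",
                "2ddg6p_c", "g3p_c", "13dpg_c"}
    cofactors = {"hqn_c", "atp_c", "adp_c", "nad_c", "nadh_c"}
    part = _sets(gsc={"3pg_c", "2pg_c"}, in_=upstream,
                 out={"pep_c", "pyr_c"}, iso=cofactors)
    return FixtureSpec(
        name="arbutin_ed", model=m, seed="3pg_c",
        precursors=("3pg_c", "g3p_c", "g6p_c", "pep_c", "pyr_c"),
        expected_fba=part, expected_gba=part,
        expected_yields={
            ("arbt_c", "pyr_c"): 0.50,   # 6 of 12 carbons; hydroquinone lost
            ("arbt_c", "3pg_c"): 0.25,
            ("g6p_c", "pyr_c"): 1.0,
            ("pyr_c", "g6p_c"): None,    # no gluconeogenesis in the fixture
        },
        expected_is_links=(frozenset({"hqn_c"}), frozenset()),
        notes="hydroquinone only leaves via its demand; ATP via the energy-balance reaction",
    )


def _false_gba_link() -> FixtureSpec:
    m = Model("fixture_false_gba_link")
    _species(m, [
        ("lys__L_c", "C6H15N2O2", 1, "c"),
        ("15dap_c", "C5H16N2", 2, "c"),
        ("ametam_c", "C14H24N6O3S", 2, "c"),
        ("na15dap_c", "C8H24N3", 3, "c"),   # synthetic formula, balances APCS
        ("5mta_c", "C11H15N5O3S", 0, "c"),
        ("ade_c", "C5H5N5", 0, "c"),
        ("pyr_c", "C3H3O3", -1, "c"),
        ("co2_c", "CO2", 0, "c"),
        ("nh3_c", "H3N", 0, "c"),
        ("h2_c", "H2", 0, "c"),
        ("h2s_c", "H2S", 0, "c"),
        ("h_c", "H", 1, "c"),
        ("h2o_c", "H2O", 0, "c"),
    ])
    _reaction(m, "LYSDC", {"lys__L_c": -1, "h_c": -1, "15dap_c": 1, "co2_c": 1})
    # cadaverine is a co-substrate here: no carbon flows 15dap -> 5mta
    _reaction(m, "APCS", {"15dap_c": -1, "ametam_c": -1,
                          "na15dap_c": 1, "5mta_c": 1, "h_c": 1})
    _reaction(m, "MTADEG_L", {"5mta_c": -1, "h2o_c": -3, "ade_c": 1, "pyr_c": 2,
                              "h2s_c": 1, "h2_c": 3, "h_c": 2})
    # redox-self-sufficient lump: surplus pyruvate is oxidised to CO2 to
    # supply the electrons, keeping the reduction-degree bound intact
    _reaction(m, "LYSSYN_L", {"pyr_c": -14, "nh3_c": -10, "h_c": -19,
                              "lys__L_c": 5, "co2_c": 12, "h2o_c": 8})
    _exchanges(m, ["nh3_c", "h2_c", "h2s_c", "h_c", "h2o_c"])
    return FixtureSpec(
        name="false_gba_link", model=m, seed="pyr_c", precursors=("pyr_c",),
        expected_fba=_sets(gsc={"pyr_c"}, out={"lys__L_c", "15dap_c", "co2_c"},
                           in_={"5mta_c"},
                           iso={"ametam_c", "na15dap_c", "ade_c"}),
        expected_gba=_sets(gsc={"pyr_c", "lys__L_c", "15dap_c", "5mta_c"},
                           in_={"ametam_c"}, out={"na15dap_c", "ade_c"}),
        expected_yields={
            ("pyr_c", "lys__L_c"): 5 / 7,  # exactly the reduction-degree bound
            ("lys__L_c", "pyr_c"): None,   # cadaverine is a dead end for FBA
            ("5mta_c", "pyr_c"): 6 / 11,
        },
        notes="graph link 15dap->5mta transfers no carbon; FBA rejects lysine uptake",
    )


def _double_transport() -> FixtureSpec:
    m = Model("fixture_double_transport")
    _species(m, [
        ("pep_c", "C3H2O6P", -3, "c"),
        ("pyr_c", "C3H3O3", -1, "c"),
        ("pyr_m", "C3H3O3", -1, "m"),
        ("oaa_c", "C4H2O5", -2, "c"),
        ("oaa_m", "C4H2O5", -2, "m"),
        ("cit_c", "C6H5O7", -3, "c"),
        ("cit_m", "C6H5O7", -3, "m"),
        ("accoa_m", "C23H34N7O17P3S", -4, "m"),
        ("coa_m", "C21H32N7O16P3S", -4, "m"),
        ("ac_c", "C2H3O2", -1, "c"),
        ("for_m", "CHO2", -1, "m"),
        ("co2_c", "CO2", 0, "c"),
        ("pi_c", "HPO4", -2, "c"),
        ("h_c", "H", 1, "c"),
        ("h_m", "H", 1, "m"),
        ("h2o_c", "H2O", 0, "c"),
        ("h2o_m", "H2O", 0, "m"),
    ])
    _reaction(m, "PPHL_L", {"pep_c": -1, "h2o_c": -1, "pyr_c": 1, "pi_c": 1})
    _reaction(m, "PYRtm", {"pyr_c": -1, "pyr_m": 1}, reversible=True)
    _reaction(m, "PFLm", {"pyr_m": -1, "coa_m": -1, "accoa_m": 1, "for_m": 1})
    _reaction(m, "CSm", {"accoa_m": -1, "h2o_m": -1, "oaa_m": -1,
                         "cit_m": 1, "coa_m": 1, "h_m": 1})
    # the antiporter graph analysis walks in both directions at once
    _reaction(m, "OAACITtm", {"cit_m": -1, "oaa_c": -1, "cit_c": 1, "oaa_m": 1},
              reversible=True)
    _reaction(m, "CITL", {"cit_c": -1, "oaa_c": 1, "ac_c": 1})
    _reaction(m, "PEPCK_L", {"oaa_c": -1, "pi_c": -1, "h_c": -1,
                             "pep_c": 1, "co2_c": 1, "h2o_c": 1})
    _exchanges(m, ["pi_c", "h_c", "h2o_c", "h_m", "h2o_m"])
    return FixtureSpec(
        name="double_transport", model=m, seed="pep_c", precursors=("pep_c", "oaa_c"),
        expected_fba=_sets(
            gsc={"pep_c"},
            out={"pyr_c", "pyr_m", "accoa_m", "for_m", "ac_c"},
            in_={"oaa_c", "cit_c"},
            iso={"oaa_m", "cit_m", "coa_m", "co2_c"},
        ),
        expected_gba=_sets(
            gsc={"pep_c", "pyr_c", "pyr_m", "accoa_m", "coa_m",
                 "cit_c", "cit_m", "oaa_c", "oaa_m"},
            out={"ac_c", "for_m"},
        ),
        expected_yields={
            ("pep_c", "pyr_c"): 1.0,
            ("pyr_c", "pep_c"): None,   # antiporter cannot do net transfer
            ("oaa_c", "pep_c"): 0.75,
        },
        notes="no PEP synthetase; OAACITtm cycling closes the graph loop only",
    )


def _cosubstrate() -> FixtureSpec:
    m = Model("fixture_cosubstrate")
    _species(m, [
        ("5aizc_c", "C9H11N3O9P", -3, "c"),
        ("asp__L_c", "C4H6NO4", -1, "c"),
        ("25aics_c", "C13H15N4O12P", -4, "c"),
        ("aicar_c", "C9H13N4O8P", -2, "c"),
        ("fum_c", "C4H2O4", -2, "c"),
        ("mal__L_c", "C4H4O5", -2, "c"),
        ("pyr_c", "C3H3O3", -1, "c"),
        ("co2_c", "CO2", 0, "c"),
        ("h2o_c", "H2O", 0, "c"),
        ("h_c", "H", 1, "c"),
        ("h2_c", "H2", 0, "c"),
    ])
    # aspartate is a co-substrate not producible from 5aizc
    _reaction(m, "PRASCS_L", {"5aizc_c": -1, "asp__L_c": -1, "25aics_c": 1, "h2o_c": 1})
    _reaction(m, "ADSL2", {"25aics_c": -1, "aicar_c": 1, "fum_c": 1})
    _reaction(m, "FUM", {"fum_c": -1, "h2o_c": -1, "mal__L_c": 1})
    _reaction(m, "ME_L", {"mal__L_c": -1, "h_c": -1, "pyr_c": 1, "co2_c": 1, "h2_c": 1})
    _exchanges(m, ["h2o_c", "h_c", "h2_c"])
    return FixtureSpec(
        name="cosubstrate", model=m, seed="pyr_c", precursors=("pyr_c",),
        expected_fba=_sets(gsc={"pyr_c"}, in_={"25aics_c", "fum_c", "mal__L_c"},
                           iso={"5aizc_c", "asp__L_c", "aicar_c", "co2_c"}),
        expected_gba=_sets(gsc={"25aics_c"}, in_={"5aizc_c", "asp__L_c"},
                           out={"aicar_c", "fum_c", "mal__L_c", "pyr_c"}),
        expected_yields={
            ("5aizc_c", "pyr_c"): None,   # aspartate cannot be sourced
            ("25aics_c", "pyr_c"): 3 / 13,
            ("fum_c", "pyr_c"): 0.75,
        },
        notes="all pyruvate carbons would come from aspartate, not 5aizc",
    )


CASES = {
    "linear": _linear,
    "coa_carrier": _coa_carrier,
    "chorismate_branch": _chorismate_branch,
    "arbutin_ed": _arbutin_ed,
    "false_gba_link": _false_gba_link,
    "double_transport": _double_transport,
    "cosubstrate": _cosubstrate,
}


def make_fixture(case: str) -> FixtureSpec:
    """Build a fixture model plus its expected bow-tie truth."""
    try:
        builder = CASES[case]
    except KeyError:
        raise ValueError(
            f"unknown fixture case {case!r}; available: {', '.join(sorted(CASES))}"
        )
    return builder()


def write_fixture(case: str, path: str | Path) -> FixtureSpec:
    """Write the fixture as SBML (L3+FBC) with a JSON truth sidecar."""
    spec = make_fixture(case)
    path = Path(path)
    # nominal objective so FBC round trips cleanly; every solve sets its own
    spec.model.objective = spec.model.reactions[0]
    cobra.io.write_sbml_model(spec.model, str(path))
    sidecar = path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(spec.truth_payload(), indent=1, sort_keys=True))
    return spec
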