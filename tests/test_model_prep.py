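"""Model loading, balance audit, carrier detection and preprocessing."""

import cobra
import pytest
from cobra import Metabolite, Model, Reaction

import bowtieflux as bf
from bowtieflux.config import AnalysisConfig, CarrierSpec


def _toy(mets, rxns):
    m = Model("toy")
    m.add_metabolites(
        [Metabolite(i, formula=f, charge=c, compartment=i.rsplit("_", 1)[-1])
         for i, f, c in mets]
    )
    for rid, stoich, rev in rxns:
        r = Reaction(rid, lower_bound=-1000.0 if rev else 0.0, upper_bound=1000.0)
        r.add_metabolites({m.metabolites.get_by_id(k): v for k, v in stoich.items()})
        m.add_reactions([r])
    return m


class TestLoadModel:
    def test_sbml_roundtrip_counts(self, tmp_path, specs):
        path = tmp_path / "linear.xml"
        cobra.io.write_sbml_model(specs["linear"].model, str(path))
        model = bf.load_model(path)
        assert len(model.metabolites) == 5
        assert len(model.reactions) == 4

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            bf.load_model(tmp_path / "nope.xml")

    def test_empty_file_raises(self, tmp_path):
        bad = tmp_path / "empty.xml"
        bad.write_text("")
        with pytest.raises(Exception):
            bf.load_model(bad)


class TestMassBalance:
    def test_balanced_reaction_absent(self):
        m = _toy([("a_c", "CH4O", 0), ("b_c", "CH4O", 0)],
                 [("R1", {"a_c": -1, "b_c": 1}, False)])
        report = bf.check_mass_balance(m)
        assert report.imbalanced == {}

    def test_hydrogen_imbalance_reported(self):
        m = _toy([("a_c", "C2H4O2", 0), ("b_c", "C2H2O2", 0)],
                 [("R1", {"a_c": -1, "b_c": 1}, False)])
        report = bf.check_mass_balance(m)
        assert report.imbalanced == {"R1": {"H": -2}}

    def test_undefined_formula_routes_to_skipped(self):
        # macromolecule stand-in: a tRNA-like species with an R-group formula
        m = _toy([("trnaglu_c", "C10H17O10PR", 0), ("glutrna_c", "C15H24NO13PR", 0)],
                 [("GLUTRS", {"trnaglu_c": -1, "glutrna_c": 1}, False)])
        report = bf.check_mass_balance(m)
        assert report.imbalanced == {}
        assert report.skipped == ["GLUTRS"]

    def test_fixtures_are_balanced(self, specs):
        for case, spec in specs.items():
            report = bf.check_mass_balance(spec.model)
            assert report.imbalanced == {}, case
            assert report.skipped == [], case


class TestCarbonMetabolites:
    def test_phosphate_excluded_compartments_distinct(self, specs):
        carbon = bf.carbon_metabolites(specs["double_transport"].model)
        assert "pi_c" not in carbon
        assert "pyr_c" in carbon and "pyr_m" in carbon  # one entry per compartment
        assert carbon["pyr_c"].carbon_count == 3

    def test_unparseable_formula_excluded(self):
        m = _toy([("x_c", "C3H6O3", 0), ("weird_c", "R2X", 0)], [])
        carbon = bf.carbon_metabolites(m)
        assert set(carbon) == {"x_c"}


class TestCarriers:
    def test_acetyl_coa_maps_to_coa(self, prepared):
        p = prepared["coa_carrier"]
        assert p.carrier_map["accoa_c"].tag == "CoA"
        assert p.info("accoa_c").moiety_carbons == 2
        assert "pyr_c" not in p.carrier_map
        assert "coa_c" not in p.carrier_map  # free carrier never mapped

    def test_udp_glucose_moiety_by_formula_subtraction(self):
        m = _toy([("udpg_c", "C15H22N2O17P2", -2), ("udp_c", "C9H11N2O12P2", -3)], [])
        mapping = bf.detect_carriers(m, bf.DEFAULT_CARRIERS)
        carbon = bf.carbon_metabolites(m, mapping)
        assert mapping["udpg_c"].tag == "UDP"
        assert carbon["udpg_c"].moiety_carbons == 6

    def test_ambiguous_match_raises(self):
        m = _toy([("accoa_c", "C23H34N7O17P3S", -4)], [])
        dup = CarrierSpec("CoA2", "coa2", "C21H32N7O16P3S", -4, r"coa")
        with pytest.raises(ValueError, match="multiple carriers"):
            bf.detect_carriers(m, list(bf.DEFAULT_CARRIERS) + [dup])


class TestPreprocess:
    def test_every_carbon_metabolite_has_one_demand(self, prepared):
        for case, p in prepared.items():
            for mid in p.carbon:
                assert mid in p.demand_of, (case, mid)
                rxn = p.demand_reaction(mid)
                assert rxn.lower_bound == 0 and rxn.upper_bound > 0

    def test_carrier_bound_demand_releases_carrier(self, prepared):
        p = prepared["coa_carrier"]
        stoich = {m.id: c for m, c in p.demand_reaction("accoa_c").metabolites.items()}
        assert stoich == {"accoa_c": -1.0, "coa_c": 1.0}
        # the free carrier's own demand is plain
        stoich = {m.id: c for m, c in p.demand_reaction("coa_c").metabolites.items()}
        assert stoich == {"coa_c": -1.0}

    def test_carbon_exchange_uptake_closed(self, specs):
        model = specs["linear"].model.copy()
        ex = Reaction("EX_A_c", lower_bound=-10.0, upper_bound=1000.0)
        ex.add_metabolites({model.metabolites.get_by_id("A_c"): -1})
        model.add_reactions([ex])
        p = bf.preprocess(model)
        assert p.model.reactions.get_by_id("EX_A_c").lower_bound == 0
        assert "EX_A_c" in p.registry["exchange_closed"]
        # non-carbon exchanges keep their bounds
        p2 = bf.preprocess(specs["arbutin_ed"].model)
        assert p2.model.reactions.get_by_id("EX_o2_c").lower_bound == -1000.0

    def test_energy_balance_added_once_and_balanced(self, prepared):
        p = prepared["arbutin_ed"]
        (ebal_id,) = p.registry["energy_balance"]
        ebal = p.model.reactions.get_by_id(ebal_id)
        assert ebal.reversibility
        assert ebal.check_mass_balance() == {}

    def test_energy_balance_skipped_without_species(self, prepared):
        assert prepared["linear"].registry["energy_balance"] == []

    def test_idempotent(self, specs):
        p1 = bf.preprocess(specs["arbutin_ed"].model)
        n = len(p1.model.reactions)
        p2 = bf.preprocess(p1.model, copy=True)
        assert len(p2.model.reactions) == n
        assert p2.demand_of == p1.demand_of

    def test_original_reactions_untouched(self, specs, prepared):
        for case, spec in specs.items():
            original = {r.id for r in spec.model.reactions}
            p = prepared[case]
            kept = {r.id for r in p.model.reactions} & original
            assert kept == original, case
            for rid in original:
                a = spec.model.reactions.get_by_id(rid)
                b = p.model.reactions.get_by_id(rid)
                assert {m.id: c for m, c in a.metabolites.items()} == \
                       {m.id: c for m, c in b.metabolites.items()}, (case, rid)

    def test_reject_many_imbalanced_reactions_rule(self):
        cfg = AnalysisConfig()
        mets = [(f"m{i}_c", "C2H4O2", 0) for i in range(7)] + \
               [(f"n{i}_c", "C2H2O2", 0) for i in range(7)]
        rxns = [(f"R{i}", {f"m{i}_c": -1, f"n{i}_c": 1}, False) for i in range(7)]
        m = _toy(mets, rxns)
        report = bf.check_mass_balance(m)
        assert report.n_imbalanced > cfg.max_imbalanced
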