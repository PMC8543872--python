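"""Currency-pair removal, graph construction and the SCC bow-tie."""

import networkx as nx
import pytest
from cobra import Metabolite, Model, Reaction
from hypothesis import given, settings, strategies as st

import bowtieflux as bf
from bowtieflux.bowtie import BowTiePartition
from bowtieflux.graph import MetaboliteGraph, bowtie_from_graph


def _model(mets, rxns):
    m = Model("toy")
    m.add_metabolites(
        [Metabolite(i, formula=f, charge=c, compartment=i.rsplit("_", 1)[-1])
         for i, f, c in mets]
    )
    out = []
    for rid, stoich, rev in rxns:
        r = Reaction(rid, lower_bound=-1000.0 if rev else 0.0, upper_bound=1000.0)
        r.add_metabolites({m.metabolites.get_by_id(k): v for k, v in stoich.items()})
        out.append(r)
    m.add_reactions(out)
    return m


NUCLEOTIDES = [
    ("udp_c", "C9H11N2O12P2", -3), ("utp_c", "C9H11N2O15P3", -4),
    ("atp_c", "C10H12N5O13P3", -4), ("adp_c", "C10H12N5O10P2", -3),
]


class TestLinkReaction:
    def test_atp_adp_pair_removed_udp_utp_kept(self):
        m = _model(NUCLEOTIDES,
                   [("NDPK", {"udp_c": -1, "atp_c": -1, "utp_c": 1, "adp_c": 1}, True)])
        links = bf.link_reaction(m.reactions.NDPK)
        assert links == {("udp_c", "utp_c"), ("utp_c", "udp_c")}

    def test_no_currency_species_keeps_single_link(self):
        m = _model([("a_c", "C2H4O2", 0), ("b_c", "C2H4O2", 0)],
                   [("R", {"a_c": -1, "b_c": 1}, False)])
        assert bf.link_reaction(m.reactions.R) == {("a_c", "b_c")}

    def test_hydride_pair_removed_from_dehydrogenase(self):
        m = _model([("nad_c", "C21H26N7O14P2", -1), ("nadh_c", "C21H27N7O14P2", -2),
                    ("etoh_c", "C2H6O", 0), ("acald_c", "C2H4O", 0)],
                   [("ALCD", {"nad_c": -1, "etoh_c": -1,
                              "nadh_c": 1, "acald_c": 1}, False)])
        assert bf.link_reaction(m.reactions.ALCD) == {("etoh_c", "acald_c")}

    def test_pure_currency_reaction_keeps_one_link(self):
        # the removal would orphan the reaction: the pair is kept instead
        m = _model([("nad_c", "C21H26N7O14P2", -1), ("nadh_c", "C21H27N7O14P2", -2)],
                   [("NOX", {"nadh_c": -1, "nad_c": 1}, False)])
        assert bf.link_reaction(m.reactions.NOX) == {("nadh_c", "nad_c")}

    def test_excluded_endpoints_never_linked(self):
        m = _model([("pyr_c", "C3H3O3", -1), ("co2_c", "CO2", 0),
                    ("acald_c", "C2H4O", 0)],
                   [("PDC", {"pyr_c": -1, "co2_c": 1, "acald_c": 1}, False)])
        assert bf.link_reaction(m.reactions.PDC) == {("pyr_c", "acald_c")}

    def test_pairs_matched_compartment_locally(self):
        # atp_c with adp_p is transport, not a group-transfer pair
        m = _model([("atp_c", "C10H12N5O13P3", -4), ("adp_p", "C10H12N5O10P2", -3),
                    ("glc_c", "C6H12O6", 0), ("g6p_c", "C6H11O9P", -2)],
                   [("ODD", {"atp_c": -1, "glc_c": -1, "g6p_c": 1, "adp_p": 1}, False)])
        links = bf.link_reaction(m.reactions.ODD)
        assert ("atp_c", "adp_p") in links  # pair not removed across compartments


class TestBuildGraph:
    def test_duplicate_links_merged_with_contributors(self):
        # two transaminases donate different amine groups, same backbone link
        m = _model(
            [("2kv_c", "C5H7O3", -1), ("val__L_c", "C5H11NO2", 0),
             ("glu__L_c", "C5H8NO4", -1), ("akg_c", "C5H4O5", -2),
             ("ala__L_c", "C3H7NO2", 0), ("pyr_c", "C3H3O3", -1)],
            [("ILVE", {"2kv_c": -1, "glu__L_c": -1, "val__L_c": 1, "akg_c": 1}, False),
             ("AVTA", {"2kv_c": -1, "ala__L_c": -1, "val__L_c": 1, "pyr_c": 1}, False)],
        )
        g = bf.build_graph(m)
        assert g.raw_link_count == 2
        assert g.graph.has_edge("2kv_c", "val__L_c")
        assert sorted(g.contributors("2kv_c", "val__L_c")) == ["AVTA", "ILVE"]

    def test_pseudo_reactions_contribute_no_links(self, specs, prepared):
        for case in ("coa_carrier", "arbutin_ed"):
            original = bf.build_graph(specs[case].model)
            with_pseudo = bf.build_graph(prepared[case].model)
            assert set(original.graph.edges) == set(with_pseudo.graph.edges), case

    def test_reaction_with_carbon_pair_always_contributes(self, specs):
        # every non-boundary reaction linking >= 2 eligible species keeps a link
        for case, spec in specs.items():
            g = bf.build_graph(spec.model)
            for rxn in spec.model.reactions:
                if rxn.boundary:
                    continue
                links = bf.link_reaction(rxn)
                nodes = set(g.graph.nodes)
                subs = {m.id for m, c in rxn.metabolites.items() if c < 0} & nodes
                prods = {m.id for m, c in rxn.metabolites.items() if c > 0} & nodes
                if subs and prods:
                    assert links, (case, rxn.id)

    def test_empty_model_gives_empty_graph(self):
        g = bf.build_graph(Model("empty"))
        assert g.n_nodes == 0 and g.n_links == 0 and g.raw_link_count == 0


def _brute_force_bowtie(g: nx.DiGraph) -> BowTiePartition:
    """Pairwise-reachability oracle for the bow-tie partition."""
    reach = {u: set(nx.descendants(g, u)) | {u} for u in g.nodes}
    unassigned = set(g.nodes)
    classes = []
    while unassigned:
        u = next(iter(unassigned))
        cls = {v for v in unassigned if v in reach[u] and u in reach[v]}
        classes.append(sorted(cls))
        unassigned -= cls
    classes.sort(key=lambda c: (-len(c), c))
    gsc = set(classes[0])
    out = set().union(*(reach[u] for u in gsc)) - gsc
    in_ = {v for v in g.nodes if gsc & reach[v]} - gsc - out
    iso = set(g.nodes) - gsc - out - in_
    return BowTiePartition(
        method="gba",
        sets={"GSC": frozenset(gsc), "IN": frozenset(in_),
              "OUT": frozenset(out), "IS": frozenset(iso)},
    )


class TestBowtieFromGraph:
    def test_cycle_with_pendant(self):
        g = nx.DiGraph([("A", "B"), ("B", "C"), ("C", "A"), ("A", "D")])
        part = bowtie_from_graph(g)
        assert part["GSC"] == {"A", "B", "C"}
        assert part["OUT"] == {"D"}
        assert part["IN"] == frozenset() and part["IS"] == frozenset()

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            bowtie_from_graph(nx.DiGraph())

    def test_matches_hand_derived_partition_on_every_fixture(self, specs, gba_partitions):
        for case, spec in specs.items():
            assert gba_partitions[case].sets == spec.expected_gba, case

    def test_node_choice_invariance(self, gba_partitions):
        part = gba_partitions["double_transport"]
        g = bf.build_graph(bf.make_fixture("double_transport").model).graph
        for anchor in sorted(part["GSC"]):
            out = frozenset(nx.descendants(g, anchor)) - part["GSC"]
            in_ = frozenset(nx.ancestors(g, anchor)) - part["GSC"]
            assert out == part["OUT"] and in_ == part["IN"]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=50),
        edges=st.lists(
            st.tuples(st.integers(0, 49), st.integers(0, 49)), max_size=150
        ),
    )
    def test_equals_reachability_oracle_on_random_digraphs(self, n, edges):
        g = nx.DiGraph()
        g.add_nodes_from(f"n{i:02d}" for i in range(n))
        g.add_edges_from(
            (f"n{a % n:02d}", f"n{b % n:02d}") for a, b in edges if a % n != b % n
        )
        assert bowtie_from_graph(g).sets == _brute_force_bowtie(g).sets
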