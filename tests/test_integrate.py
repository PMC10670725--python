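"""Overlap groups and mechanism-typed circuit assembly."""

import pandas as pd
import pytest
from hypothesis import given, strategies as st

import regcircuit as rc
from regcircuit.diffexpr import DirectionalSets
from regcircuit.integrate import (
    ProteinTable,
    circuit_summary,
    circuit_to_sif,
    filter_validated,
    normalize_interactions,
)


def _inter(rows):
    return pd.DataFrame(rows, columns=["mirna", "gene", "support_type", "database"])


class TestFilterValidated:
    def test_negative_support_removed_case_insensitive(self):
        df = _inter([
            ("hsa-mir-1", "A", "Functional MTI", "miRTarBase"),
            ("hsa-mir-1", "B", "Negative", "miRTarBase"),
            ("hsa-mir-2", "C", "non-NEGATIVE-ish", "TarBase"),
        ])
        out = filter_validated(df)
        assert set(zip(out["mirna"], out["gene"])) == {("hsa-mir-1", "A")}

    def test_duplicates_collapse_to_one_edge(self):
        df = _inter([
            ("hsa-mir-1", "a", "validated", "miRecords"),
            ("HSA-MIR-1", "A", "validated", "TarBase"),
        ])
        out = filter_validated(df)
        assert len(out) == 1

    def test_all_negative_gives_empty_table(self):
        df = _inter([("m", "g", "negative", "db")])
        out = filter_validated(df)
        assert out.empty

    def test_alias_table_maps_precursor_to_mature(self):
        df = normalize_interactions(
            _inter([("hsa-mir-200b", "CFL2", "validated", "x")]),
            alias={"hsa-mir-200b": "hsa-miR-200b-3p"},
        )
        assert df.loc[0, "mirna"] == "hsa-mir-200b-3p"


class TestProteinTable:
    def test_conflicting_directions_rejected(self):
        df = pd.DataFrame({"gene": ["a", "A"], "direction": ["up", "down"]})
        with pytest.raises(ValueError, match="conflicting"):
            ProteinTable.from_frame(df)

    def test_consistent_duplicates_collapse(self):
        df = pd.DataFrame({"gene": ["a", "A"], "direction": ["up", "up"]})
        assert ProteinTable.from_frame(df).directions == {"A": "up"}


class TestOverlapGroups:
    def test_directional_intersections(self):
        degs = DirectionalSets(up=frozenset({"U1", "U2"}),
                               down=frozenset({"A", "B"}), kind="mRNA")
        prot = ProteinTable(directions={"B": "down", "C": "down", "U1": "up",
                                        "U2": "down", "A": "up"})
        g = rc.build_overlap_groups(degs, prot)
        assert g.g_down_down == {"B"}
        assert g.g_up_up == {"U1"}
        assert g.g_up_down == {"U2"}
        assert g.g_down_up == {"A"}

    def test_disjoint_universes_give_empty_groups(self):
        degs = DirectionalSets(up=frozenset({"X"}), down=frozenset({"Y"}), kind="mRNA")
        prot = ProteinTable(directions={"Z": "up"})
        g = rc.build_overlap_groups(degs, prot)
        assert not (g.g_down_down | g.g_up_up | g.g_up_down | g.g_down_up)


def _brute_circuits(dem_dirs, deg_dirs, prot_dirs, pairs):
    """Exhaustive application of the three mechanism rules."""
    rrc1 = {(m, g) for m, g in pairs
            if dem_dirs.get(m) == "up" and deg_dirs.get(g) == "down"
            and prot_dirs.get(g) == "down"}
    rrc2 = {(m, g) for m, g in pairs
            if dem_dirs.get(m) == "up" and deg_dirs.get(g) == "up"
            and prot_dirs.get(g) == "down"}
    irc = {(m, g) for m, g in pairs
           if dem_dirs.get(m) == "down" and deg_dirs.get(g) == "up"
           and prot_dirs.get(g) == "up"}
    return rrc1, rrc2, irc


MIRNAS = ["hsa-mir-1", "hsa-mir-2", "hsa-mir-3"]
GENES = ["G1", "G2", "G3", "G4"]
DIRS = st.sampled_from(["up", "down", "none"])


class TestAssembleCircuits:
    def test_rrc1_contains_matching_edge(self):
        dems = DirectionalSets(up=frozenset({"hsa-mir-1"}), down=frozenset(),
                               kind="miRNA")
        groups = rc.OverlapGroups(g_down_down=frozenset({"G1"}))
        validated = filter_validated(_inter([("hsa-mir-1", "G1", "validated", "db")]))
        rrc1, rrc2, irc = rc.assemble_circuits(dems, groups, validated)
        assert rrc1.edges == {("hsa-mir-1", "G1")}
        assert rrc2.edges == frozenset() and irc.edges == frozenset()

    def test_wrong_direction_edge_appears_nowhere(self):
        dems = DirectionalSets(up=frozenset(), down=frozenset({"hsa-mir-2"}),
                               kind="miRNA")
        groups = rc.OverlapGroups(g_down_down=frozenset({"G1"}))
        validated = filter_validated(_inter([("hsa-mir-2", "G1", "validated", "db")]))
        for c in rc.assemble_circuits(dems, groups, validated):
            assert c.edges == frozenset()

    def test_down_up_group_yields_no_circuit(self):
        """mRNA-down/protein-up genes contradict the miRNA mechanism and are
        deliberately excluded from all three circuits."""
        dems = DirectionalSets(up=frozenset({"hsa-mir-1"}),
                               down=frozenset({"hsa-mir-2"}), kind="miRNA")
        groups = rc.OverlapGroups(g_down_up=frozenset({"G1"}))
        validated = filter_validated(_inter([
            ("hsa-mir-1", "G1", "validated", "db"),
            ("hsa-mir-2", "G1", "validated", "db"),
        ]))
        for c in rc.assemble_circuits(dems, groups, validated):
            assert c.edges == frozenset()

    @given(
        dem_dirs=st.fixed_dictionaries({m: DIRS for m in MIRNAS}),
        deg_dirs=st.fixed_dictionaries({g: DIRS for g in GENES}),
        prot_dirs=st.fixed_dictionaries({g: DIRS for g in GENES}),
        edges=st.sets(st.tuples(st.sampled_from(MIRNAS), st.sampled_from(GENES))),
    )
    def test_matches_exhaustive_rule_application(self, dem_dirs, deg_dirs,
                                                 prot_dirs, edges):
        dems = DirectionalSets(
            up=frozenset(m for m, d in dem_dirs.items() if d == "up"),
            down=frozenset(m for m, d in dem_dirs.items() if d == "down"),
            kind="miRNA",
        )
        degs = DirectionalSets(
            up=frozenset(g for g, d in deg_dirs.items() if d == "up"),
            down=frozenset(g for g, d in deg_dirs.items() if d == "down"),
            kind="mRNA",
        )
        prot = ProteinTable(directions={g: d for g, d in prot_dirs.items()
                                        if d != "none"})
        groups = rc.build_overlap_groups(degs, prot)
        validated = filter_validated(
            _inter([(m, g, "validated", "db") for m, g in edges])
        )
        got = rc.assemble_circuits(dems, groups, validated)
        # the oracle applies directions only where both omics layers agree
        # with the DE call, matching build_overlap_groups semantics
        deg_eff = {g: d for g, d in deg_dirs.items() if d != "none"}
        expected = _brute_circuits(dem_dirs, deg_eff, prot.directions, edges)
        for circuit, exp in zip(got, expected):
            assert circuit.edges == exp

    def test_order_independence_and_idempotence(self):
        dems = DirectionalSets(up=frozenset({"hsa-mir-1", "hsa-mir-2"}),
                               down=frozenset(), kind="miRNA")
        groups = rc.OverlapGroups(g_down_down=frozenset({"G1", "G2"}))
        rows = [("hsa-mir-1", "G1", "validated", "a"),
                ("hsa-mir-2", "G2", "validated", "b"),
                ("hsa-mir-1", "G2", "validated", "c")]
        fwd = rc.assemble_circuits(dems, groups, filter_validated(_inter(rows)))
        rev = rc.assemble_circuits(dems, groups, filter_validated(_inter(rows[::-1])))
        assert fwd[0].edges == rev[0].edges
        again = rc.assemble_circuits(dems, groups, filter_validated(_inter(rows)))
        assert again[0] == fwd[0]


class TestSummary:
    def test_empty_circuit(self):
        c = rc.RegulatoryCircuit("RRC1", frozenset(), {}, {}, {})
        s = circuit_summary(c)
        assert (s["n_edges"], s["n_mirnas"], s["n_genes"]) == (0, 0, 0)

    def test_star(self):
        edges = frozenset(("m1", f"G{i}") for i in range(5))
        c = rc.RegulatoryCircuit("RRC1", edges, {"m1": "up"},
                                 {f"G{i}": "down" for i in range(5)},
                                 {f"G{i}": "down" for i in range(5)})
        s = circuit_summary(c)
        assert (s["n_edges"], s["n_mirnas"], s["n_genes"]) == (5, 1, 5)

    @given(st.sets(st.tuples(st.sampled_from(MIRNAS), st.sampled_from(GENES)),
                   min_size=1))
    def test_counts_match_recount(self, edges):
        mirnas = {m for m, _ in edges}
        genes = {g for _, g in edges}
        c = rc.RegulatoryCircuit("IRC", frozenset(edges),
                                 {m: "down" for m in mirnas},
                                 {g: "up" for g in genes},
                                 {g: "up" for g in genes})
        s = circuit_summary(c)
        assert s["n_edges"] == len(edges)
        assert s["n_mirnas"] == len(mirnas)
        assert s["n_genes"] == len(genes)

    def test_sif_output(self):
        c = rc.RegulatoryCircuit("RRC1", frozenset({("m1", "G1")}),
                                 {"m1": "up"}, {"G1": "down"}, {"G1": "down"})
        assert circuit_to_sif(c) == "m1\trepresses\tG1\n"
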