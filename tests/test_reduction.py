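import numpy as np
import pytest

from drum.efm import enumerate_efms
from drum.netio import NetworkError, parse_reaction_table, stoichiometric_matrix
from drum.reduction import (
    MacroReaction,
    SubnetworkSpec,
    assemble_reduced_model,
    count_reduced_efms,
    extract_subnetwork,
    merge_reverse_pairs,
    model_from_dict,
    model_to_dict,
    reduce_network,
    reduce_subnetwork,
)
from drum.fixtures import (
    ACCUMULATING,
    COFACTORS,
    TISO_REACTION_TABLE,
    build_tisochrysis_model,
)

CHAIN = "r1: S -> A\nr2: A -> B\nr3: B -> T"


class TestExtractSubnetwork:
    def test_single_reaction_view_classifies_boundary(self):
        net = parse_reaction_table(CHAIN)
        sub = extract_subnetwork(net, SubnetworkSpec("sn", ["r2"], []))
        assert sub.network.reaction_ids == ["r2"]
        assert set(sub.boundary_ids) == {"A", "B"}

    def test_reaction_duplication_across_subnetworks(self):
        net = parse_reaction_table(CHAIN)
        s1 = extract_subnetwork(net, SubnetworkSpec("sn1", ["r1", "r2"], ["A"]))
        s2 = extract_subnetwork(net, SubnetworkSpec("sn2", ["r2", "r3"], ["B"]))
        assert "r2" in s1.network.reaction_ids and "r2" in s2.network.reaction_ids

    def test_unknown_reaction_rejected(self):
        net = parse_reaction_table(CHAIN)
        with pytest.raises(NetworkError, match="unknown reactions"):
            extract_subnetwork(net, SubnetworkSpec("sn", ["zz"], []))

    def test_untouched_internal_species_rejected(self):
        net = parse_reaction_table(CHAIN)
        with pytest.raises(NetworkError, match="not touched"):
            extract_subnetwork(net, SubnetworkSpec("sn", ["r1"], ["B"]))


class TestReduceSubnetwork:
    def test_chain_collapses_to_overall_conversion(self):
        net = parse_reaction_table("r1: Aext -> X\nr2: X -> Bext")
        sub = extract_subnetwork(net, SubnetworkSpec("sn", ["r1", "r2"], ["X"]))
        (mr,), _ = reduce_subnetwork(sub)
        assert mr.stoich == pytest.approx({"Aext": -1.0, "Bext": 1.0})

    def test_cofactors_cancel_in_macro_reaction(self):
        net = parse_reaction_table(
            "r1: Aext + ATP -> X + ADP\nr2: X + ADP -> Bext + ATP"
        )
        sub = extract_subnetwork(
            net, SubnetworkSpec("sn", ["r1", "r2"], ["X", "ATP", "ADP"])
        )
        (mr,), _ = reduce_subnetwork(sub)
        assert mr.stoich == pytest.approx({"Aext": -1.0, "Bext": 1.0})

    def test_dead_subnetwork_yields_no_macro_reaction(self):
        net = parse_reaction_table("r1: S -> X")
        sub = extract_subnetwork(net, SubnetworkSpec("sn", ["r1"], ["X"]))
        with pytest.warns(UserWarning, match="dead"):
            mrs, _ = reduce_subnetwork(sub)
        assert mrs == []

    def test_best_yield_selection_keeps_one_mode(self):
        # two routes S -> P with different substrate demand; selection keeps
        # the cheaper one
        net = parse_reaction_table(
            "r1: 2 S -> X\nr2: S -> X\nr3: X -> P\nr4: P -> Pext"
        )
        sub = extract_subnetwork(
            net,
            SubnetworkSpec(
                "sn", ["r1", "r2", "r3", "r4"], ["X", "P"],
                selection=("best-yield", "S", "Pext", "r4"),
            ),
        )
        (mr,), _ = reduce_subnetwork(sub)
        assert mr.stoich["S"] == pytest.approx(-1.0)


class TestMergeReversePairs:
    def test_exact_negatives_merge_to_reversible(self):
        mrs = [
            MacroReaction("f", {"A": -1.0, "B": 1.0}),
            MacroReaction("b", {"A": 1.0, "B": -1.0}),
        ]
        (merged,) = merge_reverse_pairs(mrs)
        assert merged.reversible and merged.stoich == {"A": -1.0, "B": 1.0}

    def test_glycolysis_pair_with_atp_asymmetry_stays_separate(self):
        # forward invests no ATP, backward does: not negatives of each other
        mr3 = MacroReaction("MR3", {"GAP": -2.0, "H2O": -1.0, "G6P": 1.0, "Pi": 1.0})
        mr4 = MacroReaction(
            "MR4", {"G6P": -1.0, "ATP": -1.0, "H": 1.0, "ADP": 1.0, "GAP": 2.0}
        )
        out = merge_reverse_pairs([mr3, mr4])
        assert len(out) == 2 and not any(m.reversible for m in out)

    def test_empty_list(self):
        assert merge_reverse_pairs([]) == []


class TestAssembleReducedModel:
    def test_packaged_reactions_assemble_to_eight_columns(self, tiso):
        assert tiso.model.K_prime.shape[1] == 8
        assert set(tiso.model.dropped) == COFACTORS

    def test_empty_drop_set_keeps_all_rows(self):
        mrs = [MacroReaction("m", {"A": -1.0, "B": 1.0})]
        model = assemble_reduced_model(mrs, accumulating={"A"}, biomass="B")
        assert set(model.species) == {"A", "B"}

    def test_dropping_accumulating_species_rejected(self):
        mrs = [MacroReaction("m", {"A": -1.0, "B": 1.0})]
        with pytest.raises(NetworkError, match="accumulating"):
            assemble_reduced_model(mrs, accumulating={"A"}, biomass="B", drop={"A"})

    def test_dropping_biomass_rejected(self):
        mrs = [MacroReaction("m", {"A": -1.0, "B": 1.0})]
        with pytest.raises(NetworkError, match="biomass"):
            assemble_reduced_model(mrs, accumulating={"A"}, biomass="B", drop={"B"})

    def test_json_round_trip(self, tiso):
        again = model_from_dict(model_to_dict(tiso.model))
        assert again.species == tiso.model.species
        assert np.allclose(again.K_prime, tiso.model.K_prime)
        assert [m.id for m in again.macro_reactions] == tiso.model.macro_ids


class TestCountReducedEfms:
    def test_packaged_model_has_eleven_modes(self, tiso):
        assert count_reduced_efms(tiso.model) == 11

    def test_empty_model(self):
        mrs = [MacroReaction("m", {"A": -1.0, "B": 1.0})]
        model = assemble_reduced_model(mrs, accumulating={"A"}, biomass="B")
        model.macro_reactions = []
        assert count_reduced_efms(model) == 0

    def test_one_reversible_reaction_counts_twice(self):
        mrs = [MacroReaction("m", {"A": -1.0, "B": 1.0}, reversible=True)]
        model = assemble_reduced_model(mrs, accumulating={"A"}, biomass="B")
        assert count_reduced_efms(model) == 2


class TestFullReduction:
    def _pipeline(self):
        net = parse_reaction_table(
            "u1: Sext -> M\nu2: M -> A\n"
            "v1: A -> N\nv2: N -> Bio\n"
        )
        specs = [
            SubnetworkSpec("up", ["u1", "u2"], ["M"]),
            SubnetworkSpec("down", ["v1", "v2"], ["N"]),
        ]
        return net, specs

    def test_subnetwork_balances_hold_in_full_network(self):
        net, specs = self._pipeline()
        model, efms = reduce_network(
            net, specs, accumulating={"A"}, biomass="Bio"
        )
        _, _, cols = stoichiometric_matrix(net)
        for spec in specs:
            K_int, _, _ = stoichiometric_matrix(net, row_subset=set(spec.internal_ids))
            E = efms[spec.name]
            for j in range(E.n_modes):
                v = np.zeros(len(net.reactions))
                for rid, x in zip(E.reaction_ids, E.modes[:, j]):
                    v[cols[rid]] += x
                assert np.allclose(K_int @ v, 0.0, atol=1e-9)

    def test_reduced_rates_match_embedded_mode_rates(self, rng):
        """K'·α equals (K E α) restricted to the retained rows for random
        nonnegative α — the reduced dynamics are the lumped full dynamics."""
        net, specs = self._pipeline()
        model, efms = reduce_network(net, specs, accumulating={"A"}, biomass="Bio")
        Kfull, rows, cols = stoichiometric_matrix(net)
        alpha = rng.random(len(model.macro_reactions))
        v = np.zeros(len(net.reactions))
        for j, m in enumerate(model.macro_reactions):
            sn, col = m.source
            E = efms[sn]
            for rid, x in zip(E.reaction_ids, E.modes[:, col]):
                v[cols[rid]] += x * alpha[j]
        full = Kfull @ v
        reduced = model.K_prime @ alpha
        for i, sid in enumerate(model.species):
            assert reduced[i] == pytest.approx(full[rows[sid]], abs=1e-9)

    def test_reduction_is_order_independent(self):
        net, specs = self._pipeline()
        m1, _ = reduce_network(net, specs, accumulating={"A"}, biomass="Bio")
        net2 = parse_reaction_table(
            "v1: A -> N\nv2: N -> Bio\n"
            "u1: Sext -> M\nu2: M -> A\n"
        )
        m2, _ = reduce_network(
            net2, list(reversed(specs)), accumulating={"A"}, biomass="Bio"
        )
        s1 = {m.id: m.stoich for m in m1.macro_reactions}
        s2 = {m.id: m.stoich for m in m2.macro_reactions}
        assert set(s1) == set(s2)
        for mid in s1:
            assert s1[mid] == pytest.approx(s2[mid])

    def test_reduction_idempotent_on_macroscopic_input(self):
        """Feeding the packaged macroscopic equations through the full
        split->EFM->reduce path as single-reaction sub-networks reproduces
        their coefficients at 2-decimal display precision."""
        from drum.fixtures import CLAMPED

        net = parse_reaction_table(TISO_REACTION_TABLE)
        specs = [SubnetworkSpec(r.id, [r.id], []) for r in net.reactions]
        model, _ = reduce_network(
            net, specs, accumulating=set(ACCUMULATING), biomass="B",
            drop=set(COFACTORS), clamp=set(CLAMPED),
        )
        reference = build_tisochrysis_model().model
        assert len(model.macro_reactions) == len(reference.macro_reactions)
        got_by_id = {m.id.split(".")[0]: m for m in model.macro_reactions}
        for m in reference.macro_reactions:
            got = got_by_id[m.id]
            strip = lambda st: {
                s: round(c, 2) for s, c in st.items() if s not in COFACTORS and c != 0
            }
            assert strip(got.stoich) == pytest.approx(strip(m.stoich))
            assert got.reversible == m.reversible
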