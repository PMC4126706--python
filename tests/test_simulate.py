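import numpy as np
import pytest

from drum.efm import enumerate_efms
from drum.netio import NetworkError, parse_reaction_table
from drum.reduction import MacroReaction, SubnetworkSpec, assemble_reduced_model, reduce_network
from drum.simulate import (
    Environment,
    KineticLaw,
    LightSignal,
    Trajectory,
    carbon_diagnostics,
    integrate,
    light_intensity,
    ode_rhs,
    rate_vector,
    reconstruct_fluxes,
    total_biomass,
)
from drum.fixtures import tisochrysis_laws


class TestLightIntensity:
    def test_square_wave_day_value(self):
        sig = LightSignal(form="square", photoperiod=24, day_length=12, I_max=100, phase=0)
        assert light_intensity(sig, 6.0) == 100.0

    @pytest.mark.parametrize("form", ["square", "truncated-sine"])
    def test_dark_window_is_zero(self, form):
        sig = LightSignal(form=form, photoperiod=24, day_length=12, I_max=100, phase=0)
        assert light_intensity(sig, 18.0) == 0.0
        assert light_intensity(sig, 18.0 + 48.0) == 0.0  # periodicity

    def test_truncated_sine_peaks_at_mid_window(self):
        sig = LightSignal(form="truncated-sine", photoperiod=24, day_length=12,
                          I_max=250, phase=12)
        assert light_intensity(sig, 12 + 6.0) == pytest.approx(250.0)

    def test_nonnegative_everywhere(self):
        sig = LightSignal(form="truncated-sine", photoperiod=24, day_length=10,
                          I_max=300, phase=5)
        t = np.linspace(0, 72, 1000)
        assert np.all(light_intensity(sig, t) >= 0)

    def test_invalid_day_length_rejected(self):
        with pytest.raises(NetworkError):
            LightSignal(photoperiod=24, day_length=30)


class TestRateVector:
    def test_photosynthesis_rate_proportional_to_light(self):
        laws = [KineticLaw("MR1", "light-proportional", [], [11.07e-3])]
        alpha = rate_vector({}, I=100.0, laws=laws)
        assert alpha[0] == pytest.approx(1.107)

    def test_all_rates_vanish_in_dark_with_empty_pools(self):
        laws = tisochrysis_laws()
        state = {s: 0.0 for s in ["GAP", "G6P", "PEP", "CARB", "PA", "NO3"]}
        assert np.allclose(rate_vector(state, I=0.0, laws=laws), 0.0)

    def test_reversible_law_net_negative_on_remobilization(self):
        laws = [KineticLaw("MR6", "reversible-mass-action", ["G6P", "CARB"], [70.0, 6.5])]
        alpha = rate_vector({"G6P": 0.0, "CARB": 1.0}, I=0.0, laws=laws)
        assert alpha[0] < 0

    def test_negative_concentration_rejected(self):
        laws = [KineticLaw("MR6", "reversible-mass-action", ["G6P", "CARB"], [70.0, 6.5])]
        with pytest.raises(NetworkError, match="negative"):
            rate_vector({"G6P": -0.1, "CARB": 1.0}, I=0.0, laws=laws)

    def test_law_arity_validated(self):
        with pytest.raises(NetworkError, match="expected"):
            KineticLaw("MR5", "reversible-mass-action", ["GAP"], [1.0])
        with pytest.raises(NetworkError, match="negative rate"):
            KineticLaw("MR3", "mass-action-1", ["GAP"], [-1.0])


class TestOdeRhs:
    def test_zero_biomass_reduces_to_pure_washout(self):
        mrs = [MacroReaction("m", {"S": -1.0, "B": 1.0})]
        model = assemble_reduced_model(mrs, accumulating=set(), biomass="B")
        laws = [KineticLaw("m", "mass-action-1", ["S"], [3.0])]
        env = Environment(dilution=0.5, inflow={"S": 2.0})
        state = np.array([1.0, 0.0])  # S, B with B = 0
        dy = ode_rhs(0.0, state, model, laws, env)
        i_s = model.species_index("S")
        assert dy[i_s] == pytest.approx(-0.5 * 1.0 + 0.5 * 2.0)
        assert dy[model.species_index("B")] == pytest.approx(0.0)

    def test_quiescent_closed_system_is_stationary(self):
        mrs = [MacroReaction("m", {"S": -1.0, "B": 1.0})]
        model = assemble_reduced_model(mrs, accumulating=set(), biomass="B")
        laws = [KineticLaw("m", "zero", [], [])]
        env = Environment(dilution=0.0, inflow={})
        dy = ode_rhs(0.0, np.array([1.0, 1.0]), model, laws, env)
        assert np.allclose(dy, 0.0)

    def test_single_reversible_column_expands_by_hand(self):
        mrs = [MacroReaction("MR6", {"G6P": -1.0, "CARB": 1.0}, reversible=True)]
        model = assemble_reduced_model(
            mrs, accumulating={"G6P"}, biomass="CARB"  # CARB stands in as row
        )
        laws = [KineticLaw("MR6", "reversible-mass-action", ["G6P", "CARB"], [70.0, 6.5])]
        env = Environment(dilution=0.1, inflow={})
        g6p, carb = 0.4, 0.2
        state = np.zeros(len(model.species))
        state[model.species_index("G6P")] = g6p
        state[model.species_index("CARB")] = carb
        dy = ode_rhs(0.0, state, model, laws, env)
        alpha = 70.0 * g6p - 6.5 * carb
        # biomass multiplier here is the CARB row itself (stand-in catalyst)
        assert dy[model.species_index("CARB")] == pytest.approx(
            alpha * carb - 0.1 * carb
        )

    def test_dimension_mismatch_rejected(self):
        mrs = [MacroReaction("m", {"S": -1.0, "B": 1.0})]
        model = assemble_reduced_model(mrs, accumulating=set(), biomass="B")
        laws = [KineticLaw("m", "zero", [], [])]
        env = Environment()
        with pytest.raises(NetworkError, match="dimension"):
            ode_rhs(0.0, np.zeros(5), model, laws, env)


class TestIntegrate:
    def test_washout_matches_closed_form(self, tiso, rng):
        """With zero biomass every pool decays exponentially to the inflow
        level: M(t) = M_in + (M0 - M_in) e^{-Dt}."""
        for D in rng.uniform(0.01, 2.0, size=3) / 24.0:
            env = Environment(dilution=float(D), inflow={"NO3": 0.2},
                              light=tiso.environment.light)
            y0 = {s: 0.0 for s in tiso.model.species}
            y0.update({"NO3": 0.05, "CARB": 0.3, "PA": 0.1})
            traj = integrate(tiso.model, tiso.laws, env, (0.0, 48.0), y0, grid=33)
            for sid, m_in in [("NO3", 0.2), ("CARB", 0.0), ("PA", 0.0)]:
                expect = m_in + (y0[sid] - m_in) * np.exp(-D * traj.times)
                scale = max(y0[sid], m_in)
                assert np.max(np.abs(traj.series(sid) - expect)) / scale < 1e-6

    def test_dark_quiescent_state_is_constant(self, tiso):
        env = Environment(dilution=0.0, inflow={},
                          light=LightSignal(form="square", day_length=0.0))
        y0 = {s: 0.0 for s in tiso.model.species}
        y0["NO3"] = 0.3
        y0["B"] = 0.2
        traj = integrate(tiso.model, tiso.laws, env, (0.0, 24.0), y0, grid=25)
        assert np.allclose(traj.state, traj.state[0], atol=1e-9)

    def test_negative_initial_state_rejected(self, tiso):
        y0 = {s: 0.0 for s in tiso.model.species}
        y0["NO3"] = -1.0
        with pytest.raises(NetworkError, match="nonnegative"):
            integrate(tiso.model, tiso.laws, tiso.environment, (0, 1), y0)

    def test_fixture_trajectory_stays_nonnegative(self, periodic_traj):
        assert periodic_traj.state.min() >= -1e-9

    def test_cycle_to_cycle_convergence(self, tiso):
        """Under periodic forcing, the lights-on state difference between
        successive cycles shrinks toward the periodic regime."""
        traj = integrate(
            tiso.model, tiso.laws, tiso.environment, (0.0, 24.0 * 20),
            tiso.initial_state(), grid=24 * 20 + 1,
        )
        diffs = []
        for c in (5, 10, 15, 19):
            i0 = np.argmin(np.abs(traj.times - 24 * (c - 1)))
            i1 = np.argmin(np.abs(traj.times - 24 * c))
            diffs.append(np.max(np.abs(traj.state[i1] - traj.state[i0])))
        assert diffs[-1] < diffs[0]
        assert diffs == sorted(diffs, reverse=True)


class TestFluxReconstruction:
    def test_single_mode_scales_linearly(self):
        net = parse_reaction_table("r1: S -> X\nr2: X -> P")
        specs = [SubnetworkSpec("sn", ["r1", "r2"], ["X"])]
        model, efms = reduce_network(net, specs, accumulating={"S"}, biomass="P")
        traj = Trajectory(
            times=np.array([0.0, 1.0]), species=model.species,
            state=np.zeros((2, len(model.species))), macro_ids=model.macro_ids,
            alpha=np.array([[2.0], [0.0]]),
        )
        traj = reconstruct_fluxes(traj, model, efms)
        assert not traj.macro_fluxes_only
        e = efms["sn"].modes[:, 0]
        assert np.allclose(traj.fluxes[0], 2.0 * e)
        assert np.allclose(traj.fluxes[1], 0.0)

    def test_duplicated_reaction_sums_contributions(self):
        net = parse_reaction_table("r1: S -> X\nr2: X -> P\nr3: X -> Q")
        specs = [
            SubnetworkSpec("a", ["r1", "r2"], ["X"]),
            SubnetworkSpec("b", ["r1", "r3"], ["X"]),
        ]
        model, efms = reduce_network(net, specs, accumulating={"S"}, biomass="P")
        alpha = np.array([[1.0, 3.0]])
        traj = Trajectory(
            times=np.array([0.0]), species=model.species,
            state=np.zeros((1, len(model.species))), macro_ids=model.macro_ids,
            alpha=alpha,
        )
        traj = reconstruct_fluxes(traj, model, efms)
        i_r1 = traj.flux_ids.index("r1")
        assert traj.fluxes[0, i_r1] == pytest.approx(1.0 + 3.0)

    def test_macroscopic_input_flagged(self, tiso, periodic_traj):
        traj = reconstruct_fluxes(periodic_traj, tiso.model, None)
        assert traj.macro_fluxes_only
        assert traj.flux_ids == tiso.model.macro_ids


class TestDerivedObservables:
    def _traj(self, state_map, species):
        n = 3
        state = np.zeros((n, len(species)))
        for sid, v in state_map.items():
            state[:, species.index(sid)] = v
        return Trajectory(
            times=np.linspace(0, 1, n), species=species, state=state,
            macro_ids=[], alpha=np.zeros((n, 0)),
        )

    COMPS = {
        "CARB": {"C": 6.0, "N": 0.0},
        "PA": {"C": 36.22, "N": 0.0},
        "B": {"C": 8.5442, "N": 1.31},
    }

    def test_total_carbon_with_empty_pools_is_biomass_only(self):
        traj = self._traj({"B": 0.5}, ["CARB", "PA", "B"])
        total_biomass(traj, self.COMPS, 0.05, accumulating={"CARB", "PA"})
        assert np.allclose(traj.derived["X_C"], 8.5442 * 0.5)

    def test_total_carbon_hand_sum(self):
        traj = self._traj({"B": 1.0, "CARB": 2.0}, ["CARB", "PA", "B"])
        total_biomass(traj, self.COMPS, 0.05, accumulating={"CARB", "PA"})
        assert np.allclose(traj.derived["X_C"], 8.5442 + 12.0)
        assert np.allclose(traj.derived["X_N"], 1.31)

    def test_chlorophyll_fixed_fraction(self):
        traj = self._traj({"B": 2.0}, ["CARB", "PA", "B"])
        total_biomass(traj, self.COMPS, 0.05, accumulating={"CARB", "PA"})
        assert np.allclose(traj.derived["chlorophyll"], 0.1)

    def test_missing_composition_rejected(self):
        traj = self._traj({"B": 1.0}, ["CARB", "PA", "B"])
        with pytest.raises(NetworkError, match="composition"):
            total_biomass(traj, {"B": {"C": 1.0}}, 0.05, accumulating={"CARB", "PA"})


class TestCarbonDiagnostics:
    def _traj_with_alpha(self, tiso, alpha):
        return Trajectory(
            times=np.array([0.0]), species=tiso.model.species,
            state=np.zeros((1, len(tiso.model.species))),
            macro_ids=tiso.model.macro_ids, alpha=np.array([alpha]),
        )

    def test_pure_biomass_synthesis_takes_full_share(self, tiso):
        alpha = np.zeros(8)
        alpha[tiso.model.macro_ids.index("MR8")] = 1.0
        d = carbon_diagnostics(self._traj_with_alpha(tiso, alpha), tiso.model, 0.0)
        assert d["shares"]["B"] == pytest.approx(1.0)
        assert d["shares"]["CARB"] == 0.0 and d["shares"]["PA"] == 0.0

    def test_pure_carbohydrate_storage_takes_full_share(self, tiso):
        alpha = np.zeros(8)
        alpha[tiso.model.macro_ids.index("MR6")] = 1.0
        d = carbon_diagnostics(self._traj_with_alpha(tiso, alpha), tiso.model, 0.0)
        assert d["shares"]["CARB"] == pytest.approx(1.0)

    def test_photosynthesis_alone_has_unit_quotient(self, tiso):
        """3 O2 released per 3 CO2 fixed in the photosynthetic equation."""
        alpha = np.zeros(8)
        alpha[tiso.model.macro_ids.index("MR1")] = 1.0
        d = carbon_diagnostics(self._traj_with_alpha(tiso, alpha), tiso.model, 0.0)
        assert d["photosynthetic_quotient"] == pytest.approx(1.0)

    def test_zero_flux_shares_flagged_undefined(self, tiso):
        d = carbon_diagnostics(self._traj_with_alpha(tiso, np.zeros(8)), tiso.model, 0.0)
        assert d["shares_undefined"]
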