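"""Worked example: day/night carbon storage of *Tisochrysis lutea*.

The packaged model is the eight-macroscopic-reaction reduction of the core
carbon network of a photoautotrophic microalga: photosynthesis (MR1), a
futile ATP-dissipating cycle (MR2), upper glycolysis forward/backward
(MR3/MR4), lower glycolysis (MR5), carbohydrate storage (MR6), lipid
storage as phosphatidic acid (MR7) and functional-biomass synthesis (MR8).
GAP, G6P and PEP are branching-point buffer pools; CARB and PA are the
day/night storage pools; B is the catalytic (functional) biomass.  Energy
cofactors (ATP/ADP, NAD(P)H/NAD(P)) appear in the macroscopic equations
but their fate is not modeled: their rows are dropped from K'.

Also here: hand-verified toy networks for exercising the EFM engine, a
synthetic-observation generator emulating chemostat measurements
(particulate C and N, chlorophyll, carbohydrates, neutral lipids, nitrate)
under a day/night light cycle, and in-silico knockouts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibrate import ObservationTable
from .efm import brute_force_efms, enumerate_efms
from .netio import Network, NetworkError, infer_composition_by_closure, parse_reaction_table
from .reduction import MacroReaction, ReducedModel, assemble_reduced_model
from .simulate import Environment, KineticLaw, LightSignal, Trajectory, integrate, total_biomass

# One line per macroscopic reaction, cofactors included.
TISO_REACTION_TABLE = """\
MR1: 30 Light + 3 CO2 + 2 H2O + Pi -> GAP + 3 O2
MR2: ATP + H2O -> ADP + Pi + H
MR3: 2 GAP + H2O -> G6P + Pi
MR4: G6P + ATP -> H + ADP + 2 GAP
MR5: GAP + ADP + Pi + NAD <-> PEP + ATP + NADH + H2O + H
MR6: G6P <-> CARB + Pi
MR7: GAP + 16.61 PEP + 2 ADP + 13.46 NAD + 29.3 NADPH + 34.48 H + 2.15 O2 <-> PA + 14.61 Pi + 2 ATP + 13.46 NADH + 29.3 NADP + 4.31 H2O + 16.61 CO2
MR8: 3.13 PEP + 7.37 O2 + 4.46 H + 1.31 NO3 + 1.14 G6P + 0.11 PA + 0.03 SO4 + 0.0025 Mg -> B + 11.67 CO2 + 4.23 Pi + 6 H2O
"""

COFACTORS = {"ATP", "ADP", "NADH", "NAD", "NADPH", "NADP"}
ACCUMULATING = {"GAP", "G6P", "PEP", "CARB", "PA"}
CLAMPED = {"Light", "CO2", "H2O", "H", "Pi", "O2", "SO4", "Mg"}

#: calibrated rate constants; units pair rates with mM effectors so that
#: alpha*B is mM/h (light in µE m^-2 s^-1, time in hours)
TISO_PARAMETERS = {
    "k_MR1": 11.07e-3,
    "k_MR3": 223.53,
    "k_MR4": 10.30,
    "k_MR5": 436.95,
    "k'_MR5": 5.00,
    "k_MR6": 70.00,
    "k'_MR6": 6.50,
    "k_MR7": 4.50e3,
    "k'_MR7": 0.60,
    "k_MR8": 2.18e4,
}

#: elemental carbon of the small species; PA and B follow by closure
KNOWN_CARBON = {
    "CO2": 1.0, "GAP": 3.0, "G6P": 6.0, "PEP": 3.0, "CARB": 6.0,
    "H2O": 0.0, "Pi": 0.0, "O2": 0.0, "H": 0.0, "NO3": 0.0,
    "SO4": 0.0, "Mg": 0.0,
}
KNOWN_NITROGEN = {
    "NO3": 1.0, "CO2": 0.0, "GAP": 0.0, "G6P": 0.0, "PEP": 0.0,
    "CARB": 0.0, "PA": 0.0, "H2O": 0.0, "Pi": 0.0, "O2": 0.0, "H": 0.0,
    "SO4": 0.0, "Mg": 0.0,
}

#: chemostat operating point of the knockout comparison: D = 1 d^-1,
#: inflow nitrogen 4.018 mgN/L -> mM NO3 at 14 g/mol atomic N
DEFAULT_DILUTION = 1.0 / 24.0
DEFAULT_S_IN = 4.018 / 14.0

#: peak irradiance of the synthetic truncated-sine day.  At this dilution the
#: culture needs a daily photon dose well above 100 µE m^-2 s^-1 peaks to
#: outgrow washout; 300 is a moderate outdoor-culture midday value and puts
#: the model on its nitrogen-limited periodic orbit.
DEFAULT_I_MAX = 300.0

#: chlorophyll as a fixed fraction of functional biomass (free fixture
#: parameter; the ratio itself is calibrated against chlorophyll data)
DEFAULT_CHL_FRACTION = 0.02

DEFAULT_INITIAL_POOLS = {"GAP": 0.01, "G6P": 0.01, "PEP": 0.01, "CARB": 0.01,
                         "PA": 0.01}
DEFAULT_INITIAL_B = 0.1
TRANSIENT_CYCLES = 10


@dataclass
class TisochrysisModel:
    """The packaged worked example: reduced model, kinetics, environment."""

    model: ReducedModel
    laws: list[KineticLaw]
    parameters: dict[str, float]
    environment: Environment
    network: Network  # the macroscopic reactions, cofactors included
    chl_fraction: float = DEFAULT_CHL_FRACTION

    def initial_state(self) -> dict[str, float]:
        state = {sid: 0.0 for sid in self.model.species}
        state.update(DEFAULT_INITIAL_POOLS)
        state["B"] = DEFAULT_INITIAL_B
        state["NO3"] = self.environment.inflow.get("NO3", DEFAULT_S_IN)
        return state


@dataclass
class SyntheticDataset:
    """Regenerable synthetic chemostat observations."""

    observations: ObservationTable
    truth: Trajectory
    initial_state: dict[str, float]
    parameters: dict[str, float]
    noise_sd: float
    seed: int


def _closure_network(net: Network) -> Network:
    """The macroscopic equations with cofactor columns removed (their rows
    cancel pairwise, so they carry no carbon or nitrogen information)."""
    reactions = []
    for r in net.reactions:
        stoich = {s: c for s, c in r.stoich.items() if s not in COFACTORS}
        reactions.append(replace(r, stoich=stoich))
    species = [s for s in net.species if s.id not in COFACTORS]
    return Network(species=species, reactions=reactions)


def tisochrysis_compositions() -> dict[str, dict[str, float]]:
    """C and N per mole for every retained species; the lipid (PA) carbon
    follows from carbon closure of MR7, then functional biomass (B) from
    MR8; B's nitrogen from MR8's nitrate stoichiometry."""
    net = _closure_network(parse_reaction_table(TISO_REACTION_TABLE))
    carbon = infer_composition_by_closure(net, "C", KNOWN_CARBON, ["PA", "B"])
    nitrogen = infer_composition_by_closure(net, "N", KNOWN_NITROGEN, ["B"])
    out: dict[str, dict[str, float]] = {}
    for sid in net.species_ids:
        if sid == "Light":
            continue
        out[sid] = {"C": carbon.get(sid, 0.0), "N": nitrogen.get(sid, 0.0)}
    return out


def tisochrysis_laws(parameters: dict[str, float] | None = None) -> list[KineticLaw]:
    p = {**TISO_PARAMETERS, **(parameters or {})}
    return [
        KineticLaw("MR1", "light-proportional", [], [p["k_MR1"]],
                   ["k_MR1"], ["µE^-1.m^2.s.mM.h^-1.mMB^-1"]),
        KineticLaw("MR2", "zero", [], []),
        KineticLaw("MR3", "mass-action-1", ["GAP"], [p["k_MR3"]],
                   ["k_MR3"], ["h^-1.mMB^-1"]),
        KineticLaw("MR4", "mass-action-1", ["G6P"], [p["k_MR4"]],
                   ["k_MR4"], ["h^-1.mMB^-1"]),
        KineticLaw("MR5", "reversible-mass-action", ["GAP", "PEP"],
                   [p["k_MR5"], p["k'_MR5"]], ["k_MR5", "k'_MR5"],
                   ["h^-1.mMB^-1", "h^-1.mMB^-1"]),
        KineticLaw("MR6", "reversible-mass-action", ["G6P", "CARB"],
                   [p["k_MR6"], p["k'_MR6"]], ["k_MR6", "k'_MR6"],
                   ["h^-1.mMB^-1", "h^-1.mMB^-1"]),
        KineticLaw("MR7", "product-2", ["PEP", "GAP", "PA"],
                   [p["k_MR7"], p["k'_MR7"]], ["k_MR7", "k'_MR7"],
                   ["mM^-1.h^-1.mMB^-1", "h^-1.mMB^-1"]),
        KineticLaw("MR8", "product-3", ["PEP", "G6P", "NO3"], [p["k_MR8"]],
                   ["k_MR8"], ["mM^-2.h^-1.mMB^-1"]),
    ]


def default_environment() -> Environment:
    return Environment(
        dilution=DEFAULT_DILUTION,
        inflow={"NO3": DEFAULT_S_IN},
        light=LightSignal(form="truncated-sine", photoperiod=24.0,
                          day_length=12.0, I_max=DEFAULT_I_MAX, phase=12.0),
    )


def build_tisochrysis_model(
    parameters: dict[str, float] | None = None,
    environment: Environment | None = None,
) -> TisochrysisModel:
    """Deterministically assemble the packaged day/night carbon model."""
    net = parse_reaction_table(TISO_REACTION_TABLE)
    mrs = [
        MacroReaction(id=r.id, stoich=dict(r.stoich), reversible=r.reversible)
        for r in net.reactions
    ]
    model = assemble_reduced_model(
        mrs,
        accumulating=set(ACCUMULATING),
        biomass="B",
        drop=set(COFACTORS),
        clamp=set(CLAMPED),
        compositions=tisochrysis_compositions(),
    )
    params = {**TISO_PARAMETERS, **(parameters or {})}
    return TisochrysisModel(
        model=model,
        laws=tisochrysis_laws(params),
        parameters=params,
        environment=environment or default_environment(),
        network=net,
    )


def simulate_tisochrysis(
    tiso: TisochrysisModel,
    n_cycles: float = 4.0,
    transient_cycles: float = TRANSIENT_CYCLES,
    points_per_hour: float = 4.0,
    rtol: float = 1e-8,
) -> Trajectory:
    """Simulate past the start-up transient and return the retained window
    (time re-zeroed at the window start), with elemental totals attached."""
    period = tiso.environment.light.photoperiod
    t_end = (transient_cycles + n_cycles) * period
    n_pts = int(t_end * points_per_hour) + 1
    traj = integrate(
        tiso.model, tiso.laws, tiso.environment, (0.0, t_end),
        tiso.initial_state(), grid=n_pts, rtol=rtol,
    )
    keep = traj.times >= transient_cycles * period - 1e-9
    window = Trajectory(
        times=traj.times[keep] - transient_cycles * period,
        species=traj.species,
        state=traj.state[keep],
        macro_ids=traj.macro_ids,
        alpha=traj.alpha[keep],
    )
    return total_biomass(window, tiso.model.compositions, tiso.chl_fraction,
                         accumulating=tiso.model.accumulating, biomass="B")


def generate_synthetic_observations(
    tiso: TisochrysisModel,
    noise_sd: float = 0.05,
    seed: int = 0,
    sampling_times: np.ndarray | None = None,
    transient_cycles: float = TRANSIENT_CYCLES,
    max_cycles: float = 30.0,
) -> SyntheticDataset:
    """Emulate the measured chemostat series from a forward simulation.

    Samples X_C, X_N, chlorophyll, CARB, PA, B and NO3 at *sampling_times*
    (hours after the discarded transient; default every 2 h over two
    cycles) and adds independent Gaussian noise with per-observable
    standard deviation ``noise_sd × range``.
    """
    if noise_sd < 0:
        raise NetworkError("noise_sd must be >= 0")
    if sampling_times is None:
        sampling_times = np.arange(0.0, 48.0 + 1e-9, 2.0)
    sampling_times = np.asarray(sampling_times, dtype=float)
    period = tiso.environment.light.photoperiod
    n_cycles = float(np.ceil(sampling_times[-1] / period))
    if n_cycles > max_cycles or sampling_times[0] < 0:
        raise NetworkError("sampling times extend beyond the simulated span")
    truth = simulate_tisochrysis(tiso, n_cycles=n_cycles,
                                 transient_cycles=transient_cycles)
    rng = np.random.default_rng(seed)
    names = ["X_C", "X_N", "chlorophyll", "CARB", "PA", "B", "NO3"]
    obs: dict[str, np.ndarray] = {}
    for name in names:
        clean = np.interp(sampling_times, truth.times, truth.series(name))
        if noise_sd > 0:
            span = float(np.ptp(truth.series(name)))
            clean = clean + rng.normal(0.0, noise_sd * span, size=clean.shape)
        obs[name] = clean
    initial_state = {
        sid: float(truth.state[0, i]) for i, sid in enumerate(truth.species)
    }
    return SyntheticDataset(
        observations=ObservationTable(times=sampling_times.copy(), observables=obs),
        truth=truth,
        initial_state=initial_state,
        parameters=dict(tiso.parameters),
        noise_sd=noise_sd,
        seed=seed,
    )


def knockout(tiso: TisochrysisModel, macro_reaction_id: str) -> TisochrysisModel:
    """Zero every rate constant of one macroscopic reaction (in-silico
    deletion of the corresponding metabolic function)."""
    if macro_reaction_id not in tiso.model.macro_ids:
        raise NetworkError(f"unknown macro reaction {macro_reaction_id!r}")
    laws = [
        replace(law, parameters=[0.0] * len(law.parameters))
        if law.macro_reaction_id == macro_reaction_id
        else law
        for law in tiso.laws
    ]
    params = dict(tiso.parameters)
    for law in tiso.laws:
        if law.macro_reaction_id == macro_reaction_id:
            for name in law.parameter_names:
                if name in params:
                    params[name] = 0.0
    return replace(tiso, laws=laws, parameters=params)


# ---------------------------------------------------------------------------
# toy network corpus for the EFM oracle


@dataclass
class ToyNetwork:
    name: str
    network: Network
    internal: set[str]
    expected_modes: list[np.ndarray] | None  # None for random entries


_TOYS = {
    "chain": ("r1: S -> A\nr2: A -> T", {"A"}, [[1.0, 1.0]]),
    "diamond": (
        "r1: S -> A\nr2: A -> X\nr3: A -> Y\nr4: X -> T\nr5: Y -> T\nr6: T -> Q",
        {"A", "X", "Y", "T"},
        [[1, 1, 0, 1, 0, 1], [1, 0, 1, 0, 1, 1]],
    ),
    "reversible-pair": ("r1: A <-> B", set(), [[1.0], [-1.0]]),
    "futile-cycle": ("r1: A -> B\nr2: B -> A", {"A", "B"}, [[1.0, 1.0]]),
    "cofactor-loop": (
        "r1: Aext + ATP -> X + ADP\nr2: X + ADP -> Bext + ATP",
        {"X", "ATP", "ADP"},
        [[1.0, 1.0]],
    ),
    "dead-end": ("r1: S -> X", {"X"}, []),
}


def toy_network(name: str, seed: int = 0, n_r: int = 8) -> ToyNetwork:
    """Registry of hand-verified toy networks plus seeded random ones."""
    if name in _TOYS:
        text, internal, modes = _TOYS[name]
        return ToyNetwork(
            name=name,
            network=parse_reaction_table(text),
            internal=set(internal),
            expected_modes=[np.asarray(m, dtype=float) for m in modes],
        )
    if name == "random":
        if n_r > 10:
            raise NetworkError("random toys are capped at 10 reactions")
        rng = np.random.default_rng(seed)
        n_s = int(rng.integers(2, 7))
        species = [f"M{i}" for i in range(n_s)]
        internal = {s for s in species if rng.random() < 0.6}
        lines = []
        for j in range(n_r):
            k_in = int(rng.integers(1, 3))
            k_out = int(rng.integers(1, 3))
            lhs = rng.choice(species, size=k_in, replace=False)
            rhs = rng.choice([s for s in species if s not in lhs],
                             size=min(k_out, n_s - k_in), replace=False)
            if len(rhs) == 0:
                rhs = ["SINK"]
            arrow = "<->" if rng.random() < 0.3 else "->"
            lines.append(f"r{j}: {' + '.join(lhs)} {arrow} {' + '.join(rhs)}")
        net = parse_reaction_table("\n".join(lines))
        return ToyNetwork(name=f"random-{seed}", network=net,
                          internal=internal & set(net.species_ids),
                          expected_modes=None)
    raise NetworkError(f"unknown toy network {name!r}")


def check_toy(name: str, **kwargs) -> bool:
    """Cross-check tableau enumeration against the brute-force oracle."""
    toy = toy_network(name, **kwargs)
    E = enumerate_efms(toy.network, toy.internal)
    oracle = brute_force_efms(toy.network, toy.internal)
    got = sorted(tuple(np.round(E.modes[:, j], 9)) for j in range(E.n_modes))
    want = sorted(tuple(np.round(m, 9)) for m in oracle)
    return got == want
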