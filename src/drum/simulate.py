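"""Kinetic ODE simulation of a reduced model under chemostat operation.

The reduced model's state vector M' collects substrates, the accumulating
metabolite pools A and functional biomass B (all in mM; B in mM of
functional biomass).  Functional biomass catalyzes every macroscopic rate,
and the chemostat washes every state variable out at the dilution rate D:

    dM'/dt = K' · α(M', I) · B  −  D · M'  +  D · M_in

Rates α carry units h⁻¹·(mM B)⁻¹ scaled by their effector concentrations,
so α·B is mM·h⁻¹.  Light enters through the first macroscopic reaction as
a periodic irradiance signal I(t) (µE·m⁻²·s⁻¹).  Species declared clamped
(dissolved gases, minerals held non-limiting by the culture controller)
keep constant concentrations: their derivative rows are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .netio import NetworkError
from .reduction import ReducedModel

try:  # optional compiled fast path for the ODE right-hand side
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

LAW_FORMS = {
    # form: (n_effectors, n_parameters)
    "zero": (0, 0),
    "light-proportional": (0, 1),
    "mass-action-1": (1, 1),
    "reversible-mass-action": (2, 2),
    "product-2": (3, 2),
    "product-3": (3, 1),
}

CLIP_FLOOR = -1e-9
HARD_FLOOR = -1e-6


@dataclass
class KineticLaw:
    """Rate law of one macroscopic reaction.

    Forms
    -----
    zero
        identically 0 (futile maintenance cycles whose rate is not described)
    light-proportional
        k · I
    mass-action-1
        k · [E1]
    reversible-mass-action
        k · [E1] − k' · [E2]
    product-2
        k · [E1]·[E2] − k' · [E3]   (bimolecular forward, linear reverse)
    product-3
        k · [E1]·[E2]·[E3]
    """

    macro_reaction_id: str
    form: str
    effectors: list[str] = field(default_factory=list)
    parameters: list[float] = field(default_factory=list)
    parameter_names: list[str] = field(default_factory=list)
    units: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.form not in LAW_FORMS:
            raise NetworkError(f"unknown kinetic form {self.form!r}")
        n_eff, n_par = LAW_FORMS[self.form]
        if len(self.effectors) != n_eff or len(self.parameters) != n_par:
            raise NetworkError(
                f"law {self.macro_reaction_id!r} ({self.form}): expected "
                f"{n_eff} effectors / {n_par} parameters, got "
                f"{len(self.effectors)} / {len(self.parameters)}"
            )
        if any(p < 0 for p in self.parameters):
            raise NetworkError(f"law {self.macro_reaction_id!r}: negative rate constant")
        if not self.parameter_names:
            base = f"k_{self.macro_reaction_id}"
            self.parameter_names = [base, base.replace("k_", "k'_", 1)][: n_par]


@dataclass
class LightSignal:
    """Periodic irradiance forcing.

    ``truncated-sine`` ramps as I_max·sin(π·(t−phase)/day_length) inside the
    light window and is 0 outside; ``square`` is I_max inside the window;
    ``tabulated`` interpolates a measured (time, irradiance) profile
    periodically.
    """

    form: str = "truncated-sine"
    photoperiod: float = 24.0
    day_length: float = 12.0
    I_max: float = 100.0
    phase: float = 12.0
    table: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.day_length <= self.photoperiod:
            raise NetworkError("day_length must lie within the photoperiod")


@dataclass
class Environment:
    """Chemostat operating point: dilution rate (h⁻¹), inflow (mM), light."""

    dilution: float = 0.0
    inflow: dict[str, float] = field(default_factory=dict)
    light: LightSignal = field(default_factory=LightSignal)

    def __post_init__(self) -> None:
        if self.dilution < 0:
            raise NetworkError("dilution rate must be >= 0")
        if any(v < 0 for v in self.inflow.values()):
            raise NetworkError("inflow concentrations must be >= 0")


@dataclass
class Trajectory:
    """Time-indexed simulation output."""

    times: np.ndarray
    species: list[str]
    state: np.ndarray  # n_t x n_s
    macro_ids: list[str]
    alpha: np.ndarray  # n_t x n_E
    fluxes: np.ndarray | None = None  # n_t x n_r (original network)
    flux_ids: list[str] | None = None
    macro_fluxes_only: bool = False
    derived: dict[str, np.ndarray] = field(default_factory=dict)

    def series(self, sid: str) -> np.ndarray:
        if sid in self.species:
            return self.state[:, self.species.index(sid)]
        if sid in self.derived:
            return self.derived[sid]
        raise KeyError(sid)

    def to_dataframe(self):
        import pandas as pd

        data = {"time": self.times}
        for i, sid in enumerate(self.species):
            data[sid] = self.state[:, i]
        for j, mid in enumerate(self.macro_ids):
            data[f"alpha_{mid}"] = self.alpha[:, j]
        for name, arr in self.derived.items():
            data[name] = arr
        return pd.DataFrame(data)


def light_intensity(signal: LightSignal, t: float | np.ndarray):
    """Irradiance at time(s) *t* (hours); periodic and nonnegative."""
    tloc = np.mod(np.asarray(t, dtype=float) - signal.phase, signal.photoperiod)
    if signal.form == "square":
        out = np.where(tloc < signal.day_length, signal.I_max, 0.0)
    elif signal.form == "truncated-sine":
        out = np.where(
            tloc < signal.day_length,
            signal.I_max * np.maximum(0.0, np.sin(np.pi * tloc / max(signal.day_length, 1e-12))),
            0.0,
        )
    elif signal.form == "tabulated":
        if signal.table is None:
            raise NetworkError("tabulated light signal needs a table")
        tt, vv = signal.table
        out = np.interp(tloc, tt, vv)
    else:
        raise NetworkError(f"unknown light form {signal.form!r}")
    return float(out) if np.isscalar(t) else out


def _law_indices(model: ReducedModel, laws: list[KineticLaw]):
    """Precompute effector state indices per law for fast evaluation."""
    order = {mid: j for j, mid in enumerate(model.macro_ids)}
    if set(order) != {law.macro_reaction_id for law in laws}:
        raise NetworkError("kinetic laws do not match the model's macro reactions")
    compiled = []
    for law in sorted(laws, key=lambda l: order[l.macro_reaction_id]):
        idx = []
        for sid in law.effectors:
            if sid not in model.species:
                raise NetworkError(
                    f"law {law.macro_reaction_id!r}: effector {sid!r} not in model"
                )
            idx.append(model.species_index(sid))
        compiled.append((law.form, idx, list(law.parameters)))
    return compiled


def _eval_rates(compiled, state: np.ndarray, I: float) -> np.ndarray:
    alpha = np.empty(len(compiled))
    for j, (form, idx, p) in enumerate(compiled):
        if form == "zero":
            alpha[j] = 0.0
        elif form == "light-proportional":
            alpha[j] = p[0] * I
        elif form == "mass-action-1":
            alpha[j] = p[0] * state[idx[0]]
        elif form == "reversible-mass-action":
            alpha[j] = p[0] * state[idx[0]] - p[1] * state[idx[1]]
        elif form == "product-2":
            alpha[j] = p[0] * state[idx[0]] * state[idx[1]] - p[1] * state[idx[2]]
        else:  # product-3
            alpha[j] = p[0] * state[idx[0]] * state[idx[1]] * state[idx[2]]
    return alpha


def rate_vector(
    state: dict[str, float] | np.ndarray,
    I: float,
    laws: list[KineticLaw],
    model: ReducedModel | None = None,
) -> np.ndarray:
    """Evaluate the macroscopic rate vector α at one state.

    Accepts either a ``{species: concentration}`` map or a state vector
    aligned with *model*.  Reversible forms may return negative net rates;
    concentrations must be nonnegative.
    """
    if isinstance(state, dict):
        if any(v < 0 for v in state.values()):
            raise NetworkError("negative concentration in state")
        alpha = np.empty(len(laws))
        for j, law in enumerate(laws):
            vals = [state[s] for s in law.effectors]
            p = law.parameters
            if law.form == "zero":
                alpha[j] = 0.0
            elif law.form == "light-proportional":
                alpha[j] = p[0] * I
            elif law.form == "mass-action-1":
                alpha[j] = p[0] * vals[0]
            elif law.form == "reversible-mass-action":
                alpha[j] = p[0] * vals[0] - p[1] * vals[1]
            elif law.form == "product-2":
                alpha[j] = p[0] * vals[0] * vals[1] - p[1] * vals[2]
            else:
                alpha[j] = p[0] * vals[0] * vals[1] * vals[2]
        return alpha
    if model is None:
        raise NetworkError("vector state requires the model for alignment")
    if np.any(np.asarray(state) < HARD_FLOOR):
        raise NetworkError("negative concentration in state")
    return _eval_rates(_law_indices(model, laws), np.asarray(state, dtype=float), I)


_FORM_CODES = {
    "zero": 0,
    "light-proportional": 1,
    "mass-action-1": 2,
    "reversible-mass-action": 3,
    "product-2": 4,
    "product-3": 5,
}

if _HAVE_NUMBA:

    @_njit(cache=False)
    def _rhs_kernel(
        t, y, K, D, m_in, clamped, b_idx,
        forms, eff, par, light_form, photoperiod, day_length, I_max, phase,
    ):  # pragma: no cover - exercised through build_rhs
        tloc = (t - phase) % photoperiod
        I = 0.0
        if tloc < day_length:
            if light_form == 0:
                I = I_max
            else:
                s = np.sin(np.pi * tloc / day_length)
                I = I_max * s if s > 0.0 else 0.0
        n_s = y.shape[0]
        n_e = forms.shape[0]
        yc = np.empty(n_s)
        for i in range(n_s):
            yc[i] = y[i] if y[i] > 0.0 else 0.0
        alpha = np.empty(n_e)
        for j in range(n_e):
            f = forms[j]
            if f == 0:
                alpha[j] = 0.0
            elif f == 1:
                alpha[j] = par[j, 0] * I
            elif f == 2:
                alpha[j] = par[j, 0] * yc[eff[j, 0]]
            elif f == 3:
                alpha[j] = par[j, 0] * yc[eff[j, 0]] - par[j, 1] * yc[eff[j, 1]]
            elif f == 4:
                alpha[j] = (
                    par[j, 0] * yc[eff[j, 0]] * yc[eff[j, 1]]
                    - par[j, 1] * yc[eff[j, 2]]
                )
            else:
                alpha[j] = par[j, 0] * yc[eff[j, 0]] * yc[eff[j, 1]] * yc[eff[j, 2]]
        B = yc[b_idx]
        dy = np.empty(n_s)
        for i in range(n_s):
            acc = 0.0
            for j in range(n_e):
                acc += K[i, j] * alpha[j]
            dy[i] = acc * B - D * y[i] + D * m_in[i]
            if clamped[i]:
                dy[i] = 0.0
        return dy


def build_rhs(model: ReducedModel, laws: list[KineticLaw], env: Environment):
    """Compile the ODE right-hand side dM'/dt = K'αB − D·M' + D·M_in."""
    compiled = _law_indices(model, laws)
    K = model.K_prime
    n_s = len(model.species)
    b_idx = model.species_index(model.biomass)
    D = env.dilution
    m_in = np.zeros(n_s)
    for sid, c in env.inflow.items():
        if sid in model.species:
            m_in[model.species_index(sid)] = c
    clamped_mask = np.array([sid in model.clamped for sid in model.species])
    light = env.light

    if _HAVE_NUMBA and light.form in ("square", "truncated-sine"):
        n_e = len(compiled)
        forms = np.array([_FORM_CODES[f] for f, _, _ in compiled], dtype=np.int64)
        eff = np.zeros((n_e, 3), dtype=np.int64)
        par = np.zeros((n_e, 2))
        for j, (_, idx, p) in enumerate(compiled):
            for k, i in enumerate(idx):
                eff[j, k] = i
            for k, v in enumerate(p):
                par[j, k] = v
        light_form = 0 if light.form == "square" else 1
        Kc = np.ascontiguousarray(K)
        clamped_arr = clamped_mask.astype(np.bool_)

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            if y.shape[0] != n_s:
                raise NetworkError("state dimension does not match model")
            return _rhs_kernel(
                float(t), y, Kc, D, m_in, clamped_arr, b_idx,
                forms, eff, par, light_form, light.photoperiod,
                light.day_length, light.I_max, light.phase,
            )

        return rhs

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        if y.shape[0] != n_s:
            raise NetworkError("state dimension does not match model")
        I = light_intensity(light, float(t))
        yc = np.maximum(y, 0.0)  # guard against solver micro-undershoot
        alpha = _eval_rates(compiled, yc, I)
        dy = K @ alpha * yc[b_idx] - D * y + D * m_in
        dy[clamped_mask] = 0.0
        return dy

    return rhs


def ode_rhs(
    t: float,
    state: np.ndarray,
    model: ReducedModel,
    laws: list[KineticLaw],
    env: Environment,
) -> np.ndarray:
    """One-shot RHS evaluation (convenience wrapper over :func:`build_rhs`)."""
    return build_rhs(model, laws, env)(t, np.asarray(state, dtype=float))


def integrate(
    model: ReducedModel,
    laws: list[KineticLaw],
    env: Environment,
    t_span: tuple[float, float],
    initial_state: dict[str, float] | np.ndarray,
    grid: np.ndarray | int = 400,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    solver_options: dict | None = None,
    max_rhs_calls: int | None = None,
) -> Trajectory:
    """Integrate the reduced kinetic model and record state + rates.

    Nonnegativity is enforced by clipping post-step undershoot at −1e−9; a
    state below −1e−6 raises (the reversible laws arrest depletion, so the
    clip is a safety net, not a model feature).  *max_rhs_calls* bounds the
    solver's work and raises when exceeded — calibration uses it to abort
    pathological parameter sets instead of grinding at a vanishing step.
    """
    if isinstance(initial_state, dict):
        y0 = np.zeros(len(model.species))
        for sid, v in initial_state.items():
            y0[model.species_index(sid)] = v
    else:
        y0 = np.asarray(initial_state, dtype=float).copy()
    if np.any(y0 < 0):
        raise NetworkError("initial state must be nonnegative")
    t_eval = np.linspace(*t_span, grid) if isinstance(grid, int) else np.asarray(grid)
    rhs = build_rhs(model, laws, env)
    if max_rhs_calls is not None:
        inner = rhs
        counter = [0]

        def rhs(t, y):
            counter[0] += 1
            if counter[0] > max_rhs_calls:
                raise RuntimeError(
                    f"integration exceeded {max_rhs_calls} RHS evaluations at t={t:.4f}"
                )
            return inner(t, y)

    sol = solve_ivp(
        rhs, t_span, y0, t_eval=t_eval, method=method, rtol=rtol, atol=atol,
        **(solver_options or {}),
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed at t={sol.t[-1] if sol.t.size else t_span[0]}: {sol.message}")
    state = sol.y.T
    if np.min(state) < HARD_FLOOR:
        worst = np.unravel_index(np.argmin(state), state.shape)
        raise RuntimeError(
            f"state went below {HARD_FLOOR} ({model.species[worst[1]]} at "
            f"t={sol.t[worst[0]]:.3f})"
        )
    state = np.maximum(state, 0.0)
    compiled = _law_indices(model, laws)
    alpha = np.vstack(
        [
            _eval_rates(compiled, state[i], light_intensity(env.light, float(t)))
            for i, t in enumerate(sol.t)
        ]
    )
    return Trajectory(
        times=sol.t,
        species=list(model.species),
        state=state,
        macro_ids=list(model.macro_ids),
        alpha=alpha,
    )


def reconstruct_fluxes(traj: Trajectory, model: ReducedModel, efms: dict | None):
    """Map macroscopic rates back onto the original network: v(t) = Σ E_SN α_SN.

    Requires per-sub-network EFM provenance; when the model was built
    directly from already-macroscopic reactions (no provenance), the macro
    rates themselves are returned and the trajectory is flagged
    ``macro_fluxes_only``.
    """
    have_provenance = efms is not None and all(
        m.source is not None and m.source[0] in efms for m in model.macro_reactions
    )
    if not have_provenance:
        traj.fluxes = traj.alpha.copy()
        traj.flux_ids = list(model.macro_ids)
        traj.macro_fluxes_only = True
        return traj
    rid_order: list[str] = []
    for E in efms.values():
        for rid in E.reaction_ids:
            if rid not in rid_order:
                rid_order.append(rid)
    idx = {rid: i for i, rid in enumerate(rid_order)}
    v = np.zeros((traj.times.size, len(rid_order)))
    for j, m in enumerate(model.macro_reactions):
        sn, col = m.source
        E = efms[sn]
        mode = E.modes[:, col]
        for rid, x in zip(E.reaction_ids, mode):
            # duplicated reactions accumulate contributions from every
            # sub-network that carries them
            v[:, idx[rid]] += x * traj.alpha[:, j]
    traj.fluxes = v
    traj.flux_ids = rid_order
    traj.macro_fluxes_only = False
    return traj


def total_biomass(
    traj: Trajectory,
    compositions: dict[str, dict[str, float]],
    chl_fraction: float,
    accumulating: set[str],
    biomass: str = "B",
) -> Trajectory:
    """Elemental totals: X_Z(t) = Σ_A Z_A·A(t) + Z_B·B(t); chlorophyll as a
    fixed fraction of functional biomass.  Energy cofactors are outside the
    model and contribute nothing."""
    for sid in sorted(accumulating | {biomass}):
        if sid not in compositions:
            raise NetworkError(f"missing composition for species {sid!r}")
    for element, key in (("C", "X_C"), ("N", "X_N")):
        total = np.zeros_like(traj.times)
        for sid in sorted(accumulating | {biomass}):
            count = compositions[sid].get(element, 0.0)
            if count:
                total = total + count * traj.series(sid)
        traj.derived[key] = total
    traj.derived["chlorophyll"] = chl_fraction * traj.series(biomass)
    return traj


def carbon_diagnostics(
    traj: Trajectory,
    model: ReducedModel,
    t: float,
    sinks: tuple[str, ...] = ("B", "CARB", "PA"),
    co2_id: str = "CO2",
    o2_id: str = "O2",
) -> dict:
    """Carbon allocation shares across sinks and the photosynthetic quotient.

    The share of sink s is the carbon flux into s (its composition carbon
    times its net production rate, counting only producing reactions —
    negative net rates are zero inflow), normalized so shares sum to 1.
    PQ = net O₂ production / net CO₂ fixation read off the K' rows.
    """
    i_t = int(np.argmin(np.abs(traj.times - t)))
    alpha = traj.alpha[i_t]
    K = model.K_prime
    inflows = {}
    for sid in sinks:
        row = K[model.species_index(sid)]
        carbon = model.compositions.get(sid, {}).get("C", 0.0)
        inflows[sid] = carbon * float(np.sum(np.maximum(row * alpha, 0.0)))
    total = sum(inflows.values())
    if total <= 0:
        shares = {sid: float("nan") for sid in sinks}
        undefined = True
    else:
        shares = {sid: v / total for sid, v in inflows.items()}
        undefined = False
    o2_prod = float(K[model.species_index(o2_id)] @ alpha)
    co2_fix = float(-(K[model.species_index(co2_id)] @ alpha))
    pq = o2_prod / co2_fix if co2_fix != 0 else float("nan")
    return {
        "time": float(traj.times[i_t]),
        "shares": shares,
        "shares_undefined": undefined,
        "photosynthetic_quotient": pq,
        "o2_production": o2_prod,
        "co2_fixation": co2_fix,
    }
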