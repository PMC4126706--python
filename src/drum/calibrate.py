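"""Rate-constant calibration by multistart Nelder–Mead.

The objective is a weighted sum of squared residuals between simulated and
observed series.  Mixed-unit observables (particulate carbon, nitrogen,
chlorophyll, pool concentrations) are made commensurate by the default
weighting w_o = 1/max(obs_o)², which normalizes each series to unit scale.

The search runs in log-parameter space, which enforces positivity without
constrained optimization and suits rate constants spread over many orders
of magnitude.  A pool of candidate points is screened by objective value,
the best are polished by Nelder–Mead, and the top polished results are
driven to the bottom of their basins by a trust-region least-squares pass
(the simplex stalls in the long sloppy valleys these kinetic models have
when fast buffer pools are unobserved).  Practical identifiability is
screened by ±5% profile likelihood; flat directions are reported, not
hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, minimize

from .netio import NetworkError
from .reduction import ReducedModel
from .simulate import Environment, KineticLaw, integrate, total_biomass

DERIVED_OBSERVABLES = ("X_C", "X_N", "chlorophyll")


@dataclass
class ObservationTable:
    """Observed time series and how each maps onto the model."""

    times: np.ndarray
    observables: dict[str, np.ndarray]
    #: observable name -> model expression (species id or derived quantity);
    #: identity by default
    mapping: dict[str, str] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not self.observables:
            raise NetworkError("observation table needs at least one observable")
        for name, series in self.observables.items():
            self.observables[name] = np.asarray(series, dtype=float)
            if self.observables[name].shape != self.times.shape:
                raise NetworkError(f"observable {name!r} length mismatch")
        for name in self.observables:
            self.mapping.setdefault(name, name)
        for name, series in self.observables.items():
            if name not in self.weights:
                peak = float(np.max(np.abs(series)))
                self.weights[name] = 1.0 / peak**2 if peak > 0 else 1.0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, **self.observables})

    @classmethod
    def from_csv(cls, path: str, **kwargs) -> "ObservationTable":
        import pandas as pd

        df = pd.read_csv(path)
        obs = {c: df[c].to_numpy() for c in df.columns if c != "time"}
        return cls(times=df["time"].to_numpy(), observables=obs, **kwargs)

    def signal_energy(self) -> float:
        """Weighted energy Σ_o w_o Σ_k obs_o(t_k)² (perfect-fit yardstick)."""
        return float(
            sum(self.weights[o] * np.sum(s**2) for o, s in self.observables.items())
        )


@dataclass
class FitResult:
    best_params: np.ndarray
    objective: float
    parameter_names: list[str]
    starts: list[dict]
    seed: int
    flat_directions: list[str] = field(default_factory=list)

    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.parameter_names, self.best_params))


def free_parameter_names(laws: list[KineticLaw]) -> list[str]:
    names = []
    for law in laws:
        if law.form == "zero":
            continue
        names.extend(law.parameter_names)
    return names


def count_free_parameters(laws: list[KineticLaw]) -> int:
    """Degrees of freedom of the kinetic model (zero-form laws carry none)."""
    return sum(len(law.parameters) for law in laws if law.form != "zero")


def get_parameter_vector(laws: list[KineticLaw]) -> np.ndarray:
    return np.array(
        [p for law in laws if law.form != "zero" for p in law.parameters]
    )


def set_parameter_vector(laws: list[KineticLaw], vec: np.ndarray) -> list[KineticLaw]:
    """New law list with free rate constants replaced by *vec* (in order)."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != count_free_parameters(laws):
        raise NetworkError("parameter vector length mismatch")
    out, k = [], 0
    for law in laws:
        if law.form == "zero":
            out.append(law)
            continue
        n = len(law.parameters)
        out.append(replace(law, parameters=list(vec[k : k + n])))
        k += n
    return out


def residual_vector(
    params: np.ndarray,
    model: ReducedModel,
    laws: list[KineticLaw],
    env: Environment,
    obs: ObservationTable,
    initial_state,
    rtol: float = 1e-6,
    chl_fraction: float | None = None,
) -> np.ndarray:
    """Weighted residuals √w_o·(sim_o(t_k) − obs_o(t_k)); the objective is the
    sum of their squares.  Solver failure returns a large constant vector."""
    n_res = sum(s.size for s in obs.observables.values())
    params = np.asarray(params, dtype=float)
    try:
        trial = set_parameter_vector(laws, params)
        t_end = float(obs.times[-1])
        traj = integrate(
            model, trial, env, (0.0, t_end), initial_state, grid=obs.times,
            rtol=rtol, atol=1e-9, solver_options={"min_step": 1e-7},
            max_rhs_calls=40_000,
        )
        if chl_fraction is not None or any(
            obs.mapping[o] in DERIVED_OBSERVABLES for o in obs.observables
        ):
            total_biomass(
                traj, model.compositions, chl_fraction or 0.0,
                accumulating=model.accumulating, biomass=model.biomass,
            )
    except (RuntimeError, FloatingPointError):
        return np.full(n_res, 1e6)
    out = []
    for name, series in obs.observables.items():
        sim = traj.series(obs.mapping[name])
        out.append(np.sqrt(obs.weights[name]) * (sim - series))
    return np.concatenate(out)


def objective(
    params: np.ndarray,
    model: ReducedModel,
    laws: list[KineticLaw],
    env: Environment,
    obs: ObservationTable,
    initial_state,
    rtol: float = 1e-6,
    chl_fraction: float | None = None,
) -> float:
    """Weighted squared error Σ_o w_o Σ_k (sim_o(t_k) − obs_o(t_k))².

    Simulation failure (solver breakdown under a pathological parameter
    set) returns +inf so the optimizer simply steps away.
    """
    params = np.asarray(params, dtype=float)
    if np.any(params < 0):
        raise NetworkError("rate constants must be nonnegative")
    for name in obs.observables:
        expr = obs.mapping[name]
        if expr not in DERIVED_OBSERVABLES and expr not in model.species:
            raise NetworkError(f"observable {name!r} maps to unknown expression {expr!r}")
    try:
        trial = set_parameter_vector(laws, params)
        t_end = float(obs.times[-1])
        # a strictly positive min_step makes hopeless (very stiff) parameter
        # sets fail fast instead of grinding the step size to nothing
        traj = integrate(
            model, trial, env, (0.0, t_end), initial_state, grid=obs.times,
            rtol=rtol, atol=1e-9, solver_options={"min_step": 1e-7},
            max_rhs_calls=40_000,
        )
        if chl_fraction is not None or any(
            obs.mapping[o] in DERIVED_OBSERVABLES for o in obs.observables
        ):
            total_biomass(
                traj, model.compositions, chl_fraction or 0.0,
                accumulating=model.accumulating, biomass=model.biomass,
            )
    except (RuntimeError, FloatingPointError):
        return float("inf")
    total = 0.0
    for name, series in obs.observables.items():
        sim = traj.series(obs.mapping[name])
        total += obs.weights[name] * float(np.sum((sim - series) ** 2))
    return total


def fit(
    model: ReducedModel,
    laws: list[KineticLaw],
    env: Environment,
    obs: ObservationTable,
    initial_state,
    n_starts: int = 20,
    seed: int = 0,
    bounds: np.ndarray | None = None,
    maxiter: int = 2000,
    explore_maxiter: int | None = None,
    screen_factor: int = 10,
    n_polish_restarts: int = 1,
    refine: bool = True,
    refine_top: int = 3,
    profile_identifiability: bool = False,
    rtol: float = 1e-6,
    chl_fraction: float | None = None,
) -> FitResult:
    """Multistart Nelder-Mead fit of the free rate constants (log space).

    ``screen_factor * n_starts`` candidate points are drawn log-uniformly
    inside *bounds* (an (n,2) array of positive lows/highs; default:
    current values x/÷ 100) from a generator seeded with *seed*; the
    *n_starts* best-scoring candidates are polished by Nelder-Mead.  The
    log parameterization enforces positivity by construction.  Because the
    simplex stalls in the long sloppy valleys these kinetic problems have,
    the top *refine_top* polished results are then driven to the bottom of
    their basins by a trust-region least-squares pass on the residual
    vector (*refine*), and the incumbent best wins.  Fully reproducible
    given *seed*.

    With *profile_identifiability*, each parameter is profiled at ±5%
    (re-optimizing all others): parameters whose profile objective stays
    at the fit's noise floor are reported in ``flat_directions`` —
    observationally flat combinations are reported, never hidden.
    """
    if n_starts < 1:
        raise NetworkError("n_starts must be >= 1")
    names = free_parameter_names(laws)
    n_par = len(names)
    p0 = get_parameter_vector(laws)
    if bounds is None:
        bounds = np.column_stack([p0 / 100.0, p0 * 100.0])
    bounds = np.asarray(bounds, dtype=float)
    if bounds.size == 0 or bounds.shape != (n_par, 2):
        raise NetworkError("bounds must be an (n_parameters, 2) array")
    if np.any(bounds <= 0):
        raise NetworkError("bounds must be strictly positive (log-space search)")
    log_lo, log_hi = np.log(bounds[:, 0]), np.log(bounds[:, 1])

    def f_log(x: np.ndarray) -> float:
        return objective(
            np.exp(x), model, laws, env, obs, initial_state, rtol=rtol,
            chl_fraction=chl_fraction,
        )

    def r_log(x: np.ndarray, free=None, fixed_vals=None) -> np.ndarray:
        if free is not None:
            full = fixed_vals.copy()
            full[free] = x
            x = full
        return residual_vector(
            np.exp(x), model, laws, env, obs, initial_state,
            rtol=min(rtol, 1e-7), chl_fraction=chl_fraction,
        )

    rng = np.random.default_rng(seed)
    n_cand = max(1, screen_factor) * n_starts
    candidates = rng.uniform(log_lo, log_hi, size=(n_cand, n_par))
    scores = np.array([f_log(x) for x in candidates])
    order = np.argsort(scores)[:n_starts]
    explore = maxiter if explore_maxiter is None else explore_maxiter

    per_start: list[dict] = []
    polished: list[tuple[float, np.ndarray]] = []
    for i in order:
        x0, f0 = candidates[i], float(scores[i])
        if explore > 0 and np.isfinite(f0):
            res = minimize(
                f_log, x0, method="Nelder-Mead",
                options={"maxiter": explore, "maxfev": 2 * explore,
                         "fatol": 1e-8, "xatol": 1e-8},
            )
            xs, fs, conv = res.x, float(res.fun), bool(res.success)
        else:
            # an infeasible start (solver failure everywhere nearby) is
            # recorded but not polished: the simplex cannot descend on +inf
            xs, fs, conv = x0, f0, False
        per_start.append(
            {
                "initial_params": np.exp(x0),
                "final_params": np.exp(xs),
                "objective": fs,
                "converged": conv,
            }
        )
        if np.isfinite(fs):
            polished.append((fs, np.asarray(xs)))
    if not polished:
        # every start infeasible: report the least-bad candidate unpolished
        j = int(np.argmin(scores))
        return FitResult(
            best_params=np.exp(candidates[j]),
            objective=float(scores[j]),
            parameter_names=names,
            starts=per_start,
            seed=seed,
        )
    polished.sort(key=lambda z: z[0])
    best_f, best_x = polished[0]

    if refine:
        for fs, xs in polished[: max(1, refine_top)]:
            ls = least_squares(
                r_log, xs, method="lm", xtol=1e-12, ftol=1e-14,
                max_nfev=500, diff_step=1e-2,
            )
            if 2 * float(ls.cost) < best_f:
                best_x, best_f = ls.x, 2 * float(ls.cost)
    else:
        for _ in range(n_polish_restarts):
            res = minimize(
                f_log, best_x, method="Nelder-Mead",
                options={"maxiter": maxiter, "maxfev": 2 * maxiter,
                         "fatol": 1e-10, "xatol": 1e-10},
            )
            improved = float(res.fun) < best_f - 1e-15
            if float(res.fun) <= best_f:
                best_x, best_f = res.x, float(res.fun)
            if not improved:
                break
    best_x = np.asarray(best_x)

    flat: list[str] = []
    if profile_identifiability:
        # noise floor: residuals below 0.01% RMS of each (unit-scaled)
        # series are beyond any real measurement precision
        floor = max(10 * best_f, 1e-8 * obs.signal_energy())
        step = np.log(1.05)
        for i, name in enumerate(names):
            distinguishable = False
            for sign in (+1, -1):
                fixed = best_x.copy()
                fixed[i] += sign * step
                free = [j for j in range(n_par) if j != i]
                prof = least_squares(
                    r_log, fixed[free], method="lm", xtol=1e-10, ftol=1e-12,
                    max_nfev=40 * n_par, diff_step=1e-2,
                    kwargs={"free": free, "fixed_vals": fixed},
                )
                if 2 * float(prof.cost) > floor:
                    distinguishable = True
                    break
            if not distinguishable:
                flat.append(name)

    return FitResult(
        best_params=np.exp(best_x),
        objective=best_f,
        parameter_names=names,
        starts=per_start,
        seed=seed,
        flat_directions=flat,
    )


def average_duplicates(tables: list[ObservationTable]) -> ObservationTable:
    """Average replicate cultures sampled on a common time grid."""
    if not tables:
        raise NetworkError("no tables to average")
    t0 = tables[0].times
    for t in tables[1:]:
        if not np.array_equal(t.times, t0):
            raise NetworkError("replicates must share the time grid")
    names = tables[0].observables.keys()
    merged = {
        n: np.mean([t.observables[n] for t in tables], axis=0) for n in names
    }
    return ObservationTable(times=t0.copy(), observables=merged,
                            mapping=dict(tables[0].mapping))
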