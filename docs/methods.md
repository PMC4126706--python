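# Methods

## The modeling problem

Balanced-growth (quasi-steady-state) metabolic models assume every internal
metabolite pool is constant, which fails for organisms whose metabolism is
driven by a periodic environment.  Photoautotrophic microalgae under a
day/night cycle are the canonical case: carbon fixed by day is parked in
carbohydrate and neutral-lipid pools and burned at night to keep growth and
maintenance running, so the storage pools — and a handful of central
branching-point metabolites — are anything but steady.

This package implements a reduction strategy for that regime.  The
quasi-steady-state assumption is applied *locally*: the network is split into
sub-networks (reaction groups sharing a compartment, a regulation unit or a
metabolic function; a reaction may belong to several groups, which duplicates
its column).  Within each sub-network the internal metabolites are balanced,
so every admissible flux is a nonnegative combination of that sub-network's
elementary flux modes (EFMs).  Multiplying the sub-network stoichiometry by
one mode gives a *macroscopic reaction* over the boundary species only.  The
metabolites linking sub-networks (set A) plus functional biomass B are exempt
from the balance constraint and carry the dynamics:

    dM'/dt = K'·α(M', I)·B − D·M' + D·M_in

with K' the reduced stoichiometric matrix, α the macroscopic rate vector,
D the chemostat dilution rate and M_in the inflow concentrations.  Functional
biomass multiplies every rate because the catalytic machinery (proteins,
nucleic acids, chlorophyll, membrane lipids) scales with it; storage pools
have no catalytic role.  Once α is known, all original-network fluxes follow
as v = Σ E_SN α_SN.

Total (measured) biomass differs from B: element Z in particulate matter is
X_Z = Σ_A Z_A·A + Z_B·B, summed over the storage/buffer pools and functional
biomass.  Energy cofactors are excluded (their fate is deliberately not
modeled); their rows are dropped from K'.

## EFM enumeration

Enumeration is a Schuster-style double-description tableau on the
reversibility-split network: start from the basis rays of the nonnegative
orthant, impose one internal-species balance at a time, combine
positive/negative residual rays, and keep a combination only if no third
ray's support is contained in its union support.  Arithmetic is exact
(`fractions.Fraction`), so no mode is lost or fabricated by floating-point
tolerance; floats appear only on output.  Spurious 2-cycles from splitting a
reversible reaction are removed; genuine futile cycles spanning two or more
distinct reactions are kept.  Columns are normalized by their
smallest-magnitude coefficient and ordered lexicographically by support,
positive orientation first, making the output deterministic and independent
of reaction declaration order.  A warning fires above 10,000 modes —
the algorithm targets sub-network scale, not genome scale.

The test suite certifies the engine against an independent brute-force
oracle (exhaustive support enumeration with sympy nullspaces: a support is
elementary iff its restricted nullspace is one-dimensional with a strictly
signed generator) on hand-verified toys and a seeded random corpus up to 10
reactions.

## The packaged worked example

The shipped model is an eight-reaction reduction of the core carbon
metabolism of the microalga *Tisochrysis lutea*: photosynthesis (MR1, one
mode: 30 photons + 3 CO₂ → GAP + 3 O₂, i.e. a 10-photon quota per carbon),
an ATP-dissipating futile cycle (MR2, rate held at zero), upper glycolysis
forward and backward (MR3/MR4, distinct because of the
fructose-bisphosphate irreversibilities), lower glycolysis (MR5),
carbohydrate storage (MR6), lipid storage as an average phosphatidic acid
(MR7) and biomass synthesis (MR8, the best-PEP/CO₂-yield mode of its
sub-network, normalized per unit biomass flux).  GAP, G6P and PEP are the
accumulating branching-point buffers; CARB and PA the storage pools.

Kinetics are deliberately minimal — one or two constants per reaction
(light-proportional, mass action, reversible mass action, and products of
two or three effector concentrations) — ten free parameters in all.
Units: concentrations in mM, B in mM functional biomass, time in hours,
light in µE·m⁻²·s⁻¹; each rate constant is per mM B so α·B is mM·h⁻¹.

Elemental bookkeeping closes the composition table at build time: carbon
counts of the small species are known (GAP/PEP 3, G6P/CARB 6, CO₂ 1);
the lipid carbon count (36.22) follows by zeroing the carbon residual of
MR7, then the functional-biomass carbon (8.5442) from MR8, and its
nitrogen (1.31) from the nitrate coefficient.  With these, every
macroscopic column is carbon-balanced to the 2-decimal printing precision
of its coefficients, which is why a closed-system simulation conserves
total carbon to solver precision.  Carbon retention of biomass synthesis,
C_B / (3.13·3 + 1.14·6 + 0.11·C_PA), evaluates to 42.27% — the remainder
is respired to cover the ATP demand of biosynthesis.

### Environment defaults

The chemostat operating point is D = 1 d⁻¹ with inflow nitrogen
4.018 mgN·L⁻¹, converted at 14 g·mol⁻¹ atomic nitrogen to 0.287 mM NO₃
(the conversion basis is atomic N, a documented interpretation).  Dissolved
gases, phosphate, sulfate and magnesium are clamped (held non-limiting, as
in a pH/CO₂-controlled culture); nitrate is dynamic.

Light forcing is a synthetic truncated sine: 24 h period, 12 h photophase,
sunrise at clock hour 12 so midday falls at hour 18.  The default peak is
**300 µE·m⁻²·s⁻¹**.  This value matters: at this dilution rate the culture
must fix enough carbon per day to outgrow washout, and below roughly
150–200 µE·m⁻²·s⁻¹ peak the model's only attractor is the washed-out state
(B → 0).  At 300 the model settles on a nitrogen-limited periodic orbit
(B ≈ 0.218 mM, pinned by inflow nitrogen over the biomass nitrogen quota)
with the qualitative phenotype the model is known for: storage minima
shortly after dawn, maxima one to three hours before dusk, and a diurnal
photosynthetic quotient within the algal 1.0–1.8 band.

Initial conditions default to small positive pools (0.01 mM each), 0.1 mM
functional biomass and inflow-level nitrate; periodic-regime analyses
discard a 10–20 cycle start-up transient (convergence is exponential:
cycle-to-cycle differences fall below 1e-5 by cycle 10 and 1e-8 by
cycle 20).

### Diagnostics

Carbon allocation shares at time t are the carbon fluxes into each sink
(functional biomass, carbohydrates, lipids): composition carbon × positive
net production rate, normalized to sum one; net-consuming (negative) rates
count as zero inflow.  The photosynthetic quotient is net O₂ production
over net CO₂ fixation read off the corresponding rows of K'.  The
instantaneous quotient is singular where net fixation crosses zero at dawn
and dusk (a ratio of two vanishing fluxes), so the reported diurnal range
is evaluated where irradiance exceeds a quarter of its peak; any threshold
between ~0.2 and 0.6 gives the same band.

## Synthetic observations

The generator emulates chemostat monitoring of a day/night culture: it
forward-simulates past the transient and samples particulate carbon and
nitrogen, chlorophyll (a fixed fraction of functional biomass, default
0.02 — the ratio is a free fixture parameter), carbohydrates, neutral
lipids, functional biomass and nitrate, by default every 2 h over two
cycles.  Independent Gaussian noise with standard deviation `noise_sd ×
range` per observable (default 5%) is added from a seeded generator, so a
dataset is bit-reproducible from (parameters, environment, noise, seed).

What the generator does **not** emulate: replicate-culture variability,
irregular sampling, instrument-specific error structure (multiplicative,
detection limits), or the real measured light profile.  Passing tests on
these data certify the machinery — reduction, simulation, calibration —
not the model's fit to any real culture.

## Calibration

The objective is Σ_o w_o Σ_k (sim_o(t_k) − obs_o(t_k))² with default
weights w_o = 1/max|obs_o|², which puts mixed-unit series on a common
scale.  The search works on log parameters (positivity by construction;
the constants span seven orders of magnitude).  Protocol: draw
`screen_factor × n_starts` candidates log-uniformly inside the bounds,
keep the `n_starts` best by objective value, polish each by Nelder–Mead
(simplex and value tolerances 1e-8, exploration capped at 250–2000
iterations), then drive the top few polished results to the bottoms of
their basins with a trust-region least-squares pass on the residual
vector.  The last step exists because the model has long, curved, nearly
flat valleys — the buffer pools GAP/G6P/PEP are not observed, so the rate
constants that only set their (fast) quasi-equilibrium scale are
constrained weakly — and a simplex stalls there.  Integration failures
under pathological parameter sets return +inf (with a floor on the solver
step and a cap on its work so they fail fast rather than grind).

Practical identifiability is assessed by ±5% profile likelihood: fix one
parameter 5% off the optimum, re-optimize all others, and compare the
profiled objective with a floor set by the larger of ten times the
achieved optimum and 1e-8 of the weighted signal energy.  Parameters whose
profiles stay below the floor are reported as flat directions.  On
noiseless synthetic data from the packaged parameter vector this screen
flags exactly the expected structure: k_MR3, k_MR5 and k_MR7 can drift by
large common factors (shrinking the invisible buffer pools in
compensation) while every distinguishable constant is recovered within a
few percent.  This mirrors why reported constants of such models should
be read as one representative point of a plausible set, not as uniquely
determined values.

## Numerical choices

- Integration: LSODA, rtol 1e-8 / atol 1e-10 for analysis runs, relaxed to
  1e-6/1e-9 inside calibration loops.  A compiled (numba) right-hand side
  is used when available, with a pure-numpy fallback of identical
  semantics.
- Nonnegativity: reversible laws arrest depletion on their own; post-step
  undershoot is clipped at −1e-9 and anything below −1e-6 is an error.
- Elemental balance tolerance: 0.05 per element per reaction (tabulated
  coefficients carry two decimals, so exact closure is impossible).  H and
  O are not audited by default — proton and water bookkeeping in lumped
  reactions is unreliable.  Photons are a non-material pseudo-species,
  excluded from all balances.
- Reversible macro-reaction pairs merge only when their stoichiometries
  are exact negatives within 1e-9 after normalization; a config can also
  declare reversibility outright.  The packaged fixture takes the declared
  route (the packaged reaction table declares which entries are reversible).
- Ties in best-yield mode selection break toward smaller byproduct
  formation, then the lowest canonical index.

## Limitations

- The partition into sub-networks is user-supplied; no automatic splitting
  (flux coupling, topological clustering) is attempted.
- Enumeration is exact rational double description and is not intended for
  genome-scale networks (the guard at 10,000 modes is advisory).
- MR1 has no light saturation or photoinhibition and no CO₂ dependence, so
  closed-bottle scenarios must provide enough dissolved carbon to stay
  physical.
- The kinetic layer supports the six law forms above; arbitrary rate
  expressions would need a new form.
- Chlorophyll is a fixed proportion of functional biomass by construction;
  photoacclimation is out of scope.
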