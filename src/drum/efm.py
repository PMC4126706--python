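"""Elementary flux mode enumeration and selection.

An elementary flux mode (EFM) of a network with internal-species
stoichiometry ``K_C`` is a support-minimal flux vector ``v`` with
``K_C v = 0``, ``v_j >= 0`` on irreversible reactions.  Any admissible
steady-state flux distribution is a nonnegative combination of EFMs, which
is what makes them the natural unit for reducing a balanced sub-network to
macroscopic reactions.

Enumeration uses a Schuster-style double-description tableau on the
reversibility-split network, with exact rational arithmetic so that no
mode is lost or fabricated by floating-point tolerance; results are
converted to floats only on output.  This is adequate for the sub-network
scale the reduction workflow targets (tens of reactions); a guard warns
when the mode count explodes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .netio import Network, NetworkError, Reaction, stoichiometric_matrix

EFM_COUNT_WARN = 10_000


@dataclass
class EfmMatrix:
    """Columns of elementary modes over a network's reactions (signed fluxes)."""

    modes: np.ndarray  # n_r x n_E
    reaction_ids: list[str]
    reversibility: list[bool]
    normalization: str = "smallest-coefficient"

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def support(self, j: int) -> frozenset[str]:
        return frozenset(
            rid for rid, x in zip(self.reaction_ids, self.modes[:, j]) if x != 0
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.modes,
            index=self.reaction_ids,
            columns=[f"EFM{j + 1}" for j in range(self.n_modes)],
        )


@dataclass
class YieldTable:
    """Per-mode (numerator consumption, denominator production) ratios,
    normalized to unit flux of a reference reaction."""

    ratios: dict[int, tuple[float, float]] = field(default_factory=dict)
    numerator: str = ""
    denominator: str = ""
    reference: str = ""


def split_reversible(net: Network) -> tuple[Network, dict[str, tuple[str, str | None]]]:
    """Replace each reversible reaction by opposed irreversible forward/backward
    columns.  Returns the split network and ``{orig_id: (fwd_id, bwd_id|None)}``."""
    reactions: list[Reaction] = []
    mapping: dict[str, tuple[str, str | None]] = {}
    for r in net.reactions:
        if r.reversible:
            fwd = Reaction(id=f"{r.id}__f", stoich=dict(r.stoich), reversible=False)
            bwd = Reaction(
                id=f"{r.id}__b",
                stoich={sid: -c for sid, c in r.stoich.items()},
                reversible=False,
            )
            reactions.extend([fwd, bwd])
            mapping[r.id] = (fwd.id, bwd.id)
        else:
            reactions.append(Reaction(id=r.id, stoich=dict(r.stoich), reversible=False))
            mapping[r.id] = (r.id, None)
    return Network(species=list(net.species), reactions=reactions), mapping


def _rational_matrix(K: np.ndarray) -> list[list[Fraction]]:
    return [[Fraction(x).limit_denominator(10**12) for x in row] for row in K]


def _enumerate_rays(K: list[list[Fraction]], n_r: int) -> list[list[Fraction]]:
    """Double-description tableau: rays of {v >= 0 : K v = 0}.

    Starts from the standard basis of the nonnegative orthant and imposes
    the balance constraints one internal species at a time, combining
    positive/negative rays and discarding non-extreme (support-dominated)
    combinations.
    """
    rays: list[list[Fraction]] = [
        [Fraction(int(i == j)) for j in range(n_r)] for i in range(n_r)
    ]
    residuals: list[list[Fraction]] = [
        [K[m][i] for m in range(len(K))] for i in range(n_r)
    ]
    supports: list[int] = [1 << i for i in range(n_r)]

    for m in range(len(K)):
        zero, pos, neg = [], [], []
        for idx in range(len(rays)):
            r = residuals[idx][m]
            (zero if r == 0 else pos if r > 0 else neg).append(idx)
        new_rays: list[list[Fraction]] = [rays[i] for i in zero]
        new_res: list[list[Fraction]] = [residuals[i] for i in zero]
        new_sup: list[int] = [supports[i] for i in zero]
        seen_new: set[tuple] = set()
        for ip, ineg in itertools.product(pos, neg):
            sup = supports[ip] | supports[ineg]
            # extremality (Schuster test): the pair combines to an extreme ray
            # iff no third ray's support is contained in the union support
            dominated = any(
                supports[k] | sup == sup
                for k in range(len(rays))
                if k != ip and k != ineg
            )
            if dominated:
                continue
            a = residuals[ip][m]
            b = -residuals[ineg][m]
            ray = [b * rays[ip][j] + a * rays[ineg][j] for j in range(n_r)]
            res = [
                b * residuals[ip][k] + a * residuals[ineg][k] for k in range(len(K))
            ]
            g = None
            for x in ray:
                if x != 0:
                    g = x if g is None else min(g, x)
            if g:
                ray = [x / g for x in ray]
                res = [x / g for x in res]
            key = tuple(ray)
            if key in seen_new:
                continue
            seen_new.add(key)
            new_rays.append(ray)
            new_res.append(res)
            new_sup.append(sup)
        rays, residuals, supports = new_rays, new_res, new_sup
    return rays


def enumerate_efms(
    net: Network,
    internal: set[str],
    normalization: str = "smallest-coefficient",
) -> EfmMatrix:
    """Enumerate the elementary flux modes of *net* w.r.t. *internal* species.

    Reversible reactions are split, rays of the pointed cone are enumerated
    exactly, the spurious 2-cycles created by the split are dropped, and the
    surviving modes are folded back to signed fluxes on the original
    reactions.  Columns are ordered lexicographically by support.
    """
    unknown = set(internal) - set(net.species_ids)
    if unknown:
        raise NetworkError(f"internal set has unknown species {sorted(unknown)}")
    split, mapping = split_reversible(net)
    n_r = len(split.reactions)
    if n_r == 0:
        return EfmMatrix(
            modes=np.zeros((0, 0)),
            reaction_ids=[],
            reversibility=[],
            normalization=normalization,
        )
    K, _, col_index = stoichiometric_matrix(split, row_subset=internal or set())
    rays = _enumerate_rays(_rational_matrix(K), n_r)

    # fold back to the original (signed) reaction space
    orig_ids = net.reaction_ids
    folded: list[list[Fraction]] = []
    for ray in rays:
        v = []
        for rid in orig_ids:
            fwd, bwd = mapping[rid]
            x = ray[col_index[fwd]]
            if bwd is not None:
                x = x - ray[col_index[bwd]]
            v.append(x)
        # spurious 2-cycle: forward and backward of one split reaction only
        if all(x == 0 for x in v):
            continue
        folded.append(v)

    # canonical normalization + dedupe (forward/backward of a fully
    # reversible mode both survive; they differ in sign so both are kept)
    def normalize(v: list[Fraction]) -> list[Fraction]:
        nz = [abs(x) for x in v if x != 0]
        g = min(nz)
        return [x / g for x in v]

    folded = [normalize(v) for v in folded]
    uniq: dict[tuple, list[Fraction]] = {}
    for v in folded:
        uniq.setdefault(tuple(v), v)
    # order: lexicographic by support, positive orientation before its mirror
    ordered = sorted(
        uniq.values(),
        key=lambda v: (
            tuple(i for i, x in enumerate(v) if x != 0),
            tuple((-float(x > 0) + float(x < 0), abs(float(x))) for x in v),
        ),
    )
    if len(ordered) > EFM_COUNT_WARN:
        warnings.warn(
            f"{len(ordered)} elementary modes enumerated; consider splitting "
            "this sub-network further",
            stacklevel=2,
        )
    modes = np.array([[float(x) for x in v] for v in ordered]).T
    if modes.size == 0:
        modes = np.zeros((len(orig_ids), 0))
    return EfmMatrix(
        modes=modes,
        reaction_ids=list(orig_ids),
        reversibility=[r.reversible for r in net.reactions],
        normalization=normalization,
    )


def validate_efms(
    E: EfmMatrix, K_internal: np.ndarray, atol: float = 1e-9
) -> list[str]:
    """Report steady-state and support-minimality violations (empty = valid)."""
    violations: list[str] = []
    if K_internal.size and E.n_modes:
        prod = K_internal @ E.modes
        for j in range(E.n_modes):
            err = np.max(np.abs(prod[:, j])) if prod.size else 0.0
            if err > atol:
                violations.append(f"mode {j}: steady-state residual {err:.2e}")
    sups = [E.support(j) for j in range(E.n_modes)]
    for i, j in itertools.combinations(range(E.n_modes), 2):
        si, sj = sups[i], sups[j]
        # opposite orientations of a reversible mode share a support legally
        if si == sj and np.allclose(E.modes[:, i], -E.modes[:, j]):
            continue
        if si < sj or si == sj:
            violations.append(f"mode {i} support included in mode {j}")
        elif sj < si:
            violations.append(f"mode {j} support included in mode {i}")
    return violations


def yield_projection(
    E: EfmMatrix,
    net: Network,
    numerator: str,
    denominator: str,
    reference: str,
) -> YieldTable:
    """Project modes into (numerator consumed, denominator produced) per unit
    flux of *reference*; modes with zero reference flux are excluded."""
    if reference not in E.reaction_ids:
        raise NetworkError(f"reference reaction {reference!r} not in EFM matrix")
    ref_row = E.reaction_ids.index(reference)
    Kfull, row_index, _ = stoichiometric_matrix(net)
    num_row = row_index[numerator]
    den_row = row_index[denominator]
    table = YieldTable(numerator=numerator, denominator=denominator, reference=reference)
    for j in range(E.n_modes):
        ref_flux = E.modes[ref_row, j]
        if ref_flux == 0:
            continue
        v = E.modes[:, j] / ref_flux
        net_change = Kfull @ v
        table.ratios[j] = (-net_change[num_row], net_change[den_row])
    return table


def select_best_yield(table: YieldTable) -> int:
    """Mode minimizing numerator consumption per unit reference flux;
    ties broken by smaller denominator production, then lowest index."""
    if not table.ratios:
        raise NetworkError("empty yield table")
    return min(table.ratios, key=lambda j: (table.ratios[j][0], table.ratios[j][1], j))


# ---------------------------------------------------------------------------
# independent brute-force oracle (test cross-check; not used by enumerate_efms)

def brute_force_efms(net: Network, internal: set[str]) -> list[np.ndarray]:
    """Enumerate EFMs by testing every reaction-support subset with sympy.

    A support S is elementary iff the nullspace of K_C restricted to S is
    one-dimensional with a generator that is nonzero on all of S and
    sign-feasible on irreversible reactions.  Exponential; for tiny
    networks only.
    """
    import sympy

    split, mapping = split_reversible(net)
    K, _, col_index = stoichiometric_matrix(split, row_subset=internal or set())
    n_r = len(split.reactions)
    Ks = sympy.Matrix(K)
    modes: dict[tuple, np.ndarray] = {}
    for size in range(1, n_r + 1):
        for sup in itertools.combinations(range(n_r), size):
            sub = Ks[:, list(sup)]
            null = sub.nullspace()
            if len(null) != 1:
                continue
            gen = null[0]
            if any(x == 0 for x in gen):
                continue
            if all(x < 0 for x in gen):
                gen = -gen
            if any(x < 0 for x in gen):
                continue
            v = [sympy.Integer(0)] * n_r
            for k, idx in enumerate(sup):
                v[idx] = gen[k]
            folded = []
            for rid in net.reaction_ids:
                fwd, bwd = mapping[rid]
                x = v[col_index[fwd]]
                if bwd is not None:
                    x = x - v[col_index[bwd]]
                folded.append(x)
            if all(x == 0 for x in folded):
                continue  # spurious 2-cycle
            arr = np.array([float(x) for x in folded])
            scale = np.min(np.abs(arr[arr != 0]))
            arr = arr / scale
            modes[tuple(np.round(arr, 10))] = arr
    return [modes[k] for k in sorted(modes)]
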