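"""Network reduction: partition into balanced sub-networks, reduce each to
macroscopic reactions via elementary flux modes, assemble the reduced model.

The reduction rests on a local quasi-steady-state assumption: within each
user-declared sub-network the internal metabolites neither accumulate nor
deplete, so every admissible flux through the sub-network is a nonnegative
combination of its elementary modes.  Multiplying the sub-network
stoichiometry by one mode yields a *macroscopic reaction* over the
boundary species only.  Species linking the sub-networks (the accumulating
set A) plus functional biomass carry the dynamics of the assembled model.

The partition is user-supplied configuration — reactions may be duplicated
across sub-networks when the same conversion serves several cell functions
(duplication shows up as redundant columns of the full stoichiometry).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .efm import EfmMatrix, enumerate_efms, select_best_yield, yield_projection
from .netio import Network, NetworkError, Reaction, Species, stoichiometric_matrix

INTERNAL_ATOL = 1e-9


@dataclass
class SubnetworkSpec:
    """One sub-network: a reaction group and its quasi-steady internal species."""

    name: str
    reaction_ids: list[str]
    internal_ids: list[str] = field(default_factory=list)
    #: optional EFM selection policy: None (keep all) or
    #: ("best-yield", numerator, denominator, reference)
    selection: tuple | None = None


@dataclass
class Subnetwork:
    """Materialized sub-network view: restricted Network + classification."""

    name: str
    network: Network
    internal_ids: list[str]
    boundary_ids: list[str]
    selection: tuple | None = None


@dataclass
class MacroReaction:
    """Net input-output stoichiometry of one elementary mode of a sub-network."""

    id: str
    stoich: dict[str, float]
    source: tuple[str, int] | None = None  # (sub-network name, EFM column)
    reversible: bool = False


@dataclass
class ReducedModel:
    """The assembled reduced model: retained species, macro reactions, K'."""

    species: list[str]
    macro_reactions: list[MacroReaction]
    K_prime: np.ndarray
    dropped: set[str] = field(default_factory=set)
    clamped: set[str] = field(default_factory=set)
    accumulating: set[str] = field(default_factory=set)
    biomass: str = "B"
    compositions: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def macro_ids(self) -> list[str]:
        return [m.id for m in self.macro_reactions]

    def species_index(self, sid: str) -> int:
        return self.species.index(sid)


def extract_subnetwork(net: Network, spec: SubnetworkSpec) -> Subnetwork:
    """Materialize the sub-network view for one partition entry."""
    by_id = {r.id: r for r in net.reactions}
    missing = [rid for rid in spec.reaction_ids if rid not in by_id]
    if missing:
        raise NetworkError(f"sub-network {spec.name!r}: unknown reactions {missing}")
    reactions = [
        Reaction(id=rid, stoich=dict(by_id[rid].stoich), reversible=by_id[rid].reversible)
        for rid in spec.reaction_ids
    ]
    touched: list[str] = []
    for r in reactions:
        for sid in r.stoich:
            if sid not in touched:
                touched.append(sid)
    untouched = [sid for sid in spec.internal_ids if sid not in touched]
    if untouched:
        raise NetworkError(
            f"sub-network {spec.name!r}: internal species {untouched} not touched "
            "by any listed reaction"
        )
    order = {sid: i for i, sid in enumerate(net.species_ids)}
    touched.sort(key=order.__getitem__)
    species = [net.species_by_id(sid) for sid in touched]
    sub = Network(species=list(species), reactions=reactions)
    boundary = [sid for sid in touched if sid not in set(spec.internal_ids)]
    return Subnetwork(
        name=spec.name,
        network=sub,
        internal_ids=list(spec.internal_ids),
        boundary_ids=boundary,
        selection=spec.selection,
    )


def reduce_subnetwork(sub: Subnetwork) -> tuple[list[MacroReaction], EfmMatrix]:
    """Reduce one sub-network to its macroscopic reactions (one per EFM)."""
    if not sub.network.reactions:
        raise NetworkError(f"sub-network {sub.name!r} has no reactions")
    E = enumerate_efms(sub.network, set(sub.internal_ids))
    if E.n_modes == 0:
        warnings.warn(f"sub-network {sub.name!r} has no elementary mode (dead)", stacklevel=2)
        return [], E
    keep = list(range(E.n_modes))
    if sub.selection is not None:
        policy, *args = sub.selection
        if policy == "best-yield":
            numerator, denominator, reference = args
            table = yield_projection(E, sub.network, numerator, denominator, reference)
            keep = [select_best_yield(table)]
        else:
            raise NetworkError(f"unknown EFM selection policy {policy!r}")
    K, row_index, _ = stoichiometric_matrix(sub.network)
    internal = set(sub.internal_ids)
    out: list[MacroReaction] = []
    for k, j in enumerate(keep):
        net_stoich = K @ E.modes[:, j]
        bad = [
            sid
            for sid, i in row_index.items()
            if sid in internal and abs(net_stoich[i]) > INTERNAL_ATOL
        ]
        if bad:
            raise NetworkError(
                f"sub-network {sub.name!r} mode {j}: internal species {bad} not balanced"
            )
        stoich = {
            sid: float(net_stoich[i])
            for sid, i in row_index.items()
            if sid not in internal and abs(net_stoich[i]) > INTERNAL_ATOL
        }
        out.append(MacroReaction(id=f"{sub.name}.{k + 1}", stoich=stoich, source=(sub.name, j)))
    return out, E


def merge_reverse_pairs(mrs: list[MacroReaction], atol: float = 1e-9) -> list[MacroReaction]:
    """Merge macro-reaction pairs whose stoichiometries are exact negatives
    into single reversible entries; everything else passes through."""

    def normalized(m: MacroReaction) -> dict[str, float]:
        nz = [abs(c) for c in m.stoich.values() if c != 0]
        if not nz:
            return dict(m.stoich)
        s = min(nz)
        return {sid: c / s for sid, c in m.stoich.items()}

    out: list[MacroReaction] = []
    used: set[int] = set()
    for i, mi in enumerate(mrs):
        if i in used:
            continue
        ni = normalized(mi)
        partner = None
        for j in range(i + 1, len(mrs)):
            if j in used:
                continue
            nj = normalized(mrs[j])
            if set(ni) == set(nj) and all(abs(ni[s] + nj[s]) <= atol for s in ni):
                partner = j
                break
        if partner is not None:
            used.add(partner)
            out.append(
                MacroReaction(id=mi.id, stoich=dict(mi.stoich), source=mi.source, reversible=True)
            )
        else:
            out.append(mi)
    return out


def assemble_reduced_model(
    mrs: list[MacroReaction],
    accumulating: set[str],
    biomass: str,
    drop: set[str] | None = None,
    clamp: set[str] | None = None,
    compositions: dict[str, dict[str, float]] | None = None,
) -> ReducedModel:
    """Build K' over retained species from the macroscopic reactions.

    Rows of *drop* species (energy cofactors whose fate is not described)
    are removed; *clamp* species keep rows for bookkeeping but are held
    constant in simulation.  Accumulating species and functional biomass
    must participate in at least one macro reaction and may not be dropped.
    """
    drop = set(drop or ())
    clamp = set(clamp or ())
    if drop & accumulating:
        raise NetworkError(
            f"cannot drop accumulating species {sorted(drop & accumulating)}"
        )
    if biomass in drop:
        raise NetworkError("cannot drop the biomass species")
    participants: list[str] = []
    for m in mrs:
        for sid in m.stoich:
            if sid not in participants:
                participants.append(sid)
    for sid in sorted(accumulating | {biomass}):
        if sid not in participants:
            raise NetworkError(f"species {sid!r} occurs in no macro reaction")
    species = [sid for sid in participants if sid not in drop]
    K = np.zeros((len(species), len(mrs)))
    idx = {sid: i for i, sid in enumerate(species)}
    for j, m in enumerate(mrs):
        for sid, c in m.stoich.items():
            if sid in idx:
                K[idx[sid], j] = c
    model = ReducedModel(
        species=species,
        macro_reactions=list(mrs),
        K_prime=K,
        dropped=drop,
        clamped=clamp,
        accumulating=set(accumulating),
        biomass=biomass,
        compositions=dict(compositions or {}),
    )
    leaks = find_unbalanced_internals(model)
    if leaks:
        warnings.warn(
            f"species {leaks} are neither accumulating, dropped nor clamped yet "
            "have nonzero net production under positive fluxes",
            stacklevel=2,
        )
    return model


def find_unbalanced_internals(model: ReducedModel) -> list[str]:
    """Retained intermediates violating local balance: not accumulating, not
    clamped, not biomass, yet both produced and consumed with a nonzero net
    under strictly positive fluxes.  Pure substrates/products (single-signed
    K' row) are exchanged with the medium and exempt."""
    out = []
    exempt = model.accumulating | model.clamped | {model.biomass}
    for i, sid in enumerate(model.species):
        if sid in exempt:
            continue
        row = model.K_prime[i]
        produced = np.any(row > INTERNAL_ATOL)
        consumed = np.any(row < -INTERNAL_ATOL)
        if produced and consumed:
            # a mixed-sign row has nonzero net production for generic
            # strictly positive fluxes: a forgotten intermediate
            out.append(sid)
    return out


def reduce_network(
    net: Network,
    specs: list[SubnetworkSpec],
    accumulating: set[str],
    biomass: str,
    drop: set[str] | None = None,
    clamp: set[str] | None = None,
    merge_reversible: bool = True,
) -> tuple[ReducedModel, dict[str, EfmMatrix]]:
    """Full pipeline: extract -> EFM-reduce -> merge -> assemble.

    Returns the reduced model plus per-sub-network EFM matrices (flux
    reconstruction provenance).
    """
    all_mrs: list[MacroReaction] = []
    efms: dict[str, EfmMatrix] = {}
    for spec in specs:
        sub = extract_subnetwork(net, spec)
        mrs, E = reduce_subnetwork(sub)
        efms[spec.name] = E
        all_mrs.extend(mrs)
    if merge_reversible:
        all_mrs = merge_reverse_pairs(all_mrs)
    model = assemble_reduced_model(
        all_mrs, accumulating=accumulating, biomass=biomass, drop=drop, clamp=clamp
    )
    return model, efms


def count_reduced_efms(model: ReducedModel) -> int:
    """Number of elementary modes of the reduced model itself: each
    irreversible macro reaction contributes one, each reversible two."""
    n_rev = sum(1 for m in model.macro_reactions if m.reversible)
    return len(model.macro_reactions) + n_rev


# ---------------------------------------------------------------------------
# serialization

def model_to_dict(model: ReducedModel) -> dict:
    return {
        "species": model.species,
        "macro_reactions": [
            {
                "id": m.id,
                "stoich": m.stoich,
                "reversible": m.reversible,
                "source": list(m.source) if m.source else None,
            }
            for m in model.macro_reactions
        ],
        "dropped": sorted(model.dropped),
        "clamped": sorted(model.clamped),
        "accumulating": sorted(model.accumulating),
        "biomass": model.biomass,
        "compositions": model.compositions,
    }


def model_from_dict(d: dict) -> ReducedModel:
    mrs = [
        MacroReaction(
            id=m["id"],
            stoich={k: float(v) for k, v in m["stoich"].items()},
            reversible=m["reversible"],
            source=tuple(m["source"]) if m.get("source") else None,
        )
        for m in d["macro_reactions"]
    ]
    model = assemble_reduced_model(
        mrs,
        accumulating=set(d["accumulating"]),
        biomass=d["biomass"],
        drop=set(d["dropped"]),
        clamp=set(d["clamped"]),
        compositions=d.get("compositions", {}),
    )
    return model


def save_model_json(model: ReducedModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model_json(path: str) -> ReducedModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def format_model_table(model: ReducedModel, decimals: int = 2) -> str:
    """Human-readable macro-reaction table (id, equation, reversibility)."""
    lines = []
    for m in model.macro_reactions:
        lhs, rhs = [], []
        for sid, c in m.stoich.items():
            mag = round(abs(c), decimals) or abs(c)  # don't round tiny coeffs away
            term = sid if mag == 1 else f"{mag:g} {sid}"
            (lhs if c < 0 else rhs).append(term)
        arrow = "<->" if m.reversible else "->"
        lines.append(f"{m.id}: {' + '.join(lhs)} {arrow} {' + '.join(rhs)}")
    return "\n".join(lines) + "\n"
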