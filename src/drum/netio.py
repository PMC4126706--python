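"""Metabolic network parsing, stoichiometry and elemental bookkeeping.

A :class:`Network` is an ordered collection of :class:`Species` and
:class:`Reaction` objects.  Reactions are written in a plain-text table
dialect, one per line::

    MR6: G6P <-> CARB + Pi        # reversible
    r1:  2 A + B -> C             # irreversible, coefficient 2 on A

Species are auto-registered on first mention.  Elemental compositions
(atoms of C, H, N, O, P, S, Mg per mole) can be attached per species and
used to audit reactions for conservation of each element, or to solve for
unknown compositions by closing the elemental balance of a reaction.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np

ELEMENTS = ("C", "H", "N", "O", "P", "S", "Mg")

#: elements audited by default; H and O bookkeeping is unreliable in lumped
#: reactions (implicit water/protons), so they are opt-in.
DEFAULT_BALANCE_ELEMENTS = ("C", "N", "S", "Mg", "P")

_ARROWS = ("<->", "<—>", "<→>", "—>", "->", "→")


class NetworkError(ValueError):
    """Malformed network input (parse errors, unknown ids, bad balances)."""


@dataclass
class Species:
    """A chemical species of the network.

    Parameters
    ----------
    id
        Short unique token (e.g. ``"G6P"``).
    name
        Free-text description.
    composition
        Map element symbol -> atoms per mole; absent key = unknown.
    is_boundary
        True for species exchanged with the environment.
    non_material
        True for pseudo-species carrying no atoms (photons written as a
        reactant); excluded from every elemental balance.
    """

    id: str
    name: str = ""
    composition: dict[str, float] = field(default_factory=dict)
    is_boundary: bool = False
    non_material: bool = False

    def __post_init__(self) -> None:
        for el, n in self.composition.items():
            if n < 0:
                raise NetworkError(f"negative {el} count for species {self.id!r}")


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed)."""

    id: str
    stoich: dict[str, float]
    reversible: bool = False

    def __post_init__(self) -> None:
        # catalytic self-loops (A -> A) net to an explicit zero entry, so the
        # invariant is a non-empty stoichiometry, not a nonzero one
        if not self.stoich:
            raise NetworkError(f"reaction {self.id!r} has empty stoichiometry")


@dataclass
class Network:
    """Ordered species + reactions; rows/columns of K follow declaration order."""

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(ids) != len(set(ids)):
            raise NetworkError("duplicate species id")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            raise NetworkError("duplicate reaction id")
        known = set(ids)
        for r in self.reactions:
            missing = set(r.stoich) - known
            if missing:
                raise NetworkError(
                    f"reaction {r.id!r} references unknown species {sorted(missing)}"
                )

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise NetworkError(f"unknown species {sid!r}")

    def reaction_by_id(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise NetworkError(f"unknown reaction {rid!r}")


_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S+)$")


def _parse_side(side: str, rid: str, lineno: int) -> dict[str, float]:
    out: dict[str, float] = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise NetworkError(f"line {lineno}: empty term in reaction {rid!r}")
        m = _TERM_RE.match(term)
        if m is None:
            raise NetworkError(f"line {lineno}: cannot parse term {term!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        sid = m.group(2)
        if sid in out:
            raise NetworkError(
                f"line {lineno}: species {sid!r} appears twice on one side of {rid!r}"
            )
        out[sid] = coeff
    return out


def parse_reaction_table(text: str, non_material: set[str] | None = None) -> Network:
    """Parse a reaction table into a :class:`Network`.

    One reaction per line, ``id: lhs -> rhs`` (or ``<->`` for reversible);
    ``#`` starts a comment; blank lines are ignored.  ASCII and em-dash
    arrow spellings are both accepted.  Species listed in *non_material*
    (default: ``{"Light"}``) are flagged as carrying no atoms.
    """
    if non_material is None:
        non_material = {"Light"}
    species: list[Species] = []
    seen: set[str] = set()
    reactions: list[Reaction] = []

    def register(sid: str) -> None:
        if sid not in seen:
            seen.add(sid)
            species.append(Species(id=sid, non_material=sid in non_material))

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise NetworkError(f"line {lineno}: missing 'id:' prefix in {line!r}")
        rid, body = line.split(":", 1)
        rid = rid.strip()
        if not rid:
            raise NetworkError(f"line {lineno}: empty reaction id")
        if any(r.id == rid for r in reactions):
            raise NetworkError(f"line {lineno}: duplicate reaction id {rid!r}")
        arrow = next((a for a in _ARROWS if a in body), None)
        if arrow is None:
            raise NetworkError(f"line {lineno}: no reaction arrow in {body!r}")
        lhs_txt, rhs_txt = body.split(arrow, 1)
        reversible = arrow.startswith("<")
        lhs = _parse_side(lhs_txt, rid, lineno)
        rhs = _parse_side(rhs_txt, rid, lineno)
        stoich: dict[str, float] = {}
        for sid, c in lhs.items():
            stoich[sid] = stoich.get(sid, 0.0) - c
        for sid, c in rhs.items():
            stoich[sid] = stoich.get(sid, 0.0) + c
        if not stoich:
            raise NetworkError(f"line {lineno}: reaction {rid!r} has empty stoichiometry")
        for sid in list(lhs) + [s for s in rhs if s not in lhs]:
            register(sid)
        reactions.append(Reaction(id=rid, stoich=stoich, reversible=reversible))
    return Network(species=species, reactions=reactions)


def serialize_reaction_table(net: Network) -> str:
    """Inverse of :func:`parse_reaction_table` (round-trips exactly)."""
    lines = []
    for r in net.reactions:
        lhs = [(sid, -c) for sid, c in r.stoich.items() if c < 0]
        rhs = [(sid, c) for sid, c in r.stoich.items() if c > 0]
        # zero-net (catalytic) participants reappear on both sides
        lhs += [(sid, 1.0) for sid, c in r.stoich.items() if c == 0]
        rhs += [(sid, 1.0) for sid, c in r.stoich.items() if c == 0]

        def fmt(side: list[tuple[str, float]]) -> str:
            terms = []
            for sid, c in side:
                terms.append(sid if c == 1 else f"{c:.12g} {sid}")
            return " + ".join(terms)

        arrow = "<->" if r.reversible else "->"
        lines.append(f"{r.id}: {fmt(lhs)} {arrow} {fmt(rhs)}")
    return "\n".join(lines) + ("\n" if lines else "")


def stoichiometric_matrix(
    net: Network, row_subset: list[str] | set[str] | None = None
) -> tuple[np.ndarray, dict[str, int], dict[str, int]]:
    """Build K (species x reactions) and its row/column index maps.

    Restricting ``row_subset`` to the internal species yields the
    K_C-style sub-matrix whose nullspace defines balanced-growth fluxes.
    """
    if row_subset is None:
        rows = net.species_ids
    else:
        unknown = set(row_subset) - set(net.species_ids)
        if unknown:
            raise NetworkError(f"row_subset has unknown species {sorted(unknown)}")
        rows = [sid for sid in net.species_ids if sid in set(row_subset)]
    row_index = {sid: i for i, sid in enumerate(rows)}
    col_index = {rid: j for j, rid in enumerate(net.reaction_ids)}
    K = np.zeros((len(rows), len(net.reactions)))
    for j, r in enumerate(net.reactions):
        for sid, c in r.stoich.items():
            i = row_index.get(sid)
            if i is not None:
                K[i, j] = c
    return K, row_index, col_index


def check_elemental_balance(
    net: Network,
    elements: tuple[str, ...] = DEFAULT_BALANCE_ELEMENTS,
    tolerance: float = 0.05,
    ignore: set[str] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-reaction elemental residuals Σ_i coeff_i · count_i(element).

    Raises if a participating species (not ignored, not non-material) lacks
    a count for a requested element.  Returns ``{rid: {element: residual}}``
    with a companion ``"_violations"``-free structure: callers flag entries
    with ``abs(residual) > tolerance`` via :func:`balance_violations`.
    """
    ignore = ignore or set()
    report: dict[str, dict[str, float]] = {}
    for r in net.reactions:
        per_el: dict[str, float] = {}
        for el in elements:
            total = 0.0
            for sid, c in r.stoich.items():
                sp = net.species_by_id(sid)
                if sid in ignore or sp.non_material:
                    continue
                if el not in sp.composition:
                    raise NetworkError(
                        f"species {sid!r} has unknown {el} composition "
                        f"(needed for reaction {r.id!r})"
                    )
                total += c * sp.composition[el]
            per_el[el] = total
        report[r.id] = per_el
    return report


def balance_violations(
    report: dict[str, dict[str, float]], tolerance: float = 0.05
) -> list[tuple[str, str, float]]:
    """Flag (reaction, element, residual) entries exceeding the tolerance."""
    return [
        (rid, el, res)
        for rid, per_el in report.items()
        for el, res in per_el.items()
        if abs(res) > tolerance
    ]


def infer_composition_by_closure(
    net: Network,
    element: str,
    known: dict[str, float],
    unknowns: list[str],
    tolerance: float = 0.05,
) -> dict[str, float]:
    """Solve for unknown per-species element counts by zeroing reaction residuals.

    Processes *unknowns* in order; each must be the single undetermined
    participant of at least one reaction (earlier unknowns count as
    determined).  If several reactions determine the same species they must
    agree within *tolerance*, else both candidates are reported.
    """
    counts = dict(known)
    for sid in unknowns:
        net.species_by_id(sid)  # existence check
        candidates: list[tuple[str, float]] = []
        for r in net.reactions:
            if sid not in r.stoich or r.stoich[sid] == 0:
                continue
            rest = 0.0
            determinable = True
            for other, c in r.stoich.items():
                if other == sid:
                    continue
                sp = net.species_by_id(other)
                if sp.non_material:
                    continue
                if other in counts:
                    rest += c * counts[other]
                else:
                    determinable = False
                    break
            if determinable:
                candidates.append((r.id, -rest / r.stoich[sid]))
        if not candidates:
            raise NetworkError(
                f"no reaction determines the {element} count of {sid!r}"
            )
        values = [v for _, v in candidates]
        if max(values) - min(values) > tolerance:
            raise NetworkError(
                f"inconsistent {element} closure for {sid!r}: "
                + ", ".join(f"{rid} -> {v:.4f}" for rid, v in candidates)
            )
        counts[sid] = values[0]
    return counts


# ---------------------------------------------------------------------------
# serialization

def network_to_dict(net: Network) -> dict:
    return {
        "species": [
            {
                "id": s.id,
                "name": s.name,
                "composition": s.composition,
                "is_boundary": s.is_boundary,
                "non_material": s.non_material,
            }
            for s in net.species
        ],
        "reactions": [
            {"id": r.id, "stoich": r.stoich, "reversible": r.reversible}
            for r in net.reactions
        ],
    }


def network_from_dict(d: dict) -> Network:
    return Network(
        species=[Species(**s) for s in d["species"]],
        reactions=[Reaction(**r) for r in d["reactions"]],
    )


def save_network_json(net: Network, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1)


def load_network_json(path: str) -> Network:
    with open(path) as fh:
        return network_from_dict(json.load(fh))


def load_compositions_csv(net: Network, path: str) -> Network:
    """Attach per-species compositions from a CSV with columns species_id, C, H, ...

    Blank cells mean unknown.  Returns a new Network; the input is untouched.
    """
    import pandas as pd

    df = pd.read_csv(path)
    comp_by_id: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        comp = {}
        for el in ELEMENTS:
            if el in df.columns and not pd.isna(row[el]):
                comp[el] = float(row[el])
        comp_by_id[str(row["species_id"])] = comp
    species = [
        replace(s, composition={**s.composition, **comp_by_id.get(s.id, {})})
        for s in net.species
    ]
    return Network(species=species, reactions=list(net.reactions))


def read_sbml(path: str) -> Network:
    """Import species and reactions from an SBML file (no kinetic laws)."""
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SBML import requires the 'cobra' package") from exc
    model = cobra.io.read_sbml_model(path)
    species = [
        Species(id=m.id, name=m.name or "", is_boundary=m.compartment == "e")
        for m in model.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoich={m.id: float(c) for m, c in r.metabolites.items()},
            reversible=r.reversibility,
        )
        for r in model.reactions
    ]
    return Network(species=species, reactions=reactions)
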