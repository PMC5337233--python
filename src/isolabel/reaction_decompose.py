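"""Atom-mapped reaction parsing and EMU-identity decomposition.

Network grammar (one reaction per line)::

    A[ab] + B[c] -> C[a] + D[bc] @ v     # irreversible, flux id v
    E[de] <-> F[ed] @ w                  # expands to w.fwd / w.rev
    A[ab] -> C[a] + CO2[b] @ v2          # any atom partition
    X + A[ab] -> A2[ba] + X @ v3         # X: untracked cofactor (no atoms)

Atom labels establish the left/right atom bijection: the multiset of
labels on the two sides must match exactly and a label may appear at
most once per side.  Single-character alphanumeric labels are written
back to back (``ab``); comma-separated multi-character labels
(``A[a1,a2]``) are accepted for wide metabolites.  ``#`` starts a
comment; blank lines are ignored.

Decomposition follows the power-set construction: for every product
and every non-empty subset ``S`` of its atom positions, one identity
``(product, S) = flux x (monoidal product of reagent EMUs)`` is
emitted, the reagent EMUs being the pre-images of ``S`` grouped by
origin reagent.  The empty subset is excluded on both sides (including
it would force ``f(empty) = v * f(empty)``).
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_states import EMUKey


class NetworkParseError(ValueError):
    """Malformed or inconsistent network text (carries the line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class UnresolvableEMUError(KeyError):
    """A requested target EMU is never produced by any reaction."""

    def __init__(self, key: EMUKey):
        self.key = key
        super().__init__(f"target EMU {key} is never produced by any reaction")


@dataclass(frozen=True)
class Reaction:
    """One irreversible atom-mapped reaction."""

    id: str
    flux_id: str
    reagents: tuple[tuple[str, tuple[str, ...]], ...]
    products: tuple[tuple[str, tuple[str, ...]], ...]
    line: int = 0

    def origin_of(self, label: str) -> tuple[int, int]:
        """(reagent occurrence index, 1-based atom position) carrying a label."""
        for ri, (_, labels) in enumerate(self.reagents):
            if label in labels:
                return ri, labels.index(label) + 1
        raise KeyError(f"label {label!r} not found on reagent side of {self.id}")


@dataclass(frozen=True)
class Identity:
    """A flux-weighted EMU identity ``lhs = flux x (factor_1 * ... * factor_k)``.

    ``atom_map`` aligns the sorted atoms of ``lhs`` with their origins:
    entry ``i`` is ``(factor_index, position_index)``, meaning the
    ``i``-th lhs atom comes from the ``position_index``-th atom (0-based,
    in sorted order) of ``rhs_factors[factor_index]``.  The map is what
    lets positional (Boolean-function) interpretations permute factor
    states into product order; mass distributions ignore it.
    """

    lhs: EMUKey
    flux_id: str
    rhs_factors: tuple[EMUKey, ...]
    atom_map: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.rhs_factors or any(f.size == 0 for f in self.rhs_factors):
            raise ValueError("identities may not contain empty EMU factors")
        if self.lhs.size == 0:
            raise ValueError("identities may not have an empty lhs EMU")
        if sum(f.size for f in self.rhs_factors) != self.lhs.size:
            raise ValueError("factor sizes must sum to the lhs size")
        if len(self.atom_map) != self.lhs.size:
            raise ValueError("atom_map length must equal lhs size")

    @property
    def size(self) -> int:
        return self.lhs.size

    def __str__(self) -> str:
        rhs = " * ".join(map(str, self.rhs_factors))
        return f"{self.lhs} = {self.flux_id} x ({rhs})"


@dataclass(frozen=True)
class IdentitySystem:
    """Deduplicated EMU identities of a network, indexed by size and lhs."""

    identities: tuple[Identity, ...]
    closure: frozenset[EMUKey] | None = None

    def __post_init__(self) -> None:
        by_size: dict[int, list[Identity]] = {}
        by_lhs: dict[EMUKey, list[Identity]] = {}
        for ident in self.identities:
            by_size.setdefault(ident.size, []).append(ident)
            by_lhs.setdefault(ident.lhs, []).append(ident)
        object.__setattr__(self, "_by_size", by_size)
        object.__setattr__(self, "_by_lhs", by_lhs)

    @property
    def by_size(self) -> dict[int, list[Identity]]:
        return self._by_size

    @property
    def by_lhs(self) -> dict[EMUKey, list[Identity]]:
        return self._by_lhs

    @property
    def sizes(self) -> list[int]:
        return sorted(self._by_size)

    def __len__(self) -> int:
        return len(self.identities)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "lhs": {"metabolite": i.lhs.metabolite_id, "atoms": list(i.lhs.atom_set)},
                    "flux_id": i.flux_id,
                    "factors": [
                        {"metabolite": f.metabolite_id, "atoms": list(f.atom_set)}
                        for f in i.rhs_factors
                    ],
                }
                for i in self.identities
            ],
            indent=1,
        )


_TERM_RE = re.compile(r"^([A-Za-z_][\w.\-]*)\s*(?:\[([^\]]*)\])?$")


def _parse_side(text: str, line: int) -> tuple[tuple[str, tuple[str, ...]], ...]:
    terms = []
    for raw in text.split("+"):
        raw = raw.strip()
        if not raw:
            raise NetworkParseError("empty term", line)
        match = _TERM_RE.match(raw)
        if not match:
            raise NetworkParseError(f"cannot parse term {raw!r}", line)
        name, labels_text = match.group(1), match.group(2)
        if labels_text is None or labels_text.strip() == "":
            labels: tuple[str, ...] = ()
        elif "," in labels_text:
            labels = tuple(p.strip() for p in labels_text.split(","))
            if any(not p for p in labels):
                raise NetworkParseError(f"empty atom label in {raw!r}", line)
        else:
            labels = tuple(labels_text.strip())
        terms.append((name, labels))
    return tuple(terms)


def parse_network(text: str) -> list[Reaction]:
    """Parse network text into validated irreversible reactions.

    Reversible arrows ``<->`` expand into two reactions with flux ids
    suffixed ``.fwd`` and ``.rev``.  Validation covers per-side label
    uniqueness, left/right label conservation and network-wide
    consistency of metabolite atom counts; failures raise
    :class:`NetworkParseError` with the offending line number.
    """
    reactions: list[Reaction] = []
    arity: dict[str, int] = {}
    counter = itertools.count(1)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        content = raw.split("#", 1)[0].strip()
        if not content:
            continue
        if "@" not in content:
            raise NetworkParseError("missing '@ flux_id'", lineno)
        body, flux_id = content.rsplit("@", 1)
        flux_id = flux_id.strip()
        if not flux_id:
            raise NetworkParseError("empty flux id", lineno)
        reversible = "<->" in body
        arrow = "<->" if reversible else "->"
        if body.count(arrow) != 1:
            raise NetworkParseError("expected exactly one reaction arrow", lineno)
        left_text, right_text = body.split(arrow)
        left = _parse_side(left_text, lineno)
        right = _parse_side(right_text, lineno)
        _check_labels(left, right, lineno)
        directions = [(left, right, flux_id)]
        if reversible:
            directions = [
                (left, right, f"{flux_id}.fwd"),
                (right, left, f"{flux_id}.rev"),
            ]
        for reagents, products, fid in directions:
            rxn = Reaction(f"R{next(counter)}", fid, reagents, products, lineno)
            for name, labels in rxn.reagents + rxn.products:
                if name in arity and arity[name] != len(labels):
                    raise NetworkParseError(
                        f"metabolite {name!r} has {len(labels)} atoms here but "
                        f"{arity[name]} elsewhere",
                        lineno,
                    )
                arity[name] = len(labels)
            reactions.append(rxn)
    return reactions


def _check_labels(left, right, lineno: int) -> None:
    for side_name, side in (("left", left), ("right", right)):
        flat = [lab for _, labels in side for lab in labels]
        dupes = {lab for lab in flat if flat.count(lab) > 1}
        if dupes:
            raise NetworkParseError(
                f"duplicate atom label(s) {sorted(dupes)} on {side_name} side", lineno
            )
    lset = sorted(lab for _, labels in left for lab in labels)
    rset = sorted(lab for _, labels in right for lab in labels)
    if lset != rset:
        unmatched = sorted(set(lset) ^ set(rset))
        raise NetworkParseError(
            f"atom labels not conserved across the arrow: {unmatched}", lineno
        )


def decompose_reaction(reaction: Reaction) -> list[Identity]:
    """Decompose one reaction into its per-product-subset EMU identities.

    Emits ``sum over products of (2**n_p - 1)`` identities.  For a
    product subset ``S``, the reagent-side factors are the origin atoms
    of ``S`` grouped by reagent occurrence; factors are ordered
    canonically by (metabolite, atom set, occurrence) so the output is
    independent of how reagents and products were listed.
    """
    out: list[Identity] = []
    for met, labels in reaction.products:
        n_p = len(labels)
        positions = range(1, n_p + 1)
        for k in range(1, n_p + 1):
            for subset in itertools.combinations(positions, k):
                origins = [reaction.origin_of(labels[p - 1]) for p in subset]
                groups: dict[int, list[int]] = {}
                for ri, q in origins:
                    groups.setdefault(ri, []).append(q)
                ordered = sorted(
                    groups.items(),
                    key=lambda item: (
                        reaction.reagents[item[0]][0],
                        tuple(sorted(item[1])),
                        item[0],
                    ),
                )
                factors = tuple(
                    EMUKey(reaction.reagents[ri][0], tuple(sorted(qs)))
                    for ri, qs in ordered
                )
                factor_index = {ri: fi for fi, (ri, _) in enumerate(ordered)}
                atom_map = tuple(
                    (factor_index[ri], sorted(groups[ri]).index(q))
                    for ri, q in origins
                )
                out.append(Identity(EMUKey(met, subset), reaction.flux_id, factors, atom_map))
    return out


def decompose_network(
    reactions: Iterable[Reaction],
    targets: Sequence[EMUKey] | None = None,
) -> IdentitySystem:
    """Union of per-reaction identities, optionally pruned to targets.

    With ``targets`` the system is restricted to the backward-reachable
    closure: every identity transitively needed to define the targets.
    The closure EMU set (targets, intermediate lhs keys, and terminal
    source EMUs) is recorded on the returned system.  A target that no
    reaction produces raises :class:`UnresolvableEMUError`.
    """
    all_identities = list(
        dict.fromkeys(ident for rxn in reactions for ident in decompose_reaction(rxn))
    )
    if targets is None:
        return IdentitySystem(tuple(all_identities))
    by_lhs: dict[EMUKey, list[Identity]] = {}
    for ident in all_identities:
        by_lhs.setdefault(ident.lhs, []).append(ident)
    closure: set[EMUKey] = set()
    kept: list[Identity] = []
    stack = list(targets)
    for t in targets:
        if t not in by_lhs:
            raise UnresolvableEMUError(t)
    visited: set[EMUKey] = set()
    while stack:
        key = stack.pop()
        if key in visited:
            continue
        visited.add(key)
        closure.add(key)
        for ident in by_lhs.get(key, ()):
            kept.append(ident)
            for factor in ident.rhs_factors:
                closure.add(factor)
                if factor in by_lhs:
                    stack.append(factor)
    ordered = [i for i in all_identities if i in set(kept)]
    return IdentitySystem(tuple(ordered), closure=frozenset(closure))
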