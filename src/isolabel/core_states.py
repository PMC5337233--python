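"""Moiety specifications and enumeration of labeling state spaces.

A *moiety* is an ordered list of isotopic atoms, each belonging to a
tracer element whose isotopes are distinguished by their number of
additional neutrons (the *mass shift*).  For a moiety of ``n`` atoms
with moiety-wide greatest shift ``m``:

* an **isotopomer** assigns a determinate shift in ``{0..m}`` to every
  atom -- there are ``(m+1)**n`` of them;
* a **cumomer** assigns each atom either a determinate shift or the
  indeterminate state ``TOP`` (the disjunction of all determinate
  states) -- ``(m+2)**n`` of them.  Conceptually a cumomer lives in an
  infinite virtual moiety whose non-local atoms are all ``TOP``; only
  the local prefix is stored, the ``TOP`` tail being information-free;
* the cumomer set partitions into ``2**n`` **EMU blocks**, one per
  subset ``N`` of atom positions, containing the cumomers determinate
  exactly on ``N``.

Index conventions (fixed throughout the package): atoms are 1-based;
state vectors are encoded as mixed-radix integers with atom 1 the most
significant digit; determinate states are ordered ascending ``0 < 1 <
... < m`` with ``TOP`` ordered after all determinate states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping


class _Sentinel:
    """Singleton labeling-state sentinel (``TOP`` or ``BOTTOM``)."""

    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name

    def __reduce__(self):
        return (_resolve_sentinel, (self._name,))


#: Indeterminate labeling state: the disjunction of every determinate state.
TOP = _Sentinel("TOP")
#: Contradiction: the conjunction of two distinct determinate states.
#: Never stored in fraction vectors; produced only by the state logic.
BOTTOM = _Sentinel("BOTTOM")


def _resolve_sentinel(name: str) -> _Sentinel:
    return TOP if name == "TOP" else BOTTOM


LabelState = "int | _Sentinel"  # determinate shift, TOP, or BOTTOM


@dataclass(frozen=True)
class ElementSpec:
    """A tracer element: symbol plus its greatest additional-neutron number."""

    symbol: str
    max_shift: int

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("element symbol must be non-empty")
        if self.max_shift < 0:
            raise ValueError(f"max_shift must be >= 0, got {self.max_shift}")


@dataclass(frozen=True)
class MoietySpec:
    """Ordered atom layout of a moiety.

    ``m`` is moiety-wide: the maximum of the atoms' own ``max_shift``
    values (0 for the empty moiety).  States exceeding an individual
    atom's own ``max_shift`` are representable but undetectable; valid
    fraction vectors assign them probability 0 (see
    :func:`isolabel.fraction_convert.FractionVector.validate`).
    """

    metabolite_id: str
    atoms: tuple[ElementSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def n(self) -> int:
        return len(self.atoms)

    @property
    def m(self) -> int:
        return max((a.max_shift for a in self.atoms), default=0)

    def restrict(self, atom_set: Iterable[int]) -> "MoietySpec":
        """Sub-moiety over the given 1-based atom positions (sorted)."""
        positions = sorted(set(atom_set))
        for i in positions:
            if not 1 <= i <= self.n:
                raise ValueError(f"atom position {i} outside [1, {self.n}]")
        return MoietySpec(self.metabolite_id, tuple(self.atoms[i - 1] for i in positions))

    @classmethod
    def homonuclear(cls, metabolite_id: str, n: int, m: int, symbol: str = "C") -> "MoietySpec":
        return cls(metabolite_id, tuple(ElementSpec(symbol, m) for _ in range(n)))


@dataclass(frozen=True)
class Isotopomer:
    """Fully determinate labeling state of a moiety."""

    states: tuple[int, ...]
    spec: MoietySpec

    def __post_init__(self) -> None:
        m = self.spec.m
        for s in self.states:
            if not isinstance(s, int) or not 0 <= s <= m:
                raise ValueError(f"isotopomer state {s!r} outside [0, {m}]")
        if len(self.states) != self.spec.n:
            raise ValueError("state vector length differs from atom count")

    @property
    def index(self) -> int:
        """Mixed-radix encoding, base ``m + 1``, atom 1 most significant."""
        return states_to_index(self.states, self.spec.m + 1)

    @property
    def total_shift(self) -> int:
        return sum(self.states)


@dataclass(frozen=True)
class Cumomer:
    """Labeling state with each atom determinate or ``TOP``.

    Only the local ``n`` positions are stored; every position beyond
    ``n`` is ``TOP`` by construction.
    """

    states: tuple
    spec: MoietySpec

    def __post_init__(self) -> None:
        m = self.spec.m
        for s in self.states:
            if s is not TOP and (not isinstance(s, int) or not 0 <= s <= m):
                raise ValueError(f"cumomer state {s!r} not in [0, {m}] or TOP")
        if len(self.states) != self.spec.n:
            raise ValueError("state vector length differs from atom count")

    @property
    def determinate_set(self) -> frozenset[int]:
        """1-based positions carrying a determinate state."""
        return frozenset(i + 1 for i, s in enumerate(self.states) if s is not TOP)

    @property
    def index(self) -> int:
        """Mixed-radix encoding, base ``m + 2``, with ``TOP`` = ``m + 1``."""
        m = self.spec.m
        digits = tuple(m + 1 if s is TOP else s for s in self.states)
        return states_to_index(digits, m + 2)


@dataclass(frozen=True, order=True)
class EMUKey:
    """A metabolite together with a subset of its 1-based atom positions.

    The empty atom set is the identity of the EMU monoid; it is legal as
    a standalone key but never appears inside reaction identities.
    """

    metabolite_id: str
    atom_set: tuple[int, ...]

    def __post_init__(self) -> None:
        atoms = tuple(sorted(set(self.atom_set)))
        if any(a < 1 for a in atoms):
            raise ValueError("atom positions are 1-based")
        object.__setattr__(self, "atom_set", atoms)

    @property
    def size(self) -> int:
        return len(self.atom_set)

    def __str__(self) -> str:
        return f"{self.metabolite_id}{{{','.join(map(str, self.atom_set))}}}"


def states_to_index(digits: tuple[int, ...], base: int) -> int:
    idx = 0
    for d in digits:
        idx = idx * base + d
    return idx


def index_to_states(index: int, base: int, n: int) -> tuple[int, ...]:
    if not 0 <= index < base**n:
        raise ValueError(f"index {index} outside [0, {base}^{n})")
    digits = []
    for _ in range(n):
        index, d = divmod(index, base)
        digits.append(d)
    return tuple(reversed(digits))


def enumerate_isotopomers(spec: MoietySpec) -> list[Isotopomer]:
    """All ``(m+1)**n`` isotopomers in ascending mixed-radix index order."""
    m = spec.m
    return [
        Isotopomer(states, spec)
        for states in itertools.product(range(m + 1), repeat=spec.n)
    ]


def enumerate_cumomers(spec: MoietySpec, punctured_at: int | None = None) -> list[Cumomer]:
    """All cumomers of the moiety, determinate states ascending, ``TOP`` last.

    Without puncture the per-atom alphabet is ``{0..m, TOP}`` giving
    ``(m+2)**n`` cumomers.  With ``punctured_at = s`` the determinate
    state ``s`` is excluded, giving the ``(m+1)**n`` punctured cumomers
    over ``({0..m} \\ {s}) | {TOP}``; the classical (Wiechert) cumomers
    are the puncture at ``s = 0``.
    """
    m = spec.m
    if punctured_at is None:
        alphabet: tuple = tuple(range(m + 1)) + (TOP,)
    else:
        if not 0 <= punctured_at <= m:
            raise ValueError(f"punctured_at={punctured_at} outside [0, {m}]")
        alphabet = tuple(s for s in range(m + 1) if s != punctured_at) + (TOP,)
    return [Cumomer(states, spec) for states in itertools.product(alphabet, repeat=spec.n)]


def emu_partition(spec: MoietySpec) -> dict[EMUKey, list[Cumomer]]:
    """Partition the cumomer set into its ``2**n`` EMU blocks.

    The block keyed by atom set ``N`` holds exactly the ``(m+1)**|N|``
    cumomers determinate on ``N`` and ``TOP`` elsewhere.  Blocks are
    returned in (size, atom-set) order, the empty set first.
    """
    m = spec.m
    blocks: dict[EMUKey, list[Cumomer]] = {}
    positions = range(1, spec.n + 1)
    subsets = sorted(
        (tuple(c) for k in range(spec.n + 1) for c in itertools.combinations(positions, k)),
        key=lambda t: (len(t), t),
    )
    for subset in subsets:
        key = EMUKey(spec.metabolite_id, subset)
        block = []
        for combo in itertools.product(range(m + 1), repeat=len(subset)):
            states: list = [TOP] * spec.n
            for pos, s in zip(subset, combo):
                states[pos - 1] = s
            block.append(Cumomer(tuple(states), spec))
        blocks[key] = block
    return blocks


def load_element_config(mapping: Mapping[str, int]) -> dict[str, ElementSpec]:
    """Build element specs from a ``{symbol: max_shift}`` mapping.

    This is the in-memory form of the YAML tracer configuration
    (``elements: {C: 1, N: 1, H: 2}``).
    """
    specs = {}
    for symbol, max_shift in mapping.items():
        if symbol in specs:
            raise ValueError(f"duplicate element symbol {symbol!r}")
        specs[symbol] = ElementSpec(str(symbol), int(max_shift))
    return specs
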