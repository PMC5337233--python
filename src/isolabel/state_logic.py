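"""Multi-valued logic of isotopic labeling states.

The set ``{0..m} | {TOP, BOTTOM}`` is closed under logical conjunction:
``TOP`` (indeterminate) is the identity, ``BOTTOM`` (contradiction) is
absorbing, and two *distinct* determinate states conjoin to ``BOTTOM``
-- the determinate states are mutually contradictory distinguished
elements, identified with neither logical true nor false.  Conjunction
of cumomers is pointwise and is defined (non-``BOTTOM``) exactly for
pairs that are positionwise equal, or determinate against
indeterminate.  Disjunction of disjoint labeling events corresponds to
addition of the matching fractions.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .core_states import BOTTOM, TOP, Cumomer, _Sentinel

#: Marker returned by :func:`conjoin_cumomers` when any position is
#: contradictory; ``None`` is deliberately not used so callers can
#: distinguish "undefined" from "absent".
UNDEFINED = _Sentinel("UNDEFINED")


def conjoin_states(a, b):
    """Conjoin two labeling states (determinate int, ``TOP`` or ``BOTTOM``).

    ``TOP`` is the identity; ``BOTTOM`` absorbs; equal states are
    idempotent; distinct determinate states are contradictory.
    """
    if a is BOTTOM or b is BOTTOM:
        return BOTTOM
    if a is TOP:
        return b
    if b is TOP:
        return a
    return a if a == b else BOTTOM


def conjoin_cumomers(a: Cumomer, b: Cumomer):
    """Pointwise conjunction of two cumomers over the same moiety.

    Returns the conjoined :class:`Cumomer`, or :data:`UNDEFINED` if any
    position is contradictory.  When the two cumomers are determinate
    on disjoint atom sets, the fraction of the result is the product of
    the operand fractions (labeling independence across atoms).
    """
    if a.spec != b.spec:
        raise ValueError(
            f"cumomers over different moieties: {a.spec.metabolite_id!r} vs {b.spec.metabolite_id!r}"
        )
    states = tuple(conjoin_states(x, y) for x, y in zip(a.states, b.states))
    if any(s is BOTTOM for s in states):
        return UNDEFINED
    return Cumomer(states, a.spec)


def disjoin_fractions(fractions: Iterable[float]) -> float:
    """Disjunction of mutually exclusive labeling events: fraction sum."""
    total = 0.0
    for f in fractions:
        if not 0.0 <= f <= 1.0 + 1e-12:
            raise ValueError(f"fraction {f} outside [0, 1]")
        total += f
    return total


def logic_elements(m: int) -> tuple:
    """The carrier ``{0..m} | {TOP, BOTTOM}``, determinate first."""
    return tuple(range(m + 1)) + (TOP, BOTTOM)


def cayley_table(m: int) -> dict:
    """Full conjunction Cayley table over :func:`logic_elements`."""
    elems = logic_elements(m)
    return {(a, b): conjoin_states(a, b) for a in elems for b in elems}


def is_closed(subset: Sequence) -> bool:
    """Whether a subset of logic values is closed under conjunction."""
    pool = list(subset)
    return all(conjoin_states(a, b) in pool for a in pool for b in pool)
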