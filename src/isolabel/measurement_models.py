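"""Measurement models: high-/low-resolution MS and NMR splitting integrals.

High-resolution MS of a heteronuclear fragment (an EMU) resolves the
mass shift contributed by each tracer element separately, yielding a
joint probability tensor with one axis per element.  Low-resolution MS
only sees the total shift: summing the tensor's anti-diagonals (all
per-element shift combinations with the same total) collapses it to
the ordinary mass distribution -- the same arithmetic as applying the
isotopomer-to-mass matrix directly.

An NMR splitting-pattern integral is the conditional probability of a
detected labeling pattern given the state of the observed nucleus,
which reduces to a quotient of two EMU isotopomer fractions: the
pattern disjunction over ``{observed} | detected`` divided by the
observed atom's fraction.  Indistinguishable detected nuclei expand to
the "at least one in the detected state" disjunction.  Observed and
detected nuclei need not be bonded; queries take arbitrary atom
positions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import deconvolve

from .core_states import EMUKey, MoietySpec, index_to_states
from .cascade_solver import LabelingSolution, emu_isotopomer_from_joint
from .fraction_convert import FractionVector, im_matrix


class ZeroConditionalError(ZeroDivisionError):
    """The conditioning (observed-state) probability is zero."""


@dataclass(frozen=True)
class MassTensor:
    """Joint per-element mass-shift probabilities of one EMU.

    One axis per distinct element, in order of first appearance among
    the EMU's atoms; axis length is that element's greatest achievable
    total shift plus one.
    """

    elements: tuple[str, ...]
    values: np.ndarray
    spec: MoietySpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != len(self.elements):
            raise ValueError("tensor rank must equal the number of elements")

    def total(self) -> float:
        return float(self.values.sum())


def high_res_tensor(emu: EMUKey | None, fractions: FractionVector) -> MassTensor:
    """Joint per-element mass tensor of an EMU's isotopomer fractions.

    ``fractions`` is an isotopomer vector over the EMU's (restricted)
    moiety; ``emu`` is carried along for provenance only and may be
    omitted.  For a homonuclear EMU the tensor has a single axis and
    equals the isotopomer-to-mass projection.
    """
    if fractions.interpretation != "isotopomer":
        raise ValueError("high_res_tensor expects an isotopomer fraction vector")
    fractions.validate()
    spec = fractions.spec
    elements = []
    for atom in spec.atoms:
        if atom.symbol not in elements:
            elements.append(atom.symbol)
    shape = tuple(
        sum(a.max_shift for a in spec.atoms if a.symbol == e) + 1 for e in elements
    )
    out = np.zeros(shape if shape else ())
    base = spec.m + 1
    axis = {e: i for i, e in enumerate(elements)}
    for idx, val in enumerate(fractions.values):
        if not val:
            continue
        states = index_to_states(idx, base, spec.n)
        coord = [0] * len(elements)
        for atom, s in zip(spec.atoms, states):
            coord[axis[atom.symbol]] += s
        out[tuple(coord)] += val
    return MassTensor(tuple(elements), out, spec)


def collapse_tensor(tensor: MassTensor) -> FractionVector:
    """Low-resolution collapse: sum the anti-diagonals of the tensor.

    Entry ``j`` of the result is the probability of total shift ``j``
    regardless of which element contributed; equivalent to applying
    the isotopomer-to-mass matrix to the underlying isotopomer vector.
    """
    spec = tensor.spec
    out = np.zeros(spec.n * spec.m + 1)
    for coord, val in np.ndenumerate(tensor.values):
        out[sum(coord)] += val
    return FractionVector("mass", out, spec)


@dataclass(frozen=True)
class NMRQuery:
    """One splitting-pattern integral request.

    ``observed`` is the (1-based) conditioning atom, fixed at
    ``observed_state``; ``detected`` are the atoms whose labeling is
    read out (required at ``detected_state``); ``equivalence_groups``
    are disjoint subsets of ``detected`` that are indistinguishable, so
    the readout is "at least one of the group at the detected state".
    """

    metabolite: str
    observed: int
    detected: tuple[int, ...]
    observed_state: int = 1
    detected_state: int = 1
    equivalence_groups: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "detected", tuple(sorted(set(self.detected))))
        groups = tuple(tuple(sorted(set(g))) for g in self.equivalence_groups)
        object.__setattr__(self, "equivalence_groups", groups)
        if self.observed in self.detected:
            raise ValueError("observed atom may not be in the detected set")
        flat = [a for g in groups for a in g]
        if len(flat) != len(set(flat)):
            raise ValueError("equivalence groups must be disjoint")
        if not set(flat) <= set(self.detected):
            raise ValueError("equivalence groups must be subsets of the detected set")
        if not self.detected:
            raise ValueError("detected set may not be empty")


def nmr_splitting_integral(query: NMRQuery, source) -> float:
    """Conditional probability of the queried splitting pattern.

    ``source`` supplies EMU isotopomer fractions: either a full
    isotopomer :class:`FractionVector` of the metabolite (marginalised
    as needed), a mapping of :class:`EMUKey` to isotopomer vectors, or
    a :class:`LabelingSolution` produced with the boolean
    interpretation.  Raises :class:`ZeroConditionalError` when the
    observed state has zero probability.
    """
    atoms = tuple(sorted((query.observed,) + query.detected))
    num_key = EMUKey(query.metabolite, atoms)
    den_key = EMUKey(query.metabolite, (query.observed,))
    num_vec = _emu_vector(source, num_key)
    den_vec = _emu_vector(source, den_key)

    denominator = float(den_vec.values[query.observed_state])
    if denominator <= 0.0:
        raise ZeroConditionalError(
            f"P({query.metabolite} atom {query.observed} = {query.observed_state}) = 0"
        )

    grouped = {a for g in query.equivalence_groups for a in g}
    base = num_vec.spec.m + 1
    position = {a: i for i, a in enumerate(atoms)}
    numerator = 0.0
    for idx, val in enumerate(num_vec.values):
        states = index_to_states(idx, base, len(atoms))
        if states[position[query.observed]] != query.observed_state:
            continue
        if any(
            states[position[a]] != query.detected_state
            for a in query.detected
            if a not in grouped
        ):
            continue
        if any(
            all(states[position[a]] != query.detected_state for a in group)
            for group in query.equivalence_groups
        ):
            continue
        numerator += float(val)
    return numerator / denominator


def _emu_vector(source, key: EMUKey) -> FractionVector:
    if isinstance(source, FractionVector):
        if source.interpretation != "isotopomer":
            raise ValueError("NMR queries need isotopomer (positional) fractions")
        return emu_isotopomer_from_joint(source, key.atom_set)
    if isinstance(source, LabelingSolution):
        if source.interpretation != "boolean":
            raise ValueError(
                "a mass-interpretation solution cannot answer NMR queries; "
                "solve with interpretation='boolean' or pass isotopomer vectors"
            )
        if key not in source:
            raise KeyError(f"solution does not contain EMU {key}")
        return source[key]
    if key in source:
        fv = source[key]
        if fv.interpretation != "isotopomer":
            raise ValueError("NMR queries need isotopomer (positional) fractions")
        return fv
    raise KeyError(f"no fractions available for EMU {key}")


def correct_derivatization(
    measured: np.ndarray, agent: np.ndarray, tol: float = 1e-9
) -> np.ndarray:
    """Deconvolve a derivatization agent's mass distribution from a measured one.

    The measured fragment distribution of a derivatized analyte is the
    convolution of the underivatized distribution with the agent's;
    polynomial deconvolution inverts that.  Noisy data can produce
    small negative entries or a nonzero remainder: entries are clipped
    at zero and the vector renormalized, with a warning.
    """
    measured = np.asarray(measured, dtype=float)
    agent = np.asarray(agent, dtype=float)
    if agent[0] == 0:
        raise ValueError("agent mass distribution must have nonzero M+0 entry")
    quotient, remainder = deconvolve(measured, agent)
    if np.any(quotient < -tol) or np.max(np.abs(remainder)) > tol:
        warnings.warn(
            "deconvolution left negative entries or a remainder; clipping and "
            "renormalizing",
            UserWarning,
            stacklevel=2,
        )
    out = np.clip(quotient, 0.0, None)
    total = out.sum()
    if total <= 0:
        raise ValueError("deconvolved distribution has no positive mass")
    return out / total
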