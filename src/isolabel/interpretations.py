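"""Monoidal interpretations of EMU labeling states.

Combining two EMUs with disjoint atom sets is a monoidal product whose
concrete form depends on the chosen interpretation:

* **mass distributions** combine by discrete convolution (total shifts
  add);
* **Boolean-function fraction vectors** (isotopomer vectors over the
  EMU's atoms) combine by the Cartesian product under multiplication
  (joint labeling of independent disjoint atom sets);
* **atom counts** combine by integer addition.

Each interpretation is a commutative monoid whose identity is the image
of the trivial (empty) EMU, and the map from disjoint atom sets to the
interpretation is a homomorphism: interpreting a disjoint union equals
combining the interpretations.
"""

from __future__ import annotations

import numpy as np

from .core_states import EMUKey, ElementSpec, MoietySpec
from .fraction_convert import FractionVector

#: Mass-distribution image of the trivial EMU (delta at shift 0).
MASS_IDENTITY = np.array([1.0])
#: Boolean-function image of the trivial EMU (the single empty pattern).
BOOLEAN_IDENTITY = np.array([1.0])


def convolve(a, b):
    """Monoidal product of two mass distributions: discrete convolution.

    Accepts plain arrays or mass :class:`FractionVector` objects.  For
    arrays the output length is ``len(a) + len(b) - 1``.  For fraction
    vectors the combined moiety is the concatenation of the two atom
    lists and the result is zero-padded up to that moiety's nominal
    mass-vector length (the padding entries are surplus shifts, which
    can only be structurally zero when the moiety is heteronuclear with
    unequal per-element shifts).
    """
    if isinstance(a, FractionVector) or isinstance(b, FractionVector):
        if a.interpretation != "mass" or b.interpretation != "mass":
            raise ValueError("convolve expects mass fraction vectors")
        spec = MoietySpec(
            f"{a.spec.metabolite_id}*{b.spec.metabolite_id}",
            a.spec.atoms + b.spec.atoms,
        )
        raw = np.convolve(a.values, b.values)
        out = np.zeros(spec.n * spec.m + 1)
        out[: len(raw)] = raw
        return FractionVector("mass", out, spec)
    return np.convolve(np.asarray(a, dtype=float), np.asarray(b, dtype=float))


def boolean_product(
    a: FractionVector,
    b: FractionVector,
    key_a: EMUKey | None = None,
    key_b: EMUKey | None = None,
) -> FractionVector:
    """Monoidal product of two Boolean-function (isotopomer) vectors.

    The operands must describe EMUs over disjoint atom sets.  When the
    EMU keys are supplied (and belong to the same metabolite) the
    result is ordered by the sorted union of the atom positions and
    overlap raises; otherwise the atoms of ``a`` simply precede those
    of ``b``.  Entry for a combined pattern is the product of the
    operand entries, so the result sums to 1 whenever the operands do.
    """
    for v in (a, b):
        if v.interpretation != "isotopomer":
            raise ValueError("boolean_product expects isotopomer fraction vectors")
    if key_a is not None and key_b is not None:
        if len(key_a.atom_set) != a.spec.n or len(key_b.atom_set) != b.spec.n:
            raise ValueError("EMU key size does not match fraction vector moiety")
        if key_a.metabolite_id == key_b.metabolite_id and set(key_a.atom_set) & set(
            key_b.atom_set
        ):
            raise ValueError(
                f"overlapping atom sets {key_a} and {key_b}: conjunction is "
                "undefined for conflicting determinate states"
            )
        tagged = sorted(
            [((key_a.metabolite_id, p), "a", i) for i, p in enumerate(key_a.atom_set)]
            + [((key_b.metabolite_id, p), "b", i) for i, p in enumerate(key_b.atom_set)]
        )
        order = [(src, i) for _, src, i in tagged]
    else:
        order = [("a", i) for i in range(a.spec.n)] + [("b", i) for i in range(b.spec.n)]

    atoms = tuple(
        (a.spec.atoms if src == "a" else b.spec.atoms)[i] for src, i in order
    )
    met = a.spec.metabolite_id
    if b.spec.metabolite_id != met:
        met = f"{a.spec.metabolite_id}*{b.spec.metabolite_id}"
    spec = MoietySpec(met, atoms)
    base = spec.m + 1

    ta = _embed_tensor(a, base)
    tb = _embed_tensor(b, base)
    joint = np.multiply.outer(ta, tb)  # axes: a atoms then b atoms
    src_axis = {("a", i): i for i in range(a.spec.n)}
    src_axis.update({("b", i): a.spec.n + i for i in range(b.spec.n)})
    joint = np.transpose(joint, [src_axis[tag] for tag in order])
    return FractionVector("isotopomer", joint.reshape(-1), spec)


def _embed_tensor(v: FractionVector, base: int) -> np.ndarray:
    """Reshape an isotopomer vector to a tensor in a (possibly larger) base."""
    own = v.spec.m + 1
    t = v.values.reshape((own,) * v.spec.n) if v.spec.n else v.values.reshape(())
    if own == base or v.spec.n == 0:
        return t
    out = np.zeros((base,) * v.spec.n)
    out[np.ix_(*[range(own)] * v.spec.n)] = t
    return out


def atom_count(key: EMUKey) -> int:
    """Scalar interpretation of an EMU: its number of atoms.

    A homomorphism into the naturals under addition: the count of a
    disjoint union is the sum of the counts.
    """
    return key.size
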