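"""Conversion matrices and fraction-vector transforms.

Three families of exact 0/1 matrices connect the coordinate systems:

* ``IC(n, m)`` -- isotopomer to cumomer fractions: the ``n``-fold
  Kronecker power of the ``(m+2) x (m+1)`` block formed by stacking the
  identity of size ``m+1`` over a single all-ones row (the ``TOP``
  row).  Rectangular, hence non-invertible.
* ``IC_punctured(n, m, s)`` -- isotopomer to punctured-cumomer
  fractions: delete the row of the single-atom block belonging to the
  determinate state ``s`` before taking the Kronecker power.  Always
  square and invertible; for ``m = 1, s = 0`` this is the binary
  Reed-Muller transform pattern.
* ``IM(n, m)`` -- isotopomer to mass fractions: row ``j`` selects the
  isotopomer columns of total shift ``j`` (exactly one 1 per column).

Mass to isotopomer is *not* a faithful conversion -- the mass
distribution forgets atom positions -- and is deliberately not offered;
:func:`pseudoinverse_demo` exposes the Moore-Penrose minimum-norm
preimage for diagnostic purposes only.

Matrices carry exact integer entries; only the fraction data are
floating point (validation tolerance 1e-9, configurable per call).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.io import mmwrite

from .core_states import (
    TOP,
    MoietySpec,
    index_to_states,
)

DEFAULT_TOL = 1e-9

INTERPRETATIONS = ("isotopomer", "cumomer", "punctured", "mass")

#: Default puncture: the Wiechert-compatible cumomer coordinates.
DEFAULT_PUNCTURE = 0


class ConversionPathError(ValueError):
    """Requested conversion has no faithful matrix representation."""


class UnfaithfulConversionWarning(UserWarning):
    """Signals a pseudoinverse preimage that is not the true vector."""


@dataclass(frozen=True)
class ConversionMatrix:
    """An exact integer conversion matrix with its construction parameters."""

    kind: str  # "IC" | "IC_punctured" | "IM"
    n: int
    m: int
    entries: np.ndarray
    puncture: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", np.asarray(self.entries, dtype=np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


def _ic_block(m: int) -> np.ndarray:
    """Single-atom isotopomer->cumomer block: I_{m+1} over an all-ones row."""
    return np.vstack([np.eye(m + 1, dtype=np.int64), np.ones((1, m + 1), dtype=np.int64)])


def _kron_power(block: np.ndarray, n: int) -> np.ndarray:
    out = np.ones((1, 1), dtype=np.int64)
    for _ in range(n):
        out = np.kron(out, block)
    return out


def ic_matrix(n: int, m: int) -> ConversionMatrix:
    """Isotopomer -> cumomer conversion matrix, shape ``(m+2)**n x (m+1)**n``.

    Rows are cumomers in mixed-radix order (``TOP`` last per atom),
    columns isotopomers in mixed-radix order.
    """
    if n < 0 or m < 0:
        raise ValueError("n and m must be non-negative")
    # m = 0 is degenerate: with a single isotope the indeterminate state
    # coincides with the sole determinate state, so the duplicated TOP row
    # collapses and the conversion is trivial.
    block = np.ones((1, 1), dtype=np.int64) if m == 0 else _ic_block(m)
    return ConversionMatrix("IC", n, m, _kron_power(block, n))


def punctured_matrix(n: int, m: int, s: int = DEFAULT_PUNCTURE) -> ConversionMatrix:
    """Isotopomer -> punctured-cumomer (Reed-Muller) matrix, square ``(m+1)**n``.

    Obtained by removing the row of the determinate state ``s`` from the
    single-atom isotopomer->cumomer block and taking the ``n``-fold
    Kronecker power; invertible for every valid ``s``.
    """
    if n < 0 or m < 0:
        raise ValueError("n and m must be non-negative")
    if not 0 <= s <= m:
        raise ValueError(f"puncture s={s} outside [0, {m}]")
    block = np.delete(_ic_block(m), s, axis=0)
    return ConversionMatrix("IC_punctured", n, m, _kron_power(block, n), puncture=s)


def im_matrix(n: int, m: int) -> ConversionMatrix:
    """Isotopomer -> mass-fraction matrix, shape ``(n*m + 1) x (m+1)**n``.

    Entry ``(j, idx(a)) = 1`` iff the isotopomer ``a`` has total mass
    shift ``j``; every column holds exactly one 1, so mass vectors
    inherit the unit sum of isotopomer vectors.
    """
    if n < 0 or m < 0:
        raise ValueError("n and m must be non-negative")
    ncols = (m + 1) ** n
    out = np.zeros((n * m + 1, ncols), dtype=np.int64)
    for idx in range(ncols):
        shift = sum(index_to_states(idx, m + 1, n))
        out[shift, idx] = 1
    return ConversionMatrix("IM", n, m, out)


@dataclass(frozen=True)
class FractionVector:
    """A probability vector over one labeling-state interpretation.

    ``interpretation`` is one of ``isotopomer`` (length ``(m+1)**n``,
    sums to 1), ``cumomer`` (length ``(m+2)**n``, sums to ``2**n`` with
    every EMU block summing to 1), ``punctured`` (length ``(m+1)**n``,
    carries the puncture state ``s``) or ``mass`` (length ``n*m + 1``,
    sums to 1).
    """

    interpretation: str
    values: np.ndarray
    spec: MoietySpec
    puncture: int | None = None

    def __post_init__(self) -> None:
        if self.interpretation not in INTERPRETATIONS:
            raise ValueError(f"unknown interpretation {self.interpretation!r}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.interpretation == "punctured" and self.puncture is None:
            object.__setattr__(self, "puncture", DEFAULT_PUNCTURE)

    # -- validation ----------------------------------------------------

    def expected_length(self) -> int:
        n, m = self.spec.n, self.spec.m
        return {
            "isotopomer": (m + 1) ** n,
            # m = 0 degenerates: TOP coincides with the sole determinate state
            "cumomer": (m + 2) ** n if m > 0 else 1,
            "punctured": (m + 1) ** n,
            "mass": n * m + 1,
        }[self.interpretation]

    def validate(self, tol: float = DEFAULT_TOL) -> "FractionVector":
        """Check lengths, ranges, sum rules and the surplus-state rule.

        Returns ``self`` so validation can be chained.  The surplus-state
        rule: in a heteronuclear moiety, states exceeding an individual
        atom's own greatest shift are undetectable and must carry
        probability 0 (checked for isotopomer and cumomer vectors).
        """
        v = self.values
        if v.ndim != 1 or len(v) != self.expected_length():
            raise ValueError(
                f"{self.interpretation} vector for n={self.spec.n}, m={self.spec.m} "
                f"must have length {self.expected_length()}, got {v.shape}"
            )
        if np.any(v < -tol):
            raise ValueError("fraction vector has negative entries")
        n, m = self.spec.n, self.spec.m
        if self.interpretation == "cumomer" and m > 0:
            if abs(v.sum() - 2**n) > tol * max(1, 2**n):
                raise ValueError(f"cumomer vector sums to {v.sum()}, expected {2**n}")
            for block in _emu_block_indices(n, m).values():
                s = v[block].sum()
                if abs(s - 1.0) > tol:
                    raise ValueError(f"EMU cumomer block sums to {s}, expected 1")
        elif self.interpretation != "punctured":
            if abs(v.sum() - 1.0) > tol:
                raise ValueError(f"{self.interpretation} vector sums to {v.sum()}, expected 1")
        if self.interpretation in ("isotopomer", "cumomer"):
            self._check_surplus_states(tol)
        return self

    def _check_surplus_states(self, tol: float) -> None:
        m = self.spec.m
        caps = [a.max_shift for a in self.spec.atoms]
        if all(c == m for c in caps):
            return
        base = (m + 1) if self.interpretation == "isotopomer" else (m + 2)
        for idx, val in enumerate(self.values):
            states = index_to_states(idx, base, self.spec.n)
            surplus = any(
                s <= m and s > cap  # digit m+1 encodes TOP in cumomer vectors
                for s, cap in zip(states, caps)
            )
            if surplus and abs(val) > tol:
                raise ValueError(
                    f"surplus labeling state at index {idx} carries probability {val}"
                )

    # -- labels and serialisation -------------------------------------

    def labels(self) -> list[str]:
        """Human-readable state labels matching the index order."""
        n, m = self.spec.n, self.spec.m
        if self.interpretation == "mass":
            return [f"M+{j}" for j in range(n * m + 1)]
        if self.interpretation == "isotopomer":
            alphabet: list = list(range(m + 1))
        elif self.interpretation == "cumomer":
            alphabet = list(range(m + 1)) + [TOP]
        else:
            alphabet = [s for s in range(m + 1) if s != self.puncture] + [TOP]
        out = []
        base = len(alphabet)
        for idx in range(self.expected_length()):
            digits = index_to_states(idx, base, n)
            out.append(",".join("⊤" if alphabet[d] is TOP else str(alphabet[d]) for d in digits))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"state": self.labels(), "fraction": self.values})


def _emu_block_indices(n: int, m: int) -> dict[tuple[int, ...], np.ndarray]:
    """Cumomer-vector index arrays for each EMU block, keyed by atom set."""
    import itertools

    blocks: dict[tuple[int, ...], list[int]] = {}
    for idx in range((m + 2) ** n):
        states = index_to_states(idx, m + 2, n)
        det = tuple(i + 1 for i, s in enumerate(states) if s != m + 1)
        blocks.setdefault(det, []).append(idx)
    return {k: np.asarray(v) for k, v in blocks.items()}


def convert(
    v: FractionVector,
    target: str,
    puncture: int = DEFAULT_PUNCTURE,
    tol: float = DEFAULT_TOL,
) -> FractionVector:
    """Convert a fraction vector to another interpretation.

    Faithful paths: isotopomer -> {cumomer, punctured, mass} and
    punctured -> isotopomer (exact inverse of the Reed-Muller matrix).
    Mass -> isotopomer is refused: the mass distribution is a lossy
    projection (see :func:`pseudoinverse_demo` for the minimum-norm
    preimage and why it is not the answer).
    """
    v.validate(tol)
    n, m = v.spec.n, v.spec.m
    src = v.interpretation
    if src == target and (target != "punctured" or puncture == v.puncture):
        return v
    if src == "isotopomer":
        if target == "cumomer":
            out = ic_matrix(n, m).entries @ v.values
        elif target == "punctured":
            out = punctured_matrix(n, m, puncture).entries @ v.values
        elif target == "mass":
            out = im_matrix(n, m).entries @ v.values
        else:
            raise ConversionPathError(f"no conversion isotopomer -> {target!r}")
        return FractionVector(target, out, v.spec, puncture if target == "punctured" else None)
    if src == "punctured" and target == "isotopomer":
        mat = punctured_matrix(n, m, v.puncture).entries.astype(float)
        out = np.linalg.solve(mat, v.values)
        return FractionVector("isotopomer", out, v.spec)
    if src == "mass":
        raise ConversionPathError(
            "mass is a non-invertible interpretation: the mass distribution "
            "forgets atom positions, so mass -> isotopomer has no faithful "
            "matrix; see pseudoinverse_demo for the minimum-norm preimage"
        )
    raise ConversionPathError(f"no conversion {src!r} -> {target!r}")


def pseudoinverse_demo(mass: FractionVector, tol: float = DEFAULT_TOL) -> FractionVector:
    """Moore-Penrose preimage of a mass vector -- *not* a faithful inverse.

    Returns ``pinv(IM) @ mass``: the minimum-norm isotopomer vector with
    the given mass distribution, which spreads each mass fraction
    uniformly over the isotopomers of that shift.  It coincides with
    the true isotopomer vector only when that vector happens to be
    symmetric within every shift class (trivially so for ``n = 1``,
    where ``IM`` is the identity).  Emits
    :class:`UnfaithfulConversionWarning`.
    """
    mass.validate(tol)
    if mass.interpretation != "mass":
        raise ValueError("pseudoinverse_demo expects a mass fraction vector")
    n, m = mass.spec.n, mass.spec.m
    out = np.linalg.pinv(im_matrix(n, m).entries.astype(float)) @ mass.values
    warnings.warn(
        "pseudoinverse preimage is the minimum-norm candidate, not the true "
        "isotopomer vector",
        UnfaithfulConversionWarning,
        stacklevel=2,
    )
    return FractionVector("isotopomer", out, mass.spec)


# -- file formats ------------------------------------------------------


def write_vector_tsv(v: FractionVector, path) -> None:
    v.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_vector_tsv(
    path, spec: MoietySpec, interpretation: str, puncture: int | None = None
) -> FractionVector:
    """Read a two-column (state label, fraction) TSV written by this package.

    Rows may appear in any order; labels use ``⊤`` (or ``T``/``x``) for
    the indeterminate state.
    """
    df = pd.read_csv(path, sep="\t", dtype={"state": str}, float_precision="round_trip")
    fv = FractionVector(interpretation, np.zeros(0), spec, puncture)
    order = {_norm_label(lab): i for i, lab in enumerate(fv.labels())}
    values = np.zeros(len(order))
    seen = set()
    for lab, frac in zip(df["state"], df["fraction"]):
        key = _norm_label(str(lab))
        if key not in order:
            raise ValueError(f"unknown state label {lab!r}")
        if key in seen:
            raise ValueError(f"duplicate state label {lab!r}")
        seen.add(key)
        values[order[key]] = float(frac)
    if len(seen) != len(order):
        raise ValueError(f"expected {len(order)} rows, got {len(seen)}")
    return FractionVector(interpretation, values, spec, puncture)


def _norm_label(label: str) -> str:
    return ",".join(
        "⊤" if part in ("⊤", "T", "x", "X") else part
        for part in label.strip().split(",")
    )


def vector_to_json(v: FractionVector) -> str:
    return json.dumps(
        {
            "interpretation": v.interpretation,
            "metabolite": v.spec.metabolite_id,
            "puncture": v.puncture,
            "states": v.labels(),
            "fractions": [float(x) for x in v.values],
        },
        ensure_ascii=False,
    )


def export_matrix_mtx(cm: ConversionMatrix, path) -> None:
    """Export a conversion matrix in Matrix Market coordinate format."""
    mmwrite(path, scipy.sparse.coo_matrix(cm.entries), field="integer")
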