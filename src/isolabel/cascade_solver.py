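"""Steady-state cascade assembly and solving, plus a brute-force oracle.

The identity system of a network is partitioned by EMU size.  Within a
size, identities form a labeled directed graph whose vertices split
into sources (EMUs with supplied labeling, plus virtual *convolution
vertices* whose values are monoidal products of strictly smaller,
already-solved EMUs), intermediates and sinks.  The flux balance for
the unknown vertices is linear:

``(diag(total influx) - intra-size coupling) . x = source inflow``

the left matrix being the consistent mass matrix (row-sum mass lumping
minus the intra-level transport operator); its diagonal is strictly
positive for any network with positive fluxes, and sizes are solved in
ascending order so every convolution vertex is well-founded.

Two interpretations are supported end to end: ``mass`` (per-EMU mass
distributions, convolution as the product, the classical EMU cascade)
and ``boolean`` (per-EMU isotopomer fraction vectors, Cartesian product
under multiplication with atom-order bookkeeping; flux coefficients
become coefficient matrices).  The brute-force oracle instead iterates
the full per-metabolite isotopomer balance to a fixed point and is the
independent correctness reference for both.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .core_states import EMUKey, ElementSpec, MoietySpec, index_to_states
from .fraction_convert import FractionVector, im_matrix
from .reaction_decompose import Identity, IdentitySystem, Reaction, decompose_network

logger = logging.getLogger("isolabel")

STATIONARITY_RTOL = 1e-6


class MissingInputError(ValueError):
    """A source EMU or metabolite has no supplied labeling or spec."""


class StationarityError(ValueError):
    """An internal metabolite pool violates influx = efflux."""


class SingularCascadeError(np.linalg.LinAlgError):
    """The consistent mass matrix of one size is singular."""

    def __init__(self, size: int, component: Sequence[EMUKey]):
        self.size = size
        self.component = tuple(component)
        names = ", ".join(map(str, self.component))
        super().__init__(
            f"singular consistent mass matrix at EMU size {size}; "
            f"under-determined or zero-throughput component: {names}"
        )


class ConvergenceError(RuntimeError):
    """Brute-force fixed-point iteration failed to converge."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        super().__init__(
            f"fixed point not reached after {iterations} iterations "
            f"(residual {residual:.3e})"
        )


@dataclass(frozen=True)
class FluxAssignment:
    """Non-negative flux value per flux identifier."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        vals = {k: float(v) for k, v in self.values.items()}
        for k, v in vals.items():
            if v < 0:
                raise ValueError(f"flux {k!r} is negative: {v}")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, flux_id: str) -> float:
        if flux_id not in self.values:
            raise KeyError(f"no value supplied for flux {flux_id!r}")
        return self.values[flux_id]

    def items(self):
        return self.values.items()

    def scaled(self, factor: float) -> "FluxAssignment":
        return FluxAssignment({k: v * factor for k, v in self.values.items()})


# ---------------------------------------------------------------------
# moiety spec inference


def infer_moiety_specs(
    reactions: Iterable[Reaction],
    known: Mapping[str, MoietySpec],
    default_element: ElementSpec | None = None,
) -> dict[str, MoietySpec]:
    """Propagate per-atom elements from source metabolites through the maps.

    ``known`` supplies specs for (at least) the source metabolites;
    product specs follow from the atom bijections by fixed-point
    iteration.  Conflicting element assignments raise.  Metabolites
    that remain unknown (unlabeled sources) fall back to
    ``default_element`` when given, otherwise raise
    :class:`MissingInputError`.
    """
    reactions = list(reactions)
    specs: dict[str, MoietySpec] = {}
    for met, spec in known.items():
        specs[met] = spec
    all_mets: dict[str, int] = {}
    for rxn in reactions:
        for met, labels in rxn.reagents + rxn.products:
            all_mets[met] = len(labels)
    for met, natoms in all_mets.items():
        if met in specs and specs[met].n != natoms:
            raise ValueError(
                f"metabolite {met!r}: supplied spec has {specs[met].n} atoms, "
                f"network says {natoms}"
            )
        if natoms == 0:
            specs.setdefault(met, MoietySpec(met, ()))
    changed = True
    while changed:
        changed = False
        for rxn in reactions:
            if not all(m in specs for m, labels in rxn.reagents if labels):
                continue
            for met, labels in rxn.products:
                if not labels:
                    continue
                atoms = []
                for pos, lab in enumerate(labels, start=1):
                    ri, q = rxn.origin_of(lab)
                    atoms.append(specs[rxn.reagents[ri][0]].atoms[q - 1])
                derived = MoietySpec(met, tuple(atoms))
                if met in specs:
                    if specs[met].atoms != derived.atoms:
                        raise ValueError(
                            f"metabolite {met!r}: conflicting element signatures "
                            f"{[a.symbol for a in specs[met].atoms]} vs "
                            f"{[a.symbol for a in derived.atoms]} (reaction {rxn.id})"
                        )
                else:
                    specs[met] = derived
                    changed = True
    missing = sorted(m for m in all_mets if m not in specs)
    if missing:
        if default_element is None:
            raise MissingInputError(
                f"cannot infer element layout for {missing}; supply their "
                "moiety specs or input labelings"
            )
        for met in missing:
            specs[met] = MoietySpec(met, (default_element,) * all_mets[met])
    return specs


# ---------------------------------------------------------------------
# marginals


def emu_isotopomer_from_joint(joint: FractionVector, atom_set: Sequence[int]) -> FractionVector:
    """Marginal isotopomer vector of an EMU from a full joint vector."""
    if joint.interpretation != "isotopomer":
        raise ValueError("expected an isotopomer fraction vector")
    spec = joint.spec
    positions = tuple(sorted(set(atom_set)))
    base = spec.m + 1
    tensor = joint.values.reshape((base,) * spec.n) if spec.n else joint.values.reshape(())
    drop = tuple(i for i in range(spec.n) if (i + 1) not in positions)
    marg = tensor.sum(axis=drop) if drop else tensor
    sub = spec.restrict(positions)
    sub_base = sub.m + 1
    if sub.n and sub_base < base:
        marg = marg[np.ix_(*[range(sub_base)] * sub.n)]
    return FractionVector("isotopomer", np.asarray(marg).reshape(-1), sub)


def emu_mass_from_joint(joint: FractionVector, atom_set: Sequence[int]) -> FractionVector:
    """Marginal mass distribution of an EMU from a full joint vector."""
    iso = emu_isotopomer_from_joint(joint, atom_set)
    mat = im_matrix(iso.spec.n, iso.spec.m).entries
    return FractionVector("mass", mat @ iso.values, iso.spec)


# ---------------------------------------------------------------------
# cascade assembly


@dataclass
class CascadeSystem:
    """Per-size flux-balance systems, ready for ascending-order solving."""

    system: IdentitySystem
    fluxes: FluxAssignment
    specs: dict[str, MoietySpec]
    met_inputs: dict[str, FractionVector]
    emu_inputs: dict[EMUKey, FractionVector]
    interpretation: str
    sizes: list[int]
    unknowns: dict[int, list[EMUKey]]

    def restricted_spec(self, key: EMUKey) -> MoietySpec:
        return self.specs[key.metabolite_id].restrict(key.atom_set)

    def vector_length(self, key: EMUKey) -> int:
        rs = self.restricted_spec(key)
        if self.interpretation == "mass":
            return rs.n * rs.m + 1
        return (rs.m + 1) ** rs.n

    def is_source(self, key: EMUKey) -> bool:
        return (
            key.metabolite_id in self.met_inputs
            or key in self.emu_inputs
            or key not in self.system.by_lhs
        )

    def vertex_partition(self, size: int) -> dict[str, list]:
        """Source / intermediate / sink vertex lists of one size level.

        Sources comprise supplied-labeling EMUs and the virtual
        convolution vertices; intermediates are unknowns consumed
        within the level, sinks are unknowns that feed nothing.
        """
        idents = self.system.by_size.get(size, [])
        unknowns = self.unknowns.get(size, [])
        consumed = set()
        conv = []
        srcs = []
        for ident in idents:
            if len(ident.rhs_factors) > 1:
                conv.append(ident)
            else:
                f = ident.rhs_factors[0]
                if f in unknowns:
                    consumed.add(f)
                elif ident.lhs in unknowns:
                    srcs.append(f)
        inter = [u for u in unknowns if u in consumed]
        sinks = [u for u in unknowns if u not in consumed]
        return {
            "sources": sorted(set(srcs)) + conv,
            "intermediates": inter,
            "sinks": sinks,
        }

    def adjacency_blocks(self, size: int) -> dict[str, np.ndarray]:
        """Scalar flux-coefficient blocks ``A21, A22, A31, A32`` of one size.

        Edges run source/intermediate -> intermediate/sink with weight
        equal to the flux value of the identity; convolution vertices
        count as sources.  (The solved system additionally applies the
        per-identity transport operator; these blocks expose the graph
        structure.)
        """
        part = self.vertex_partition(size)
        srcs = part["sources"]
        inter = part["intermediates"]
        sinks = part["sinks"]
        src_pos = {id(v) if isinstance(v, Identity) else v: j for j, v in enumerate(srcs)}
        inter_pos = {v: j for j, v in enumerate(inter)}
        sink_pos = {v: j for j, v in enumerate(sinks)}
        blocks = {
            "A21": np.zeros((len(inter), len(srcs))),
            "A22": np.zeros((len(inter), len(inter))),
            "A31": np.zeros((len(sinks), len(srcs))),
            "A32": np.zeros((len(sinks), len(inter))),
        }
        for ident in self.system.by_size.get(size, []):
            if ident.lhs in inter_pos:
                row, tag = inter_pos[ident.lhs], "2"
            elif ident.lhs in sink_pos:
                row, tag = sink_pos[ident.lhs], "3"
            else:
                continue
            v = self.fluxes[ident.flux_id]
            if len(ident.rhs_factors) > 1:
                blocks[f"A{tag}1"][row, src_pos[id(ident)]] += v
            else:
                f = ident.rhs_factors[0]
                if f in inter_pos:
                    blocks[f"A{tag}2"][row, inter_pos[f]] += v
                else:
                    blocks[f"A{tag}1"][row, src_pos[f]] += v
        return blocks


def _check_stationarity(
    reactions: Iterable[Reaction],
    fluxes: FluxAssignment,
    clamped: set[str],
) -> None:
    produced: dict[str, float] = {}
    consumed: dict[str, float] = {}
    tracked: set[str] = set()
    for rxn in reactions:
        v = fluxes[rxn.flux_id]
        for met, labels in rxn.reagents:
            if labels:
                tracked.add(met)
                consumed[met] = consumed.get(met, 0.0) + v
        for met, labels in rxn.products:
            if labels:
                tracked.add(met)
                produced[met] = produced.get(met, 0.0) + v
    for met in sorted(tracked):
        if met in clamped:
            continue
        p, c = produced.get(met, 0.0), consumed.get(met, 0.0)
        if p > 0 and c > 0 and abs(p - c) > STATIONARITY_RTOL * max(p, c):
            raise StationarityError(
                f"metabolite {met!r} pool is not stationary: influx {p} != efflux {c}"
            )


def build_cascade(
    system: IdentitySystem,
    fluxes: FluxAssignment,
    inputs: Mapping,
    specs: Mapping[str, MoietySpec] | None = None,
    reactions: Iterable[Reaction] | None = None,
    interpretation: str = "mass",
) -> CascadeSystem:
    """Assemble the per-size flux-balance systems for a decomposed network.

    ``inputs`` maps either metabolite ids to full isotopomer
    :class:`FractionVector` objects (marginalised per EMU as needed) or
    :class:`EMUKey` objects to per-EMU vectors (``mass`` vectors serve
    the mass interpretation; ``isotopomer`` vectors serve both).
    EMUs with supplied labeling are clamped sources; source EMUs
    without labeling default to unlabeled (delta at shift zero) with a
    logged warning at solve time.  Pool stationarity is checked when
    the parsed reactions are supplied.
    """
    if interpretation not in ("mass", "boolean"):
        raise ValueError(f"unknown interpretation {interpretation!r}")
    met_inputs: dict[str, FractionVector] = {}
    emu_inputs: dict[EMUKey, FractionVector] = {}
    for key, fv in inputs.items():
        if isinstance(key, EMUKey):
            emu_inputs[key] = fv.validate()
        else:
            if fv.interpretation != "isotopomer":
                raise ValueError(
                    f"metabolite-level input for {key!r} must be an isotopomer vector"
                )
            met_inputs[str(key)] = fv.validate()
    if specs is None:
        if reactions is None:
            raise ValueError("need either explicit specs or the parsed reactions")
        specs = infer_moiety_specs(reactions, {m: fv.spec for m, fv in met_inputs.items()})
    specs = dict(specs)
    if reactions is not None:
        _check_stationarity(reactions, fluxes, set(met_inputs))
    unknowns: dict[int, list[EMUKey]] = {}
    for size, idents in system.by_size.items():
        keys = []
        for ident in idents:
            if ident.lhs.metabolite_id in met_inputs or ident.lhs in emu_inputs:
                continue  # clamped by supplied labeling
            if ident.lhs not in keys:
                keys.append(ident.lhs)
        unknowns[size] = sorted(keys)
    for key in _referenced_keys(system):
        if key.metabolite_id not in specs:
            raise MissingInputError(
                f"no moiety spec available for metabolite {key.metabolite_id!r}"
            )
    return CascadeSystem(
        system=system,
        fluxes=fluxes,
        specs=specs,
        met_inputs=met_inputs,
        emu_inputs=emu_inputs,
        interpretation=interpretation,
        sizes=sorted(unknowns),
        unknowns=unknowns,
    )


def _referenced_keys(system: IdentitySystem) -> set[EMUKey]:
    keys = set()
    for ident in system.identities:
        keys.add(ident.lhs)
        keys.update(ident.rhs_factors)
    return keys


# ---------------------------------------------------------------------
# solving


@dataclass
class LabelingSolution:
    """Solved labeling states, one vector per EMU.

    ``interpretation`` is ``mass`` (mass distributions) or ``boolean``
    (per-EMU isotopomer vectors).
    """

    values: dict[EMUKey, FractionVector]
    interpretation: str

    def __getitem__(self, key: EMUKey) -> FractionVector:
        return self.values[key]

    def __contains__(self, key: EMUKey) -> bool:
        return key in self.values

    def items(self):
        return self.values.items()

    def mass(self, key: EMUKey) -> FractionVector:
        """Mass distribution of an EMU under either interpretation."""
        fv = self.values[key]
        if fv.interpretation == "mass":
            return fv
        mat = im_matrix(fv.spec.n, fv.spec.m).entries
        return FractionVector("mass", mat @ fv.values, fv.spec)

    def cumomer_fraction(self, key: EMUKey, states: tuple | None = None) -> float:
        """Cumomer fraction determinate on ``key``'s atoms at ``states``.

        Under the boolean interpretation any determinate pattern is
        available.  Under the mass interpretation only the all-greatest
        pattern (every atom at its own greatest shift) survives the
        projection: it equals the highest entry of the mass vector.
        """
        fv = self.values[key]
        rs = fv.spec
        caps = tuple(a.max_shift for a in rs.atoms)
        if states is None:
            states = caps
        if fv.interpretation == "isotopomer":
            idx = 0
            for s in states:
                idx = idx * (rs.m + 1) + s
            return float(fv.values[idx])
        if tuple(states) != caps:
            raise ValueError(
                "mass distributions only expose the all-greatest-shift cumomer "
                "fraction; solve with interpretation='boolean' for others"
            )
        return float(fv.values[sum(caps)])


def solve_steady_state(cascade: CascadeSystem, tol: float = 1e-9) -> LabelingSolution:
    """Solve the cascade sizes in ascending order.

    Returns vectors for every unknown EMU plus the source EMUs they
    reference.  Every solved vector is validated to be a probability
    distribution within ``tol``.
    """
    sol: dict[EMUKey, np.ndarray] = {}
    source_cache: dict[EMUKey, np.ndarray] = {}

    def value_of(key: EMUKey) -> np.ndarray:
        if key in sol:
            return sol[key]
        if key in source_cache:
            return source_cache[key]
        vec = _source_value(cascade, key)
        source_cache[key] = vec
        return vec

    for size in cascade.sizes:
        unknowns = cascade.unknowns[size]
        if not unknowns:
            continue
        lengths = [cascade.vector_length(u) for u in unknowns]
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        pos = {u: i for i, u in enumerate(unknowns)}
        dim = offsets[-1]
        M = np.zeros((dim, dim))
        R = np.zeros(dim)
        influx = {u: 0.0 for u in unknowns}
        for ident in cascade.system.by_size.get(size, []):
            if ident.lhs in influx:
                influx[ident.lhs] += cascade.fluxes[ident.flux_id]
        for u in unknowns:
            i = pos[u]
            M[offsets[i] : offsets[i + 1], offsets[i] : offsets[i + 1]] += influx[u] * np.eye(
                lengths[i]
            )
        for ident in cascade.system.by_size.get(size, []):
            if ident.lhs not in pos:
                continue
            i = pos[ident.lhs]
            rows = slice(offsets[i], offsets[i + 1])
            v = cascade.fluxes[ident.flux_id]
            if len(ident.rhs_factors) == 1:
                factor = ident.rhs_factors[0]
                T = _transport_matrix(cascade, ident)
                if factor in pos:
                    j = pos[factor]
                    M[rows, offsets[j] : offsets[j + 1]] -= v * T
                else:
                    R[rows] += v * (T @ value_of(factor))
            else:
                R[rows] += v * _combine_factors(cascade, ident, [value_of(f) for f in ident.rhs_factors])
        try:
            x = np.linalg.solve(M, R)
        except np.linalg.LinAlgError:
            raise _diagnose_singular(cascade, size, unknowns) from None
        for u in unknowns:
            i = pos[u]
            vec = x[offsets[i] : offsets[i + 1]]
            s = vec.sum()
            if abs(s - 1.0) > max(tol, 1e-9) or np.any(vec < -max(tol, 1e-9)):
                raise SingularCascadeError(size, [u]) if not np.isfinite(s) else ValueError(
                    f"solved vector for {u} is not a distribution (sum {s})"
                )
            sol[u] = vec

    out: dict[EMUKey, FractionVector] = {}
    kind = "mass" if cascade.interpretation == "mass" else "isotopomer"
    for key, vec in itertools.chain(sol.items(), source_cache.items()):
        out[key] = FractionVector(kind, vec, cascade.restricted_spec(key))
    return LabelingSolution(out, cascade.interpretation)


def _source_value(cascade: CascadeSystem, key: EMUKey) -> np.ndarray:
    met = key.metabolite_id
    if met in cascade.met_inputs:
        joint = cascade.met_inputs[met]
        if cascade.interpretation == "mass":
            return emu_mass_from_joint(joint, key.atom_set).values
        return emu_isotopomer_from_joint(joint, key.atom_set).values
    if key in cascade.emu_inputs:
        fv = cascade.emu_inputs[key]
        if fv.interpretation == "isotopomer":
            if cascade.interpretation == "mass":
                mat = im_matrix(fv.spec.n, fv.spec.m).entries
                return mat @ fv.values
            return fv.values.copy()
        if fv.interpretation == "mass":
            if cascade.interpretation == "boolean":
                raise MissingInputError(
                    f"input for {key} is a mass distribution; the boolean "
                    "interpretation needs positional (isotopomer) labeling"
                )
            return fv.values.copy()
        raise MissingInputError(f"unsupported input interpretation for {key}")
    if key in cascade.system.by_lhs:
        raise MissingInputError(f"EMU {key} referenced before its size was solved")
    logger.warning("source EMU %s has no supplied labeling; assuming unlabeled", key)
    vec = np.zeros(cascade.vector_length(key))
    vec[0] = 1.0
    return vec


def _transport_matrix(cascade: CascadeSystem, ident: Identity) -> np.ndarray:
    lhs_len = cascade.vector_length(ident.lhs)
    factor = ident.rhs_factors[0]
    if cascade.interpretation == "mass":
        # same element multiset on both sides => identical mass spaces
        return np.eye(lhs_len)
    rs_l = cascade.restricted_spec(ident.lhs)
    rs_f = cascade.restricted_spec(factor)
    base_l, base_f = rs_l.m + 1, rs_f.m + 1
    k = rs_l.n
    P = np.zeros((lhs_len, base_f**k))
    for fidx in range(base_f**k):
        digits = index_to_states(fidx, base_f, k)
        lhs_digits = tuple(digits[ident.atom_map[i][1]] for i in range(k))
        if any(d >= base_l for d in lhs_digits):
            continue  # surplus state on the factor side carries zero mass
        lidx = 0
        for d in lhs_digits:
            lidx = lidx * base_l + d
        P[lidx, fidx] = 1.0
    return P


def _combine_factors(
    cascade: CascadeSystem, ident: Identity, values: list[np.ndarray]
) -> np.ndarray:
    lhs_len = cascade.vector_length(ident.lhs)
    if cascade.interpretation == "mass":
        combined = values[0]
        for v in values[1:]:
            combined = np.convolve(combined, v)
        out = np.zeros(lhs_len)
        out[: len(combined)] = combined
        return out
    rs_l = cascade.restricted_spec(ident.lhs)
    base_l = rs_l.m + 1
    k = rs_l.n
    factor_specs = [cascade.restricted_spec(f) for f in ident.rhs_factors]
    out = np.zeros(lhs_len)
    for lhs_digits in itertools.product(range(base_l), repeat=k):
        prob = 1.0
        ok = True
        for fi, (fspec, fvec) in enumerate(zip(factor_specs, values)):
            fdigits = [0] * fspec.n
            for i, (f_idx, p_idx) in enumerate(ident.atom_map):
                if f_idx == fi:
                    fdigits[p_idx] = lhs_digits[i]
            if any(d > fspec.m for d in fdigits):
                ok = False
                break
            fidx = 0
            for d in fdigits:
                fidx = fidx * (fspec.m + 1) + d
            prob *= fvec[fidx]
        if ok and prob:
            lidx = 0
            for d in lhs_digits:
                lidx = lidx * base_l + d
            out[lidx] = prob
    return out


def _diagnose_singular(
    cascade: CascadeSystem, size: int, unknowns: list[EMUKey]
) -> SingularCascadeError:
    graph = nx.DiGraph()
    graph.add_nodes_from(unknowns)
    pool = set(unknowns)
    for ident in cascade.system.by_size.get(size, []):
        if ident.lhs in pool and len(ident.rhs_factors) == 1:
            f = ident.rhs_factors[0]
            if f in pool:
                graph.add_edge(f, ident.lhs)
    cyclic = [c for c in nx.strongly_connected_components(graph) if len(c) > 1]
    component = sorted(cyclic[0]) if cyclic else sorted(unknowns)
    return SingularCascadeError(size, component)


def steady_state_residual(
    cascade: CascadeSystem, solution: LabelingSolution
) -> dict[int, np.ndarray]:
    """Flux-balance residual ``f(...)`` of a candidate solution, per size.

    Zero (to numerical tolerance) exactly at isotopic steady state;
    exposed so external time integrators can drive the non-stationary
    balance, which this package does not integrate itself.
    """
    out: dict[int, np.ndarray] = {}
    for size in cascade.sizes:
        unknowns = cascade.unknowns[size]
        if not unknowns:
            continue
        residuals = []
        for u in unknowns:
            total = np.zeros(cascade.vector_length(u))
            influx = 0.0
            for ident in cascade.system.by_lhs.get(u, []):
                v = cascade.fluxes[ident.flux_id]
                influx += v
                vals = []
                for f in ident.rhs_factors:
                    fv = solution.values.get(f)
                    if fv is None:
                        fv_arr = _source_value(cascade, f)
                    else:
                        fv_arr = fv.values
                    vals.append(fv_arr)
                if len(vals) == 1:
                    total += v * (_transport_matrix(cascade, ident) @ vals[0])
                else:
                    total += v * _combine_factors(cascade, ident, vals)
            residuals.append(influx * solution[u].values - total)
        out[size] = np.concatenate(residuals)
    return out


# ---------------------------------------------------------------------
# brute-force oracle


def brute_force_isotopomer_solve(
    reactions: Iterable[Reaction],
    fluxes: FluxAssignment,
    inputs: Mapping[str, FractionVector],
    specs: Mapping[str, MoietySpec] | None = None,
    tol: float = 1e-12,
    max_iter: int = 50000,
) -> dict[str, FractionVector]:
    """Fixed-point solve of the full per-metabolite isotopomer balance.

    The labeling of every produced metabolite is the flux-weighted
    mixture, over the reactions producing it, of the joint distribution
    its atoms inherit from the reagents (independent reagent pools, so
    atoms from different reagent occurrences are independent).  Jacobi
    iteration runs until the max-abs update falls below ``tol``.

    This is the un-optimized balance the EMU cascade compresses; it is
    exponential in atoms per metabolite and meant for small networks
    and testing.
    """
    reactions = list(reactions)
    for met, fv in inputs.items():
        fv.validate()
    if specs is None:
        specs = infer_moiety_specs(reactions, {m: fv.spec for m, fv in inputs.items()})
    specs = dict(specs)

    def caps(met: str) -> tuple[int, ...]:
        return tuple(a.max_shift + 1 for a in specs[met].atoms)

    def to_caps_tensor(fv: FractionVector) -> np.ndarray:
        spec = fv.spec
        base = spec.m + 1
        t = fv.values.reshape((base,) * spec.n) if spec.n else fv.values.reshape(())
        shape = tuple(a.max_shift + 1 for a in spec.atoms)
        if spec.n and shape != t.shape:
            t = t[np.ix_(*[range(s) for s in shape])]
        return np.asarray(t)

    produced = {met for rxn in reactions for met, labels in rxn.products if labels}
    consumed = {met for rxn in reactions for met, labels in rxn.reagents if labels}
    clamped = set(inputs)
    state: dict[str, np.ndarray] = {}
    for met in produced | consumed:
        if met in clamped:
            state[met] = to_caps_tensor(inputs[met])
        else:
            if met not in produced:
                logger.warning(
                    "metabolite %s has no supplied labeling; assuming unlabeled", met
                )
                t = np.zeros(caps(met))
                t[(0,) * len(caps(met))] = 1.0
                state[met] = t
            else:
                t = np.zeros(caps(met))
                t[(0,) * len(caps(met))] = 1.0
                state[met] = t

    free = sorted(m for m in produced if m not in clamped)
    plans = _production_plans(reactions, free)
    residual = np.inf
    for iteration in range(max_iter):
        new_state = dict(state)
        residual = 0.0
        for met in free:
            total_flux = 0.0
            acc = np.zeros(caps(met))
            for rxn, prod_idx in plans[met]:
                v = fluxes[rxn.flux_id]
                total_flux += v
                acc += v * _product_tensor(rxn, prod_idx, state, specs)
            new = acc / total_flux
            residual = max(residual, float(np.max(np.abs(new - state[met]))))
            new_state[met] = new
        state = new_state
        if residual < tol:
            break
    else:
        raise ConvergenceError(residual, max_iter)

    out: dict[str, FractionVector] = {}
    for met, tensor in state.items():
        spec = specs[met]
        base = spec.m + 1
        full = np.zeros((base,) * spec.n) if spec.n else np.zeros(())
        if spec.n:
            full[np.ix_(*[range(s) for s in tensor.shape])] = tensor
        else:
            full = tensor
        out[met] = FractionVector("isotopomer", full.reshape(-1), spec)
    return out


def _production_plans(reactions, free):
    plans = {met: [] for met in free}
    for rxn in reactions:
        for prod_idx, (met, labels) in enumerate(rxn.products):
            if labels and met in plans:
                plans[met].append((rxn, prod_idx))
    return plans


def _product_tensor(rxn: Reaction, prod_idx: int, state, specs) -> np.ndarray:
    """Joint distribution a product inherits from the reagents of one reaction."""
    met, labels = rxn.products[prod_idx]
    n_p = len(labels)
    groups: dict[int, list[tuple[int, int]]] = {}
    for pos, lab in enumerate(labels, start=1):
        ri, q = rxn.origin_of(lab)
        groups.setdefault(ri, []).append((q, pos))
    combined = np.ones(())
    axis_product_pos: list[int] = []
    for ri, pairs in sorted(groups.items()):
        reagent = rxn.reagents[ri][0]
        tensor = state[reagent]
        keep_q = sorted(q for q, _ in pairs)
        drop = tuple(i for i in range(tensor.ndim) if (i + 1) not in keep_q)
        marg = tensor.sum(axis=drop) if drop else tensor
        combined = np.multiply.outer(combined, marg)
        pos_by_q = dict(pairs)
        axis_product_pos.extend(pos_by_q[q] for q in keep_q)
    order = np.argsort(axis_product_pos)
    return np.transpose(combined, order)


# ---------------------------------------------------------------------
# convenience driver


def simulate(
    network,
    fluxes: FluxAssignment,
    inputs: Mapping,
    targets: Sequence[EMUKey] | None = None,
    specs: Mapping[str, MoietySpec] | None = None,
    interpretation: str = "mass",
) -> LabelingSolution:
    """Parse, decompose, assemble and solve in one call.

    ``network`` is either network text or a list of parsed reactions.
    """
    from .reaction_decompose import parse_network

    reactions = parse_network(network) if isinstance(network, str) else list(network)
    system = decompose_network(reactions, targets)
    cascade = build_cascade(
        system, fluxes, inputs, specs=specs, reactions=reactions, interpretation=interpretation
    )
    return solve_steady_state(cascade)
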