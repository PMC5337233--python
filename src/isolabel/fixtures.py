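"""Random well-posed network fixtures for tests and demos.

The generator grows a network forward from one or two substrate
metabolites: each step consumes existing metabolites (two of them with
``condensation_probability``), permutes the pooled atoms, and splits
them into one or two products -- either fresh metabolites or, with
``cycle_probability``, an existing compatible metabolite, which closes
a cycle.  Atom balance holds by construction.  Flux values are then
found by linear programming on the pool-stationarity constraints with
strictly positive lower bounds, so every generated assignment is
stationary with positive throughput; seeds whose topology admits no
such flux (for example a cycle with no drain) are retried with a
derived sub-seed.  Substrate labelings are Dirichlet-random isotopomer
distributions over each source's detectable states.

Everything is driven by one seeded generator, so a given seed always
yields byte-identical network text, fluxes and labelings.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .cascade_solver import FluxAssignment
from .core_states import ElementSpec, MoietySpec
from .fraction_convert import FractionVector
from .reaction_decompose import Reaction, parse_network

_LABELS = string.ascii_lowercase + string.digits


class FixtureError(ValueError):
    """Unsatisfiable fixture configuration."""


class _Retry(Exception):
    pass


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_metabolites: int = 6
    max_atoms: int = 3
    elements: Mapping[str, int] = field(default_factory=lambda: {"C": 1})
    cycle_probability: float = 0.3
    condensation_probability: float = 0.4
    max_reactions: int = 12
    flux_bounds: tuple[float, float] = (0.2, 10.0)

    def __post_init__(self) -> None:
        if self.n_metabolites < 2:
            raise FixtureError("need at least 2 metabolites")
        if self.max_atoms < 1:
            raise FixtureError("metabolites need at least 1 atom")
        if not self.elements:
            raise FixtureError("need at least one tracer element")
        for p in (self.cycle_probability, self.condensation_probability):
            if not 0.0 <= p <= 1.0:
                raise FixtureError(f"probability {p} outside [0, 1]")
        lo, hi = self.flux_bounds
        if not 0 < lo <= hi:
            raise FixtureError("flux bounds must satisfy 0 < lo <= hi")


@dataclass
class Fixture:
    """A generated network with consistent fluxes and substrate labelings."""

    config: FixtureConfig
    network_text: str
    reactions: list[Reaction]
    fluxes: FluxAssignment
    inputs: dict[str, FractionVector]
    specs: dict[str, MoietySpec]

    @property
    def sources(self) -> list[str]:
        return sorted(self.inputs)


def generate_fixture(cfg: FixtureConfig, max_attempts: int = 100) -> Fixture:
    """Generate a deterministic, well-posed fixture for the given config."""
    for attempt in range(max_attempts):
        sub_seed = (cfg.seed * 1_000_003 + attempt * 7_919) % (2**31)
        rng = np.random.default_rng(sub_seed)
        try:
            return _build(cfg, rng)
        except _Retry:
            continue
    raise FixtureError(
        f"no well-posed network found for seed {cfg.seed} in {max_attempts} attempts"
    )


def _build(cfg: FixtureConfig, rng: np.random.Generator) -> Fixture:
    element_specs = [ElementSpec(s, int(m)) for s, m in sorted(cfg.elements.items())]

    signatures: dict[str, tuple[ElementSpec, ...]] = {}
    counter = [0]

    def new_met(atoms: tuple[ElementSpec, ...]) -> str:
        name = f"M{counter[0]}"
        counter[0] += 1
        signatures[name] = atoms
        return name

    def rand_atoms(n: int) -> tuple[ElementSpec, ...]:
        idx = rng.integers(0, len(element_specs), size=n)
        return tuple(element_specs[i] for i in idx)

    n_sources = 1 + int(rng.random() < 0.5)
    sources = [
        new_met(rand_atoms(int(rng.integers(1, cfg.max_atoms + 1))))
        for _ in range(n_sources)
    ]

    lines: list[str] = []
    produced: set[str] = set()
    consumed: set[str] = set()

    while len(signatures) < cfg.n_metabolites and len(lines) < cfg.max_reactions:
        candidates = sorted(signatures)
        n_reag = 1
        if len(candidates) >= 2 and rng.random() < cfg.condensation_probability:
            n_reag = 2
        reagents = [
            candidates[i]
            for i in rng.choice(len(candidates), size=n_reag, replace=False)
        ]
        pooled = [
            (met, pos, atom)
            for met in reagents
            for pos, atom in enumerate(signatures[met], start=1)
        ]
        perm = rng.permutation(len(pooled))
        pooled = [pooled[i] for i in perm]
        parts = _split_parts(pooled, cfg.max_atoms, rng)
        labels = {(met, pos): _LABELS[i] for i, (met, pos, _) in enumerate(pooled)}

        product_terms = []
        this_products = []
        for part in parts:
            target = None
            if rng.random() < cfg.cycle_probability:
                sig = sorted(a.symbol for _, _, a in part)
                reusable = [
                    m
                    for m in sorted(signatures)
                    if m not in reagents
                    and m not in sources
                    and m not in this_products
                    and sorted(a.symbol for a in signatures[m]) == sig
                ]
                if reusable:
                    target = reusable[int(rng.integers(0, len(reusable)))]
            if target is None:
                target = new_met(tuple(a for _, _, a in part))
                assigned = list(part)
            else:
                remaining = list(part)
                assigned = []
                for atom in signatures[target]:
                    j = next(
                        i for i, (_, _, a) in enumerate(remaining) if a.symbol == atom.symbol
                    )
                    assigned.append(remaining.pop(j))
            this_products.append(target)
            term_labels = "".join(labels[(met, pos)] for met, pos, _ in assigned)
            product_terms.append(f"{target}[{term_labels}]")

        reagent_terms = [
            f"{met}[{''.join(labels[(met, pos)] for pos in range(1, len(signatures[met]) + 1))}]"
            for met in reagents
        ]
        flux_id = f"v{len(lines) + 1}"
        lines.append(
            f"{' + '.join(reagent_terms)} -> {' + '.join(product_terms)} @ {flux_id}"
        )
        consumed.update(reagents)
        produced.update(this_products)

    if not lines:
        raise _Retry
    if not (produced - consumed):
        # every product recycled: add a drain so positive flux can exist
        pool = sorted(produced)
        met = pool[int(rng.integers(0, len(pool)))]
        sig = signatures[met]
        drain = new_met(sig)
        lab = _LABELS[: len(sig)]
        lines.append(f"{met}[{lab}] -> {drain}[{lab}] @ v{len(lines) + 1}")
        consumed.add(met)
        produced.add(drain)

    network_text = "\n".join(lines) + "\n"
    reactions = parse_network(network_text)
    fluxes = _stationary_fluxes(reactions, sources, cfg, rng)
    specs = {m: MoietySpec(m, sig) for m, sig in signatures.items()}
    inputs = {m: _random_labeling(specs[m], rng) for m in sources}
    return Fixture(cfg, network_text, reactions, fluxes, inputs, specs)


def _split_parts(pooled, max_atoms: int, rng: np.random.Generator):
    n = len(pooled)
    must_split = n > max_atoms
    if n >= 2 and (must_split or rng.random() < 0.5):
        lo = max(1, n - max_atoms)
        hi = min(max_atoms, n - 1)
        k = int(rng.integers(lo, hi + 1))
        return [pooled[:k], pooled[k:]]
    return [pooled]


def _stationary_fluxes(
    reactions: list[Reaction],
    sources: list[str],
    cfg: FixtureConfig,
    rng: np.random.Generator,
) -> FluxAssignment:
    flux_ids = [r.flux_id for r in reactions]
    produced = {m for r in reactions for m, labels in r.products if labels}
    consumed = {m for r in reactions for m, labels in r.reagents if labels}
    balanced = sorted((produced & consumed) - set(sources))
    a_eq = np.zeros((len(balanced), len(flux_ids)))
    for j, rxn in enumerate(reactions):
        for met, labels in rxn.products:
            if met in balanced:
                a_eq[balanced.index(met), j] += 1
        for met, labels in rxn.reagents:
            if met in balanced:
                a_eq[balanced.index(met), j] -= 1
    cost = rng.uniform(0.5, 2.0, size=len(flux_ids))
    res = linprog(
        cost,
        A_eq=a_eq if balanced else None,
        b_eq=np.zeros(len(balanced)) if balanced else None,
        bounds=[cfg.flux_bounds] * len(flux_ids),
        method="highs",
    )
    if not res.success:
        raise _Retry
    return FluxAssignment({fid: float(v) for fid, v in zip(flux_ids, res.x)})


def _random_labeling(spec: MoietySpec, rng: np.random.Generator) -> FractionVector:
    caps = tuple(a.max_shift + 1 for a in spec.atoms)
    dense = rng.dirichlet(np.ones(int(np.prod(caps)))).reshape(caps)
    base = spec.m + 1
    full = np.zeros((base,) * spec.n)
    full[np.ix_(*[range(c) for c in caps])] = dense
    return FractionVector("isotopomer", full.reshape(-1), spec)
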