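# Methods

## Model

`isolabel` treats an isotopic labeling state as an assignment of a
*mass shift* (number of additional neutrons above the element's
least-neutron isotope) to each atom of a moiety.  A moiety is any
ordered set of isotopic atoms — not necessarily bonded, not
necessarily from one metabolite.  Per moiety we carry a single
greatest shift `m = max` over its atoms' own element maxima; states
that exceed an individual atom's own maximum are representable but
undetectable, and validation requires them to carry probability zero
(the *surplus-state rule*).  This keeps every vector space a function
of `(n, m)` only, which is what makes the conversion matrices Kronecker
powers of single-atom blocks.

Three index conventions are fixed throughout and documented on
`core_states`: atoms are 1-based; state tuples are encoded as
mixed-radix integers with atom 1 most significant; determinate states
order ascending with the indeterminate state ⊤ last.  The last choice
matters: placing ⊤ below the determinate states (as older cumomer
software does) scrambles the block structure of the conversion
matrices.

Cumomers are formally states of an infinite virtual moiety whose
non-local atoms are all ⊤.  Only the local prefix is stored; the ⊤
tail carries no information, so the finite truncation is canonical for
every purpose in this package (enumeration, conversion, partition).

### Degenerate `m = 0`

With a single isotope per element, ⊤ (the disjunction of all
determinate states) coincides with the one determinate state.  The
formal enumeration still yields `(m+2)^n = 2^n` cumomer symbols, but
the conversion treats the duplicated symbol as one: `ic_matrix(n, 0)`
is the 1×1 matrix `[1]`, and cumomer vectors at `m = 0` have length 1.
The punctured construction keeps the full two-row single-atom block
before deleting the punctured row, so `punctured_matrix(n, 0, 0)`
remains the (trivially invertible) identity.

## Conversions

* `IC(n, m)`: `n`-fold Kronecker power of `[I_{m+1}; 1…1]`
  (determinate rows first, ⊤ row last).
* `punctured(n, m, s)`: delete row `s` of the single-atom block, then
  the Kronecker power.  Square and invertible for every `s`
  (checked exhaustively for `n, m ≤ 3`); for `m = 1, s = 0` this is
  the binary Reed–Muller transform pattern.  Inversion is performed by
  `np.linalg.solve` on the exact integer matrix rather than by a
  stored inverse.
* `IM(n, m)`: built directly from its semantics — entry `(j, a) = 1`
  iff isotopomer `a` has total shift `j`.  An equivalent formulation
  via column-interspersed identity blocks under matrix convolution
  exists, but its literal spacing parameter does not reproduce the
  direct definition for `n > 1` unless the spacing grows per factor
  (`(m+1)^(i-1) − 1` for the `i`-th factor); the direct definition is
  used because it is unambiguous.
* Mass→isotopomer is refused.  `pseudoinverse_demo` returns
  `pinv(IM)·mass` — the minimum-norm preimage, which spreads each mass
  fraction uniformly over its shift class — and warns, because it
  coincides with the truth only for shift-symmetric vectors.

Matrices are exact `int64`; fraction data are floats validated at a
default tolerance of 1e-9 (per-call configurable).

## Reaction decomposition

The network grammar is one reaction per line with per-atom transition
labels and a flux identifier.  Validation enforces label uniqueness
per side, label conservation across the arrow, and network-wide
consistency of metabolite atom counts.  Reversible reactions expand
into `.fwd`/`.rev` irreversible pairs.  Zero-atom species (cofactors)
are parsed and ignored by decomposition.  Symmetric metabolites are
expressed by the user as parallel half-weighted reactions; no
automatic symmetry handling is attempted.

Decomposition is the power-set construction: for every product and
every non-empty subset of its atoms, one identity whose right-hand
side is the origin atoms grouped by reagent occurrence.  The empty set
is excluded on both sides (it would assert `f(∅) = v·f(∅)`).  Each
identity also records an *atom map* aligning product atoms with factor
atoms; mass distributions ignore it, positional interpretations need
it.  Emission is exhaustive — `2^(n_p) − 1` identities per product —
optionally restricted to the backward-reachable closure of requested
target EMUs (plain reachability; no further structural decomposition
of the adjacency matrices is performed).

## Cascade solver

Identities are grouped by EMU size and solved in ascending order.  At
each size the unknowns are the EMUs with at least one defining
identity and no supplied labeling; the linear system is

```
(diag(total influx) − Σ v·T) · x = Σ v·(known inflow)
```

where `T` is the per-identity transport operator (identity matrix for
mass vectors; a permutation matrix for positional vectors — flux
coefficients become coefficient matrices under the boolean
interpretation).  Multi-factor identities contribute through virtual
convolution vertices whose values are monoidal products of
strictly-smaller solved EMUs, so the recursion is well-founded.
Within-size cycles are handled by a direct dense solve (systems are
small; the consistent matrix has a strictly positive diagonal whenever
fluxes are positive).  A singular matrix raises a structured error
reporting the size and the strongly connected component responsible
(diagnosed with networkx), which signals an under-determined or
zero-throughput subnetwork.

Vertex classification follows the source/intermediate/sink partition:
sources are EMUs with declared labeling or no producing identity
(plus convolution vertices); sinks are unknowns never consumed.  Pool
stationarity (influx = efflux per internal metabolite, relative
tolerance 1e-6) is checked when the parsed reactions are available.
Source EMUs without labeling default to unlabeled (delta at shift 0)
with a logged warning.  The non-steady-state balance is exposed as a
residual function (`steady_state_residual`) for external integrators;
time integration itself is out of scope, as are flux fitting and
natural-abundance correction.

### Brute-force oracle

`brute_force_isotopomer_solve` iterates the full per-metabolite joint
isotopomer balance (Jacobi fixed point, convergence when the max-abs
update < 1e-12, default cap 50 000 iterations).  It assumes reagent
pools are independently distributed, which is exactly the assumption
of the cascade; the two must therefore agree, and the test suite
asserts agreement ≤ 1e-8 of IM-projected oracle marginals with
cascade solutions over 100 seeded random networks, including cyclic
and condensing ones, plus positional agreement under the boolean
interpretation.

## Measurement models

High-resolution MS of an EMU yields a tensor with one axis per
element (order of first appearance), entry = probability of each
per-element total shift combination.  Low-resolution collapse sums
anti-diagonals (equal total shift), and commutes exactly with the
isotopomer→mass matrix — a property test.  GC-MS derivatization
correction deconvolves a supplied agent MID (polynomial deconvolution;
negative entries are clipped and renormalized with a warning).

An NMR splitting-pattern integral is `P(detected pattern | observed
atom at its state)`, computed as a quotient of EMU isotopomer
fractions over `{observed} ∪ detected` and `{observed}`.
Indistinguishable detected nuclei form equivalence groups, expanded to
"at least one atom of the group at the detected state".  Only a single
observed atom is supported; conditioning on several observed atoms
simultaneously is not defined here.  Because mass distributions forget
positions, NMR queries require positional information: a full joint
isotopomer vector, per-EMU isotopomer vectors, or a cascade solution
computed with `interpretation="boolean"`.

## Fixture generator

The generator emulates small metabolic networks: 6 metabolites of up
to 3 atoms by default, one tracer element (C, one shift), condensation
probability 0.4, cycle probability 0.3 — sizes chosen so the
brute-force oracle (exponential in atoms per metabolite) stays
instantaneous while condensations, cleavages, branch points and cycles
all occur across seeds.  Networks are grown forward from one or two
substrates by consuming existing metabolites, permuting pooled atoms
and splitting them into new or (for cycles) existing compatible
metabolites; atom balance holds by construction.  Fluxes come from a
linear program on the stationarity constraints with positive lower
bounds and a seeded random objective, so every emitted assignment is
stationary with positive throughput; topologies admitting no such flux
are regenerated from a derived sub-seed.  Substrate labelings are
Dirichlet draws over each source's detectable states.

What the fixtures do *not* emulate: measurement noise, natural
isotope abundance, compartmentation, metabolite symmetry, and
realistic network motifs (cofactor coupling, conserved moiety pools).
Passing the oracle-equivalence suite therefore demonstrates the
correctness of the decomposition and solver algebra on well-posed
networks, not robustness to noisy or ill-posed experimental data.

## Numerical choices

* validation tolerance 1e-9 on sums/non-negativity (configurable);
* fixed-point tolerance 1e-12, cascade-vs-oracle test tolerance 1e-8;
* stationarity relative tolerance 1e-6;
* all randomness (fixtures, test vectors) flows through
  `numpy.random.default_rng` with explicit seeds; the fixture
  generator derives retry sub-seeds deterministically, so all outputs
  are byte-reproducible for a given seed;
* dense solves throughout — the per-size systems of desk-scale
  networks are tiny; sparse assembly is a straightforward extension
  if ever needed.

## Known limitations

* No isotopically non-stationary (time-resolved) simulation and no
  inverse problem (flux estimation).
* Conditionally dependent labeling states (correlated source atoms
  within one metabolite are supported; correlations *between* reagent
  pools are not representable) and radioactive decay are out of scope.
* The two-dimensional (proton, neutron) tensor interpretation is
  realized only on the measurement side (`MassTensor`), not as a
  cascade combinator.
* Products of two different punctured (Reed–Muller) matrices are
  constructible and provably injective but have no established use;
  they are exposed only through the matrix API.
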