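# isolabel

Forward simulation and exact state-space algebra for isotopic-labeling
experiments (¹³C/¹⁵N/²H… metabolic flux analysis), generalized to
**heteronuclear moieties**: any mix of tracer elements, any number of
isotopes per element, distinguished by any number of additional
neutrons (mass shifts).

A moiety of `n` isotopic atoms with greatest mass shift `m` has four
standard coordinate systems for its labeling state, all supported here
with exact conversions:

| representation | length | meaning |
|---|---|---|
| isotopomer fractions | `(m+1)ⁿ` | probability of each fully determinate state; sums to 1 |
| cumomer fractions | `(m+2)ⁿ` | cumulative probabilities, each atom determinate or indeterminate (⊤); sums to `2ⁿ` |
| punctured cumomers | `(m+1)ⁿ` | cumomers with one determinate state `s` excluded per atom — the Reed–Muller spectral domain of the isotopomers; invertible (the classical cumomer coordinates are the puncture at `s = 0`) |
| mass fractions (MID) | `n·m + 1` | probability of each total shift M+0, M+1, …; a lossy projection |

The conversion matrices are exact 0/1 integer matrices:
`IC(n,m)` (isotopomer→cumomer) is the `n`-fold Kronecker power of the
single-atom block `[I_{m+1}; 1…1]`; deleting the row of state `s`
before the Kronecker power gives the invertible Reed–Muller matrices;
`IM(n,m)` (isotopomer→mass) has one 1 per column, at the row equal to
the isotopomer's total shift.  Mass→isotopomer is *not* offered: the
mass distribution forgets atom positions, and the Moore–Penrose
pseudoinverse (exposed as `pseudoinverse_demo` for teaching) returns
only the minimum-norm preimage.

On top of the state algebra, `isolabel` simulates labeling propagation
through atom-mapped reaction networks:

1. each reaction `A[ab] + B[c] -> C[a] + D[bc] @ v` is decomposed, via
   the power-set construction, into flux-weighted identities over
   **elementary metabolite units** (EMUs — a metabolite plus a subset
   of its atom positions), e.g. `D{1,2} = v × (A{2} ⋆ B{1})` where `⋆`
   is the monoidal product (convolution for mass distributions,
   Cartesian product under multiplication for positional vectors);
2. identities are partitioned by EMU size and assembled into a cascade
   of linear systems `(diag(total influx) − intra-size coupling)·x =
   source inflow`, solved in ascending size order at isotopic steady
   state;
3. solved states feed measurement models: high-resolution MS tensors
   (per-element mass shifts), low-resolution MIDs (anti-diagonal
   collapse), GC-MS derivatization correction, and NMR
   splitting-pattern integrals as conditional probabilities of EMU
   isotopomer fractions.

A brute-force fixed-point solver of the full per-metabolite isotopomer
balance is included as an independent oracle, and a seeded fixture
generator produces random well-posed networks (atom-balanced, with
stationary positive fluxes found by linear programming) for testing.

## Worked example

A condensation followed by an atom-swapping step:

```python
import numpy as np
from isolabel import EMUKey, FluxAssignment, FractionVector, MoietySpec
from isolabel.cascade_solver import simulate

network = """\
Glc[ab] + Amm[c] -> Keto[a] + Amide[bc] @ v1
Amide[bc] -> Prod[cb] @ v2
"""
glc = FractionVector("isotopomer", [0.1, 0.6, 0.05, 0.25],
                     MoietySpec.homonuclear("Glc", 2, 1))
amm = FractionVector("isotopomer", [0.7, 0.3],
                     MoietySpec.homonuclear("Amm", 1, 1))
solution = simulate(network, FluxAssignment({"v1": 1.0, "v2": 1.0}),
                    {"Glc": glc, "Amm": amm})
for key in sorted(solution.values):
    print(key, np.round(solution[key].values, 4))
```

prints

```
Amide{1} [0.15 0.85]
Amide{1,2} [0.105 0.64  0.255]
Amide{2} [0.7 0.3]
Amm{1} [0.7 0.3]
Glc{1} [0.7 0.3]
Glc{2} [0.15 0.85]
Keto{1} [0.7 0.3]
Prod{1} [0.7 0.3]
Prod{1,2} [0.105 0.64  0.255]
Prod{2} [0.15 0.85]
```

Each line is an EMU's mass distribution `[M+0, M+1, …]`.  `Amide{1}`
inherits glucose atom 2 (15 % unlabeled, 85 % labeled), `Amide{2}`
inherits the ammonium atom, and `Amide{1,2}` is their convolution —
e.g. M+1 = 0.15·0.3 + 0.85·0.7 = 0.64.  `Prod` shows the same
distributions with atoms 1 and 2 swapped by the second reaction.
Solving with `interpretation="boolean"` returns positional
(isotopomer) vectors per EMU instead, which is what NMR queries need.

A command-line interface wraps the same operations:

```sh
isolabel decompose net.txt --target "D[1,2]"
isolabel convert vec.tsv --from isotopomer --to mass --n 2 --m 1
isolabel simulate net.txt --fluxes fluxes.tsv --config model.yaml --input Glc=glc.tsv
isolabel measure request.yaml
isolabel fixture --seed 1 --out fixtures/demo
```

## Layout

```
src/isolabel/
  core_states.py        moiety specs; isotopomer/cumomer/EMU enumeration
  state_logic.py        multi-valued conjunction/disjunction of states
  fraction_convert.py   IC / Reed-Muller / IM matrices; FractionVector; TSV/JSON/MTX
  interpretations.py    monoidal products: convolution, boolean product, atom count
  reaction_decompose.py network grammar; power-set EMU decomposition
  cascade_solver.py     cascade assembly/solve; brute-force oracle
  measurement_models.py MS tensors, MID collapse, NMR integrals, derivatization
  fixtures.py           seeded random well-posed network generator
  cli.py                click command line
docs/methods.md         model assumptions, numerical choices, limitations
```
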