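# pairled

Fragment-pairwise interaction energy maps from local energy decomposition
(LED) terms.

## The problem

Supramolecular binding energies — a ligand in a protein pocket, two DNA
strands, molecules in a cluster — are routinely decomposed by LED-style
schemes into intra-fragment energies `E^(X)`, inter-fragment pair terms
`E^(X,Y)` (split into electrostatics, exchange, dispersion, and
non-dispersive correlation), and, upon binding, a per-fragment **electronic
preparation** energy

    ΔE_el-prep^X = E^(X)_complex − E^(X)_isolated,

the cost of distorting a fragment's electronic structure in the field of
its partners. That last term is *not* pairwise: it lumps together a
fragment's response to all its neighbours, which blurs the question one
usually asks — *how strongly does this fragment interact with that one?*

`pairled` answers it by redistributing the electronic preparation energies
over fragment pairs. With ε_{X,Y} the unified pair term (the
binding-induced *change* of `E^(X,Y)` for fragments in the same subsystem,
the full `E^(X,Y)` for fragments on different subsystems), each fragment's
el-prep is shared over its pairs with weights

    w(X→Y) = |ε_{X,Y}| / Σ_{Z≠X} |ε_{X,Z}|,

and the fragment-pairwise interaction map is

    ΔE_int^{X,Y} = ΔE_el-prep^{XY} + ε_{X,Y},
    ΔE_el-prep^{XY} = ΔE_el-prep^X · w(X→Y) + ΔE_el-prep^Y · w(Y→X).

Because the weights are normalized per fragment, the map is an **exact**
decomposition: its entries sum to the supramolecular binding energy
`ΔE_int = E_super − Σ_A E_A` to machine precision, with no fitted or
discarded remainder. Each physical channel is carried through to its own
pairwise map, and comparing the fp map with the standard two-body (MBE)
matrix `ΔE²_{XY} = E_dimer − E_mono1 − E_mono2` (all at the complex
geometry) gives a **cooperativity matrix** — how much each pair
interaction is reshaped by its chemical environment.

The package is a pure post-processor: it consumes LED-style energy terms
(e.g. from DLPNO-CCSD(T) or HFLD calculations) and never computes
wavefunctions. A built-in toy polarizable point-charge emulator generates
fully consistent synthetic term sets with genuine many-body character, so
everything can be exercised and verified without quantum-chemistry
software.

## Worked example

Three charged, polarizable toy fragments (a "water-trimer-like" triangle),
each its own subsystem:

```python
import pairled as pl
from pairled.units import HARTREE_TO_KCAL as K

system = pl.charged_trimer()                       # W1, W2, W3
result = pl.fp_map(system.supersystem, system.references)

print(f"dE_int = {result.delta_e_int * K:.2f} kcal/mol")
for (x, y), v in result.fp_map.items():
    print(f"  {x}-{y}: fp = {v * K:6.2f}   "
          f"eps = {result.epsilon.get(x, y) * K:6.2f}   "
          f"el-prep = {result.el_prep_pairs.get(x, y) * K:5.2f}")
```

prints

```
dE_int = -16.69 kcal/mol
  W1-W2: fp = -14.71   eps = -15.05   el-prep =  0.33
  W1-W3: fp =  10.68   eps =  10.55   el-prep =  0.12
  W2-W3: fp = -12.66   eps = -12.97   el-prep =  0.31
```

The three fp entries sum to the binding energy (−16.69 kcal/mol) exactly:
two attractive pairs (the +/− contacts), one repulsive pair (the two
positive fragments), each carrying its share of the polarization cost.
The physical-component totals (`pl.physical_summary(result)`, kcal/mol)

```
elstat -13.56   exch 0.46   disp -2.83   induction -1.54   el-prep 0.77
```

again sum to −16.69. Comparing with the two-body matrix:

```python
tb = pl.two_body_matrix(system.dimers, system.scheme)
coop = pl.cooperativity_matrix(result, tb)
print(f"total cooperativity = {coop.total_coop * K:.3f} kcal/mol")
```

gives `total cooperativity = 0.125 kcal/mol` — the genuinely many-body
(induction cross-term) part of the binding, which an additive model
(all polarizabilities zero) reduces to exactly zero.

From the shell, the same pipeline is:

```
pairled emulate --n 6 --subsystems 2 --seed 42 --out fixtures/
pairled decompose --super fixtures/supersystem.json \
    --ref fixtures/isolated_S1.json --ref fixtures/isolated_S2.json \
    --out maps/
pairled render --matrix maps/fp_map.csv --out maps/fp_map.png
```

File formats (canonical JSON, the plain-text LED block dialect, CSV
matrices) are documented in `docs/formats.md`; the model and its design
choices in `docs/methods.md`.

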