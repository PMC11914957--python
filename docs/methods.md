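# Methods

## Scope and model of the data

`pairled` post-processes local energy decomposition (LED) term sets. One
*calculation* is: a total electronic energy `E`, intra-fragment energies
`E^(X)` for every fragment, a symmetric inter-fragment pair matrix
`E^(X,Y)` resolved into physical channels (electrostatics, exchange,
London dispersion, non-dispersive correlation, optional named extras),
and optionally a dielectric (implicit-solvent) energy change. The
completeness identity — total equals the sum of all parts — is the
entry contract for every dataset; its tolerance is 1e-6 Hartree by
default (upstream outputs are printed with finite precision) and
overridable per file. All internal identities are enforced at 1e-10
Hartree; emulator-generated datasets, being exact constructions, are
validated at that tighter level.

A *decomposition problem* is one supersystem calculation plus one
isolated-subsystem calculation per subsystem, all at the complex
geometry, with identical fragment labels and channel conventions.

## The fragment-pairwise decomposition

1. Binding energy: `dE_int = E_super − Σ_A E_A`.
2. Electronic preparation per fragment:
   `p_X = E^(X)_complex − E^(X)_isolated`.
3. Unified pair term `ε_{X,Y}`: for same-subsystem pairs the
   binding-induced change `E^(X,Y)_complex − E^(X,Y)_isolated`
   (channel-wise); for cross-subsystem pairs the complex pair term
   itself. By construction `dE_int = Σ_X p_X + Σ_{X<Y} ε_{X,Y}` — an
   algebraic identity, independent of the underlying electronic-structure
   model.
4. Distribution: `p_X` is shared over pairs with per-fragment weights
   `w(X→Y) = g(ε_{X,Y}) / Σ_{Z≠X} g(ε_{X,Z})`, and the fp map is
   `fp(X,Y) = p_X w(X→Y) + p_Y w(Y→X) + ε_{X,Y}`. Row-normalization makes
   the distribution conserving for *any* non-negative `g`, so the fp map
   sums to `dE_int` to machine precision.

### Weight functional

The default is `g = |ε|` (`abs_epsilon`): a fragment's electronic
perturbation is attributed to its neighbours in proportion to the
*strength* of each pair coupling. Magnitudes rather than signed values
are used so that rows with near-cancelling attractive/repulsive entries
cannot produce weights outside [0, 1] or divide by a vanishing net sum.
`squared_epsilon` (emphasizes the dominant partner) and `equal`
(uninformative prior) are provided for sensitivity analysis; all modes
satisfy the same conservation identity, which is the binding contract.
Weights are always computed from the *total* ε (all channels summed) and
the same split is reused for the "el-prep" channel map; channel-specific
weighting is rejected by design because it would break the entrywise
closure of the channel maps on the fp map.

Degenerate case: a fragment whose ε row is identically zero has no basis
for attribution. Default policy splits its el-prep equally over its pairs
(such a fragment has essentially zero el-prep anyway, and conservation is
preserved); a strict `error` policy is available. A single-fragment
system has no pairs and is rejected.

### Channels

Per-channel fp maps pass each ε channel through unchanged and add the
distributed el-prep as its own channel, so channels sum entrywise to the
fp map and channel totals sum to `dE_int` exactly. The channel set is
open: extra named channels (e.g. an induction term, or triples
corrections folded in upstream) propagate automatically.

### Dielectric term

An implicit-solvent energy change is distributed over pairs with a single
*global* normalization proportional to `g(|ε|)` — the simplest conserving
rule, chosen as the default because the pair coupling strength is the
only pairwise information available to the post-processor. This differs
deliberately from the per-fragment el-prep normalization (the dielectric
change is not attributable to individual fragments) and is documented as
provisional; alternative strategies plug in through the same
`WeightConfig` interface. The map total equals the input scalar to 1e-12.

## Cooperativity

The two-body matrix holds `dE²(X,Y) = E_dimer − E_mono1 − E_mono2`, all
*frozen at the complex geometry* — the schema has no slot for
relaxed-monomer energies, on purpose, since geometric relaxation would
contaminate the comparison with strain. The cooperativity matrix is the
entrywise difference `fp − two_body`; its total is
`dE_int − Σ dE²`, the full many-body contribution. Pairs without dimer
data stay NaN and totals are flagged partial. Note that the total is the
many-body energy only when each fragment is its own subsystem; with
multi-fragment subsystems the all-pairs two-body sum also spans
intra-subsystem pairs that the binding energy excludes, and the
difference should be read accordingly.

## The synthetic emulator

Purpose: generate internally consistent supersystem / isolated-subsystem
/ dimer term sets with genuine many-body character, plus closed-form
totals computed on an independent code path, so every identity above can
be tested end to end without quantum-chemistry software.

Each toy fragment is a point particle with charge `q` (e), isotropic
polarizability `α` (Å³), Born–Mayer repulsion `A·exp(−b·r)` (A in
Hartree, b in 1/Å), and dispersion `−C6/r⁶` (C6 in Hartree·Å⁶);
combination rules are geometric means for `A` and `C6` and the
arithmetic mean for `b`. The Coulomb constant is 332.0637 kcal·Å/mol
converted with the package-wide 627.509474 kcal/mol per Hartree. The
non-additive piece is classical induction `−½ Σ_i α_i |F_i|²` with `F_i`
the total monopole field at fragment i within the calculation's fragment
set; the `|F_i|²` cross terms couple triples and are the sole source of
cooperativity.

Mapping to LED terms: the polarization cost `+½ α_i |F_i|²` goes into the
intra-fragment energy (so el-prep is a deterministic, non-negative
function of the local field for monomer subsystems, and el-prep tracks
pair interaction strength — the property the linearity diagnostic
probes); the induction attraction `−α_i f_ij·F_i − α_j f_ji·F_j` goes
into an extra pair channel named `induction`, with each three-body cross
term split half-and-half between its two pairs. Summed over pairs this
reproduces the induction energy exactly, so every emulated dataset passes
completeness at 1e-10 Hartree by construction, not by rounding.

Default parameter ranges for random configurations (charges uniform in
±0.5 e, α in 0.5–1.5 Å³, A in 5–15 Hartree, b in 3–4 Å⁻¹, C6 in 0.5–2
Hartree·Å⁶, minimum separation 2.2 Å in an 8 Å box) are loosely modelled
on small polar molecules; they produce pair energies of a few to a few
tens of kcal/mol and polarization costs of tenths of kcal/mol, i.e. the
right orders of magnitude for hydrogen-bonded clusters. Placement uses
uniform rejection sampling; every generator is driven by an explicit
seed and identical seeds give bit-identical files.

Canonical fixtures:

* `canonical_dimer(r)` — a +0.35/−0.35 polarizable pair; equilibrium-like
  separation 3.0 Å. The linearity scan covers 20 separations over
  2.5–4.5 Å, the window where the pair energy varies by an order of
  magnitude around the well; over it the summed polarization cost is
  strongly linear in the pair energy, as the diagnostic tests verify.
* `canonical_trimer(d)` — that dimer plus a *neutral* polarizable probe
  on the axis at distance d. The probe is neutral by design: real
  closed-shell molecules have no monopole, and a charged toy probe would
  add a 1/r charge–charge tail that keeps perturbing the distant pair at
  any separation. With a neutral probe all couplings to it fall off as
  1/r⁴ or faster, so the perturbed pair's fp entry converges to the
  isolated-dimer binding energy to better than 1e-8 Hartree by 100×
  the equilibrium separation — the clean asymptotic limit the scan tests
  assert. Because the probe leaves the dimer's fields unchanged, its
  whole effect on the W1–W2 fp entry flows through the redistribution
  weights, and the frozen two-body term is exactly flat along the scan.
* `charged_trimer(scale)` — three charged polarizable fragments within
  ~3 Å of each other; guarantees a nonzero many-body (cooperativity)
  signal of order 0.1 kcal/mol.
* `equilateral_trimer()` — three identical fragments with exact three-fold
  symmetry; all fp entries must agree to 1e-12.

What the emulator does *not* emulate: quantum-mechanical
exchange-repulsion anisotropy, charge transfer, self-consistent
(iterated) polarization, non-dispersive correlation (its `no_disp`
channel is always zero), or any specific chemistry. Passing tests
therefore demonstrate that the bookkeeping, conservation, limiting
behaviour, and diagnostics of the decomposition are correct for any
internally consistent LED input — not that the toy energies resemble a
particular molecular system.

## Numerical choices

* Internal unit Hartree; one fixed conversion constant (627.509474
  kcal/mol) used everywhere.
* Tolerance hierarchy: input completeness 1e-6 Hartree (printed
  precision), internal exactness identities 1e-10, symmetry and
  conservation checks on constructed data 1e-12.
* Pair matrices are dense symmetric arrays with a zero diagonal, ordered
  by the fragment scheme; file serialization is key-sorted and
  full-precision (`repr` doubles; CSV reads use round-trip float
  parsing), so read/write cycles are value-identical.
* Ties or equal-|ε| rows need no special handling — the weights are a
  continuous function of ε.
* The linearity fit is ordinary least squares; a constant response is
  reported as R² = 0 with a degeneracy flag, a constant predictor is an
  error.
* Geometric strain ("geometric preparation") is out of scope; a
  user-supplied scalar can simply be added to reported totals.

## Limitations

* The weight functional is a modelling choice, not an observable; the
  exactness of the total is guaranteed, the split of the el-prep among
  pairs inherits the `abs_epsilon` assumption (hence the alternative
  modes for sensitivity checks).
* The dielectric distribution rule is provisional (see above).
* Cooperativity requires user-supplied dimer energies at the complex
  geometry; the package cannot detect relaxed-monomer inputs, it can
  only document the requirement.
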