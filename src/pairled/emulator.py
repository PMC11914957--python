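"""Toy polarizable point-charge emulator of LED-style datasets.

The emulator generates internally consistent supersystem, isolated-
subsystem, and dimer energy-term sets from a classical model with genuine
many-body character, so the decomposition bookkeeping can be exercised and
verified against closed-form totals without any quantum-chemistry
software.  No chemical realism is claimed.

Model
-----
Each fragment i is a point particle with charge ``q_i`` (e), isotropic
polarizability ``alpha_i`` (A^3), Born-Mayer repulsion parameters
``A_i`` (Hartree) and ``b_i`` (1/A), and a dispersion coefficient
``C6_i`` (Hartree*A^6).  Pairwise additive terms, with combination rules
``A_ij = sqrt(A_i A_j)``, ``b_ij = (b_i + b_j)/2``, ``C6_ij =
sqrt(C6_i C6_j)``:

* electrostatics  ``k q_i q_j / r``      (k in Hartree*A/e^2)
* exchange        ``A_ij exp(-b_ij r)``
* dispersion      ``-C6_ij / r^6``

Non-additive induction: with ``f_ij`` the Coulomb field at i due to j and
``F_i = sum_j f_ij`` the total field, the induction energy is
``-1/2 sum_i alpha_i |F_i|^2``.  The ``|F_i|^2`` cross terms couple
fragment triples, which is what produces cooperativity.

Mapping onto LED terms (exact by construction):

* intra-fragment energy in a calculation over fragment set S:
  ``E_self_i + 1/2 alpha_i |F_i(S)|^2`` -- the *polarization cost* of the
  distorted state, the emulator's electronic preparation;
* pair channels: elstat/exch/disp as above, ``no_disp = 0``, plus an extra
  ``"induction"`` channel carrying the attraction ``-alpha_i f_ij.F_i -
  alpha_j f_ji.F_j``.  Each three-body cross term ``-alpha_i f_ij.f_il``
  is split half to pair (i,j) and half to (i,l); summed over pairs this
  reproduces ``-sum_i alpha_i |F_i|^2`` exactly, so every dataset passes
  the completeness identity at machine precision.

Setting all polarizabilities to zero gives a strictly additive model:
zero electronic preparation, zero cooperativity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    DimerReference,
    EnergyChannels,
    FragmentScheme,
    LEDDataset,
    SubsystemReferenceSet,
    ValidationError,
)
from .units import COULOMB_HARTREE_ANGSTROM as K_COULOMB

#: Fragments closer than this are rejected as overlapping (Angstrom).
HARD_CORE_CUTOFF = 0.5

#: Emulated datasets are exact constructions; validate them tightly.
EMULATOR_COMPLETENESS_TOL = 1e-10

INDUCTION_CHANNEL = "induction"


@dataclass(frozen=True)
class ToyFragment:
    """One point-charge fragment of the toy model."""

    position: Tuple[float, float, float]
    charge: float = 0.0
    polarizability: float = 0.0
    exch_amp: float = 0.0
    exch_decay: float = 3.5
    c6: float = 0.0
    self_energy: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", tuple(float(v) for v in self.position))
        if len(self.position) != 3:
            raise ValidationError("position must be a 3-vector")
        if self.polarizability < 0:
            raise ValidationError("polarizability must be >= 0")
        if self.exch_decay <= 0:
            raise ValidationError("exch_decay must be > 0")
        if self.c6 < 0:
            raise ValidationError("c6 must be >= 0")


@dataclass
class EmulatedSystem:
    """All calculations the decomposition needs, from one geometry."""

    fragments: Tuple[ToyFragment, ...]
    scheme: FragmentScheme
    supersystem: LEDDataset
    references: SubsystemReferenceSet
    dimers: Tuple[DimerReference, ...]
    seed: Optional[int] = None


@dataclass(frozen=True)
class OracleTotals:
    """Closed-form totals, computed independently of the LED bookkeeping."""

    delta_e_int: float
    two_body_sum: float
    many_body_remainder: float


# ---------------------------------------------------------------------------
# Closed-form model evaluation
# ---------------------------------------------------------------------------

def _check_geometry(fragments: Sequence[ToyFragment]) -> np.ndarray:
    if len(fragments) < 2:
        raise ValidationError("emulator needs at least 2 fragments")
    pos = np.array([f.position for f in fragments])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    n = len(fragments)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < HARD_CORE_CUTOFF:
                raise ValidationError(
                    f"fragments {i} and {j} overlap (r = {d[i, j]:.3f} A "
                    f"< hard-core cutoff {HARD_CORE_CUTOFF} A)")
    return d


def _pair_additive(fragments: Sequence[ToyFragment], i: int, j: int,
                   r: float) -> Tuple[float, float, float]:
    """(elstat, exch, disp) for one pair at separation r."""
    fi, fj = fragments[i], fragments[j]
    elstat = K_COULOMB * fi.charge * fj.charge / r
    a_ij = math.sqrt(fi.exch_amp * fj.exch_amp)
    b_ij = 0.5 * (fi.exch_decay + fj.exch_decay)
    exch = a_ij * math.exp(-b_ij * r)
    c6_ij = math.sqrt(fi.c6 * fj.c6)
    disp = -c6_ij / r ** 6
    return elstat, exch, disp


def _fields(fragments: Sequence[ToyFragment],
            members: Sequence[int]) -> Dict[int, Dict[int, np.ndarray]]:
    """Coulomb field vectors f[i][j]: field at member i due to member j."""
    pos = {i: np.array(fragments[i].position) for i in members}
    f: Dict[int, Dict[int, np.ndarray]] = {i: {} for i in members}
    for i in members:
        for j in members:
            if i == j:
                continue
            rij = pos[i] - pos[j]
            r = float(np.linalg.norm(rij))
            f[i][j] = K_COULOMB * fragments[j].charge * rij / r ** 3
    return f


def subset_energy(fragments: Sequence[ToyFragment],
                  members: Sequence[int]) -> float:
    """Analytic total energy of the model restricted to ``members``."""
    e = sum(fragments[i].self_energy for i in members)
    pos = np.array([fragments[i].position for i in members])
    mem = list(members)
    for a in range(len(mem)):
        for b in range(a + 1, len(mem)):
            r = float(np.linalg.norm(pos[a] - pos[b]))
            e += sum(_pair_additive(fragments, mem[a], mem[b], r))
    f = _fields(fragments, mem)
    for i in mem:
        big_f = sum(f[i].values()) if f[i] else np.zeros(3)
        e -= 0.5 * fragments[i].polarizability * float(np.dot(big_f, big_f))
    return float(e)


# ---------------------------------------------------------------------------
# LED dataset construction
# ---------------------------------------------------------------------------

def _dataset_for(fragments: Sequence[ToyFragment], scheme: FragmentScheme,
                 members: Sequence[int], all_labels: Sequence[str],
                 method_label: str) -> LEDDataset:
    """Exact LED-style term set for the model restricted to ``members``."""
    mem = list(members)
    labels = [all_labels[i] for i in mem]
    f = _fields(fragments, mem)
    big_f = {i: (sum(f[i].values()) if f[i] else np.zeros(3)) for i in mem}

    intra = {}
    for i in mem:
        prep = 0.5 * fragments[i].polarizability * float(np.dot(big_f[i], big_f[i]))
        intra[all_labels[i]] = fragments[i].self_energy + prep

    inter: Dict[Tuple[str, str], EnergyChannels] = {}
    pos = {i: np.array(fragments[i].position) for i in mem}
    for a in range(len(mem)):
        for b in range(a + 1, len(mem)):
            i, j = mem[a], mem[b]
            r = float(np.linalg.norm(pos[i] - pos[j]))
            elstat, exch, disp = _pair_additive(fragments, i, j, r)
            induction = (
                -fragments[i].polarizability * float(np.dot(f[i][j], big_f[i]))
                - fragments[j].polarizability * float(np.dot(f[j][i], big_f[j]))
            )
            inter[(all_labels[i], all_labels[j])] = EnergyChannels(
                elstat=elstat, exch=exch, disp=disp, no_disp=0.0,
                extra={INDUCTION_CHANNEL: induction},
            )

    total = (sum(intra.values())
             + sum(ch.total() for ch in inter.values()))
    return LEDDataset(
        scheme=scheme,
        total_energy=total,
        intra=intra,
        inter=inter,
        method_label=method_label,
        completeness_tol=EMULATOR_COMPLETENESS_TOL,
    )


def emulate_led(fragments: Sequence[ToyFragment], scheme: FragmentScheme,
                seed: Optional[int] = None) -> EmulatedSystem:
    """Generate supersystem, isolated-subsystem, and dimer term sets.

    All datasets come from the same closed forms restricted to the
    relevant fragment subsets, at the (frozen) complex geometry, and are
    fully determined by the fragments and scheme; ``seed`` is recorded for
    provenance only.
    """
    fragments = tuple(fragments)
    if len(fragments) != scheme.n_fragments:
        raise ValidationError("fragment list length does not match scheme")
    _check_geometry(fragments)
    labels = scheme.fragment_labels

    supersystem = _dataset_for(fragments, scheme, range(len(fragments)),
                               labels, "toy-polarizable")

    refs: Dict[str, LEDDataset] = {}
    for sub in scheme.subsystems:
        sub_scheme = scheme.restricted(sub)
        members = [labels.index(x) for x in sub_scheme.fragment_labels]
        refs[sub] = _dataset_for(fragments, sub_scheme, members,
                                 labels, "toy-polarizable")
    references = SubsystemReferenceSet(parent_scheme=scheme,
                                       references=refs).validate()

    dimers: List[DimerReference] = []
    for x, y in scheme.pairs():
        i, j = labels.index(x), labels.index(y)
        dimers.append(DimerReference(
            pair=(x, y),
            dimer_energy=subset_energy(fragments, [i, j]),
            monomer_energies=(subset_energy(fragments, [i]),
                              subset_energy(fragments, [j])),
        ))

    supersystem.validate()
    return EmulatedSystem(
        fragments=fragments, scheme=scheme, supersystem=supersystem,
        references=references, dimers=tuple(dimers), seed=seed,
    )


def subset_energy_for(system: EmulatedSystem, labels: Sequence[str]) -> float:
    """Analytic energy of a labelled fragment subset of an emulated system."""
    all_labels = system.scheme.fragment_labels
    return subset_energy(system.fragments, [all_labels.index(x) for x in labels])


# ---------------------------------------------------------------------------
# Closed-form oracle totals
# ---------------------------------------------------------------------------

def oracle_totals(fragments: Sequence[ToyFragment],
                  scheme: FragmentScheme) -> OracleTotals:
    """Analytic binding energy, two-body sum, and many-body remainder.

    Computed directly from :func:`subset_energy` -- a code path that never
    touches the LED bookkeeping -- so it can serve as an independent check
    of the decomposition pipeline.  The remainder is defined against the
    all-pairs two-body sum, matching the cooperativity totals.
    """
    fragments = tuple(fragments)
    _check_geometry(fragments)
    labels = scheme.fragment_labels
    n = len(labels)
    e_super = subset_energy(fragments, range(n))
    e_isol = sum(
        subset_energy(fragments, [labels.index(x)
                                  for x in scheme.fragments_of(sub)])
        for sub in scheme.subsystems
    )
    de_int = e_super - e_isol

    two_body = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            two_body += (subset_energy(fragments, [i, j])
                         - subset_energy(fragments, [i])
                         - subset_energy(fragments, [j]))
    return OracleTotals(
        delta_e_int=de_int,
        two_body_sum=two_body,
        many_body_remainder=de_int - two_body,
    )


# ---------------------------------------------------------------------------
# Canonical generators
# ---------------------------------------------------------------------------

def random_system(n_fragments: int, n_subsystems: int, seed: int,
                  box: float = 8.0, min_dist: float = 2.2,
                  polarizable: bool = True) -> EmulatedSystem:
    """Random fragment configuration in a cubic box, fully seeded.

    Fragments are placed uniformly with minimum-distance rejection;
    parameters are drawn from ranges loosely modelled on small polar
    molecules (charges up to +-0.5 e, polarizabilities 0.5-1.5 A^3,
    dispersion coefficients 0.5-2 Hartree*A^6).  Fragments are assigned to
    ``n_subsystems`` contiguous groups, each with at least one fragment.
    """
    if n_fragments < 2:
        raise ValidationError("need at least 2 fragments")
    if not 1 <= n_subsystems <= n_fragments:
        raise ValidationError("need 1 <= n_subsystems <= n_fragments")
    rng = np.random.default_rng(seed)

    positions: List[np.ndarray] = []
    attempts = 0
    while len(positions) < n_fragments:
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - p) >= min_dist for p in positions):
            positions.append(cand)
        attempts += 1
        if attempts > 10000 * n_fragments:
            raise ValidationError(
                "could not place fragments with the requested minimum distance")

    fragments = tuple(
        ToyFragment(
            position=tuple(positions[i]),
            charge=float(rng.uniform(-0.5, 0.5)),
            polarizability=float(rng.uniform(0.5, 1.5)) if polarizable else 0.0,
            exch_amp=float(rng.uniform(5.0, 15.0)),
            exch_decay=float(rng.uniform(3.0, 4.0)),
            c6=float(rng.uniform(0.5, 2.0)),
            self_energy=float(-1.0 - i),
        )
        for i in range(n_fragments)
    )

    labels = tuple(f"F{i + 1}" for i in range(n_fragments))
    # contiguous split into n_subsystems groups, each non-empty
    bounds = sorted(rng.choice(np.arange(1, n_fragments),
                               size=n_subsystems - 1, replace=False).tolist())
    subsystem_of: Dict[str, str] = {}
    start = 0
    for s, end in enumerate(bounds + [n_fragments]):
        for i in range(start, end):
            subsystem_of[labels[i]] = f"S{s + 1}"
        start = end
    scheme = FragmentScheme(labels, subsystem_of)
    return emulate_led(fragments, scheme, seed=seed)


# -- canonical scan fixtures -------------------------------------------------

#: Equilibrium-like separation of the canonical charged dimer (Angstrom).
DIMER_EQ_SEPARATION = 3.0

_DIMER_PARAMS = (
    dict(charge=+0.35, polarizability=1.1, exch_amp=8.0, exch_decay=3.4, c6=1.2),
    dict(charge=-0.35, polarizability=1.4, exch_amp=10.0, exch_decay=3.6, c6=1.0),
)

#: Neutral polarizable probe used as the receding third body in trimer
#: scans.  A neutral probe couples to the dimer only through exchange,
#: dispersion, and induction (all falling off as 1/r^4 or faster), which is
#: what makes the large-separation limit clean; a monopole third body would
#: add an unphysical 1/r charge-charge tail that real closed-shell
#: molecules do not have.
_PROBE_PARAMS = dict(charge=0.0, polarizability=1.5, exch_amp=9.0,
                     exch_decay=3.5, c6=1.3)


def canonical_dimer(separation: float = DIMER_EQ_SEPARATION) -> EmulatedSystem:
    """Charged dimer W1...W2 at the given separation, one subsystem each."""
    frags = (
        ToyFragment(position=(0.0, 0.0, 0.0), **_DIMER_PARAMS[0]),
        ToyFragment(position=(separation, 0.0, 0.0), **_DIMER_PARAMS[1]),
    )
    scheme = FragmentScheme(("W1", "W2"), {"W1": "A", "W2": "B"})
    return emulate_led(frags, scheme)


def canonical_trimer(probe_distance: float,
                     dimer_separation: float = DIMER_EQ_SEPARATION) -> EmulatedSystem:
    """Charged dimer plus a neutral polarizable probe P3 on the dimer axis.

    ``probe_distance`` is the P3...W2 distance (Angstrom); all three
    fragments are their own subsystem, the standard setting for
    distance scans of a pair interaction under a perturbing third body.
    """
    frags = (
        ToyFragment(position=(0.0, 0.0, 0.0), **_DIMER_PARAMS[0]),
        ToyFragment(position=(dimer_separation, 0.0, 0.0), **_DIMER_PARAMS[1]),
        ToyFragment(position=(dimer_separation + probe_distance, 0.0, 0.0),
                    **_PROBE_PARAMS),
    )
    scheme = FragmentScheme(("W1", "W2", "P3"),
                            {"W1": "A", "W2": "B", "P3": "C"})
    return emulate_led(frags, scheme)


#: Default separation window of the canonical dimer scan (Angstrom):
#: from just inside the equilibrium separation out to near-dissociation,
#: where the pair interaction still varies by an order of magnitude.
DIMER_SCAN_RANGE = (2.5, 4.5)


def dimer_scan_systems(n_points: int = 20,
                       rmin: float = DIMER_SCAN_RANGE[0],
                       rmax: float = DIMER_SCAN_RANGE[1]):
    """Canonical-dimer systems over a separation grid.

    Yields ``(separation, EmulatedSystem)`` for ``n_points`` evenly spaced
    separations -- the standard input of the el-prep-vs-pair-energy
    linearity diagnostic.
    """
    if n_points < 2:
        raise ValidationError("need at least 2 scan points")
    for r in np.linspace(rmin, rmax, n_points):
        yield float(r), canonical_dimer(float(r))


def charged_trimer(scale: float = 1.0, seed: Optional[int] = None) -> EmulatedSystem:
    """Three charged polarizable fragments in a triangle (scaled geometry).

    With all three charged and polarizable within ~10 A, the field cross
    terms guarantee nonzero cooperativity; ``scale < 1`` compresses the
    geometry and raises every polarization cost.
    """
    frags = (
        ToyFragment(position=(0.0, 0.0, 0.0), charge=+0.35,
                    polarizability=1.1, exch_amp=8.0, exch_decay=3.4, c6=1.2),
        ToyFragment(position=(3.0 * scale, 0.0, 0.0), charge=-0.35,
                    polarizability=1.4, exch_amp=10.0, exch_decay=3.6, c6=1.0),
        ToyFragment(position=(1.5 * scale, 2.6 * scale, 0.0), charge=+0.30,
                    polarizability=1.2, exch_amp=9.0, exch_decay=3.5, c6=1.1),
    )
    scheme = FragmentScheme(("W1", "W2", "W3"),
                            {"W1": "A", "W2": "B", "W3": "C"})
    return emulate_led(frags, scheme, seed=seed)


def equilateral_trimer(side: float = 3.2) -> EmulatedSystem:
    """Three *identical* charged fragments on an equilateral triangle.

    The exact three-fold symmetry makes all fp entries equal -- a sharp
    symmetry check for the whole pipeline.
    """
    h = side * math.sqrt(3.0) / 2.0
    params = dict(charge=0.25, polarizability=1.0, exch_amp=9.0,
                  exch_decay=3.5, c6=1.0)
    frags = (
        ToyFragment(position=(0.0, 0.0, 0.0), **params),
        ToyFragment(position=(side, 0.0, 0.0), **params),
        ToyFragment(position=(side / 2.0, h, 0.0), **params),
    )
    scheme = FragmentScheme(("W1", "W2", "W3"),
                            {"W1": "A", "W2": "B", "W3": "C"})
    return emulate_led(frags, scheme)
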