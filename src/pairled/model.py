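"""Domain types for LED datasets and fragment-pairwise decomposition results.

The central objects are:

* :class:`FragmentScheme` -- the partition of a supramolecular complex into
  N fragments, each assigned to one of M subsystems.  Subsystems (e.g. a
  protein and its ligand, or two DNA strands) are the chemical entities
  whose mutual binding energy is decomposed; fragments (residues,
  nucleobases, individual molecules) are the finer pieces the maps are
  resolved over.
* :class:`EnergyChannels` -- the physical components of one inter-fragment
  pair term: electrostatics, exchange, London dispersion, non-dispersive
  correlation, plus optional named extras.
* :class:`LEDDataset` -- one calculation's complete LED term set: the total
  electronic energy, per-fragment intra-fragment energies, and the
  symmetric inter-fragment pair matrix, optionally a dielectric
  (implicit-solvent) energy change.
* :class:`PairMatrix` -- a labelled symmetric matrix over fragment pairs,
  the container all maps are returned in.

All energies are Hartree; see :mod:`pairled.units`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input object violates a structural or numerical invariant."""


# ---------------------------------------------------------------------------
# Fragment scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentScheme:
    """Fragment labels, their subsystem assignment, and optional atom lists.

    Parameters
    ----------
    fragment_labels
        Ordered, unique fragment labels.  File/matrix order follows this
        ordering everywhere.
    subsystem_of
        Mapping fragment label -> subsystem label.  Every fragment belongs
        to exactly one subsystem and every subsystem has at least one
        fragment.
    atom_indices
        Optional 1-based atom index lists per fragment (quantum-chemistry
        convention); must be non-empty and pairwise disjoint when given.
    """

    fragment_labels: Tuple[str, ...]
    subsystem_of: Mapping[str, str]
    atom_indices: Optional[Tuple[Tuple[int, ...], ...]] = None

    def __post_init__(self) -> None:
        labels = tuple(self.fragment_labels)
        object.__setattr__(self, "fragment_labels", labels)
        if len(labels) == 0:
            raise ValidationError("fragment scheme needs at least one fragment")
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate fragment labels")
        missing = [x for x in labels if x not in self.subsystem_of]
        if missing:
            raise ValidationError(f"fragments without subsystem assignment: {missing}")
        orphans = [x for x in self.subsystem_of if x not in labels]
        if orphans:
            raise ValidationError(f"subsystem assignment for unknown fragments: {orphans}")
        if self.n_fragments < self.n_subsystems:
            raise ValidationError("more subsystems than fragments")
        if self.atom_indices is not None:
            idx = tuple(tuple(a) for a in self.atom_indices)
            object.__setattr__(self, "atom_indices", idx)
            if len(idx) != len(labels):
                raise ValidationError("atom_indices length must match fragment count")
            seen: set = set()
            for lab, atoms in zip(labels, idx):
                if len(atoms) == 0:
                    raise ValidationError(f"empty atom list for fragment {lab!r}")
                if any(a < 1 for a in atoms):
                    raise ValidationError("atom indices are 1-based (>= 1)")
                if seen & set(atoms):
                    raise ValidationError("atom index lists must be pairwise disjoint")
                seen |= set(atoms)

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_labels)

    @property
    def subsystems(self) -> Tuple[str, ...]:
        """Subsystem labels in order of first appearance."""
        out: List[str] = []
        for x in self.fragment_labels:
            s = self.subsystem_of[x]
            if s not in out:
                out.append(s)
        return tuple(out)

    @property
    def n_subsystems(self) -> int:
        return len(self.subsystems)

    def fragments_of(self, subsystem: str) -> Tuple[str, ...]:
        if subsystem not in self.subsystems:
            raise KeyError(f"unknown subsystem {subsystem!r}")
        return tuple(x for x in self.fragment_labels
                     if self.subsystem_of[x] == subsystem)

    def restricted(self, subsystem: str) -> "FragmentScheme":
        """Sub-scheme containing only one subsystem's fragments."""
        frags = self.fragments_of(subsystem)
        return FragmentScheme(
            fragment_labels=frags,
            subsystem_of={x: subsystem for x in frags},
        )

    def same_subsystem(self, x: str, y: str) -> bool:
        return self.subsystem_of[x] == self.subsystem_of[y]

    def pairs(self) -> Iterator[Tuple[str, str]]:
        """All unordered fragment pairs in canonical (scheme) order."""
        labs = self.fragment_labels
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                yield labs[i], labs[j]

    def pair_key(self, x: str, y: str) -> Tuple[str, str]:
        """Canonical ordering of an unordered pair (scheme order)."""
        if x == y:
            raise ValidationError(f"self-pair ({x!r}, {x!r}) is not allowed")
        order = {lab: i for i, lab in enumerate(self.fragment_labels)}
        if x not in order or y not in order:
            raise ValidationError(f"unknown fragment in pair ({x!r}, {y!r})")
        return (x, y) if order[x] < order[y] else (y, x)


# ---------------------------------------------------------------------------
# Energy channels
# ---------------------------------------------------------------------------

#: Fixed summation order of the built-in channels.
BASE_CHANNELS = ("elstat", "exch", "disp", "no_disp")


@dataclass(frozen=True)
class EnergyChannels:
    """Physical components of one inter-fragment pair energy (Hartree).

    ``total()`` sums the channels in a fixed declared order (built-in
    channels first, then extras sorted by name) so that identical inputs
    always reduce to bit-identical floating-point totals.
    """

    elstat: float = 0.0
    exch: float = 0.0
    disp: float = 0.0
    no_disp: float = 0.0
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "extra", dict(self.extra))
        clash = set(self.extra) & set(BASE_CHANNELS)
        if clash:
            raise ValidationError(f"extra channel names clash with built-ins: {sorted(clash)}")

    def total(self) -> float:
        t = self.elstat + self.exch + self.disp + self.no_disp
        for name in sorted(self.extra):
            t += self.extra[name]
        return t

    def channel_names(self) -> Tuple[str, ...]:
        return BASE_CHANNELS + tuple(sorted(self.extra))

    def get(self, name: str) -> float:
        if name in BASE_CHANNELS:
            return getattr(self, name)
        return self.extra.get(name, 0.0)

    def __sub__(self, other: "EnergyChannels") -> "EnergyChannels":
        names = sorted(set(self.extra) | set(other.extra))
        return EnergyChannels(
            elstat=self.elstat - other.elstat,
            exch=self.exch - other.exch,
            disp=self.disp - other.disp,
            no_disp=self.no_disp - other.no_disp,
            extra={n: self.extra.get(n, 0.0) - other.extra.get(n, 0.0) for n in names},
        )

    def scaled(self, factor: float) -> "EnergyChannels":
        return EnergyChannels(
            elstat=self.elstat * factor,
            exch=self.exch * factor,
            disp=self.disp * factor,
            no_disp=self.no_disp * factor,
            extra={n: v * factor for n, v in self.extra.items()},
        )


# ---------------------------------------------------------------------------
# Symmetric pair matrix
# ---------------------------------------------------------------------------

class PairMatrix:
    """Labelled symmetric matrix over fragment pairs with a zero diagonal.

    Thin wrapper over a dense numpy array; all decomposition maps
    (epsilon, distributed electronic preparation, fp interaction, channel
    and cooperativity maps) are returned as ``PairMatrix``.  Entries may be
    NaN to flag pairs without data (partial dimer coverage).
    """

    def __init__(self, labels: Sequence[str], values: Optional[np.ndarray] = None):
        self.labels: Tuple[str, ...] = tuple(labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate labels in PairMatrix")
        n = len(self.labels)
        if values is None:
            values = np.zeros((n, n))
        values = np.asarray(values, dtype=float)
        if values.shape != (n, n):
            raise ValidationError(f"matrix shape {values.shape} does not match {n} labels")
        if not np.array_equal(values, values.T, equal_nan=True):
            raise ValidationError("PairMatrix values must be symmetric")
        if not np.all(np.diag(values) == 0.0):
            raise ValidationError("PairMatrix diagonal must be zero")
        self.values = values
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    # -- construction -------------------------------------------------------
    @classmethod
    def from_pairs(cls, labels: Sequence[str],
                   entries: Mapping[Tuple[str, str], float]) -> "PairMatrix":
        m = cls(labels)
        for (x, y), v in entries.items():
            m.set(x, y, v)
        return m

    # -- element access -----------------------------------------------------
    def get(self, x: str, y: str) -> float:
        return float(self.values[self._index[x], self._index[y]])

    def set(self, x: str, y: str, value: float) -> None:
        i, j = self._index[x], self._index[y]
        if i == j:
            raise ValidationError(f"self-pair ({x!r}, {x!r}) is not allowed")
        self.values[i, j] = value
        self.values[j, i] = value

    def pairs(self) -> Iterator[Tuple[str, str]]:
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                yield self.labels[i], self.labels[j]

    def items(self) -> Iterator[Tuple[Tuple[str, str], float]]:
        for x, y in self.pairs():
            yield (x, y), self.get(x, y)

    # -- reductions / algebra ----------------------------------------------
    def total(self) -> float:
        """Sum over all unordered pairs (upper triangle)."""
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return float(np.sum(self.values[iu]))

    def row_abs_sum(self, x: str) -> float:
        i = self._index[x]
        return float(np.sum(np.abs(self.values[i]))) - 0.0

    def __add__(self, other: "PairMatrix") -> "PairMatrix":
        self._check_same_labels(other)
        return PairMatrix(self.labels, self.values + other.values)

    def __sub__(self, other: "PairMatrix") -> "PairMatrix":
        self._check_same_labels(other)
        return PairMatrix(self.labels, self.values - other.values)

    def scaled(self, factor: float) -> "PairMatrix":
        return PairMatrix(self.labels, self.values * factor)

    def allclose(self, other: "PairMatrix", atol: float = 0.0, rtol: float = 0.0) -> bool:
        return (self.labels == other.labels
                and np.allclose(self.values, other.values,
                                atol=atol, rtol=rtol, equal_nan=True))

    def permuted(self, new_labels: Sequence[str]) -> "PairMatrix":
        """Reorder rows/columns to ``new_labels`` (a permutation of labels)."""
        if set(new_labels) != set(self.labels) or len(new_labels) != len(self.labels):
            raise ValidationError("new_labels must be a permutation of the labels")
        perm = [self._index[lab] for lab in new_labels]
        return PairMatrix(new_labels, self.values[np.ix_(perm, perm)])

    def _check_same_labels(self, other: "PairMatrix") -> None:
        if self.labels != other.labels:
            raise ValidationError("pair-set mismatch between matrices")

    # -- interop ------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PairMatrix":
        if list(df.index) != list(df.columns):
            raise ValidationError("matrix index and columns must agree")
        return cls(list(df.index), df.to_numpy(dtype=float))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PairMatrix(labels={self.labels}, total={self.total():.6e})"


# ---------------------------------------------------------------------------
# LED dataset
# ---------------------------------------------------------------------------

#: Default tolerance for the dataset completeness identity (Hartree).
#: LED blocks in program outputs carry printed-precision rounding.
DEFAULT_COMPLETENESS_TOL = 1e-6


@dataclass
class LEDDataset:
    """One calculation's full LED term set (all energies in Hartree).

    The completeness identity

    ``total_energy == sum_X intra[X] + sum_{X<Y} inter[(X,Y)].total() + dielectric``

    must hold to ``completeness_tol``; ``validate()`` enforces it together
    with the structural pair-set requirements.
    """

    scheme: FragmentScheme
    total_energy: float
    intra: Dict[str, float]
    inter: Dict[Tuple[str, str], EnergyChannels]
    method_label: str = ""
    dielectric: Optional[float] = None
    completeness_tol: float = DEFAULT_COMPLETENESS_TOL

    def __post_init__(self) -> None:
        # canonicalize pair keys to scheme order
        canon: Dict[Tuple[str, str], EnergyChannels] = {}
        for (x, y), ch in self.inter.items():
            key = self.scheme.pair_key(x, y)
            if key in canon:
                raise ValidationError(f"duplicate pair entry for {key}")
            canon[key] = ch
        self.inter = canon

    # -- derived quantities --------------------------------------------------
    def intra_sum(self) -> float:
        return float(sum(self.intra[x] for x in self.scheme.fragment_labels))

    def inter_sum(self) -> float:
        return float(sum(self.inter[p].total() for p in self.scheme.pairs()))

    def completeness_residual(self) -> float:
        d = self.dielectric if self.dielectric is not None else 0.0
        return self.total_energy - self.intra_sum() - self.inter_sum() - d

    def channel_names(self) -> Tuple[str, ...]:
        extras: set = set()
        for ch in self.inter.values():
            extras |= set(ch.extra)
        return BASE_CHANNELS + tuple(sorted(extras))

    def inter_matrix(self) -> PairMatrix:
        """Total inter-fragment pair energies as a PairMatrix."""
        m = PairMatrix(self.scheme.fragment_labels)
        for p in self.scheme.pairs():
            m.set(*p, self.inter[p].total())
        return m

    def channel_matrix(self, name: str) -> PairMatrix:
        m = PairMatrix(self.scheme.fragment_labels)
        for p in self.scheme.pairs():
            m.set(*p, self.inter[p].get(name))
        return m

    # -- validation ----------------------------------------------------------
    def validate(self) -> "LEDDataset":
        labels = set(self.scheme.fragment_labels)
        extra_intra = set(self.intra) - labels
        if extra_intra:
            raise ValidationError(f"intra terms for unknown fragments: {sorted(extra_intra)}")
        missing_intra = labels - set(self.intra)
        if missing_intra:
            raise ValidationError(f"missing intra terms: {sorted(missing_intra)}")
        expected = set(self.scheme.pairs())
        missing = expected - set(self.inter)
        if missing:
            pair = sorted(missing)[0]
            raise ValidationError(
                f"incomplete pair matrix: missing entry for pair {pair}")
        spurious = set(self.inter) - expected
        if spurious:
            raise ValidationError(f"pair entries for unknown pairs: {sorted(spurious)}")
        res = self.completeness_residual()
        if not math.isfinite(res) or abs(res) > self.completeness_tol:
            raise ValidationError(
                "completeness violation: total_energy differs from the sum of "
                f"intra + inter (+ dielectric) terms by {res:.6e} Hartree "
                f"(tolerance {self.completeness_tol:.1e})")
        return self


# ---------------------------------------------------------------------------
# Isolated-subsystem references
# ---------------------------------------------------------------------------

@dataclass
class SubsystemReferenceSet:
    """Isolated-subsystem LED datasets, one per subsystem of a parent scheme.

    Each reference calculation contains exactly its subsystem's fragments
    (same labels, same channel conventions) at the complex geometry; the
    union of the reference fragment sets must equal the supersystem's.
    """

    parent_scheme: FragmentScheme
    references: Dict[str, LEDDataset]

    def validate(self) -> "SubsystemReferenceSet":
        subs = set(self.parent_scheme.subsystems)
        if set(self.references) != subs:
            raise ValidationError(
                f"reference set covers {sorted(self.references)}, "
                f"expected subsystems {sorted(subs)}")
        covered: set = set()
        for sub, ds in self.references.items():
            frags = set(ds.scheme.fragment_labels)
            expected = set(self.parent_scheme.fragments_of(sub))
            if frags != expected:
                raise ValidationError(
                    f"reference for subsystem {sub!r} holds fragments "
                    f"{sorted(frags)}, expected {sorted(expected)}")
            if covered & frags:
                raise ValidationError("overlapping fragments across references")
            covered |= frags
            ds.validate()
        return self

    def total_isolated_energy(self) -> float:
        """E_isol: sum of the isolated subsystem total energies."""
        return float(sum(self.references[s].total_energy
                         for s in self.parent_scheme.subsystems))

    def reference_of(self, fragment: str) -> LEDDataset:
        return self.references[self.parent_scheme.subsystem_of[fragment]]


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class FPLEDResult:
    """Fragment-pairwise decomposition of a binding energy.

    ``fp_map`` is the exact pairwise decomposition: its entries sum to
    ``delta_e_int``.  ``channel_maps`` resolves it into physical components
    (one map per pair channel plus an ``"el-prep"`` map equal to
    ``el_prep_pairs``); the channel maps sum entrywise to ``fp_map``.
    """

    scheme: FragmentScheme
    delta_e_int: float
    epsilon: PairMatrix
    el_prep: Dict[str, float]
    el_prep_pairs: PairMatrix
    fp_map: PairMatrix
    channel_maps: Dict[str, PairMatrix]
    weight_mode: str
    metadata: Dict[str, object] = field(default_factory=dict)

    def el_prep_sum(self) -> float:
        return float(sum(self.el_prep[x] for x in self.scheme.fragment_labels))


@dataclass
class CooperativityResult:
    """fp map vs two-body (MBE) map: entrywise difference and totals.

    ``coop = fp_map - two_body`` entrywise; ``total_coop`` is the many-body
    contribution to binding, ``delta_e_int - sum(two_body)``.  ``partial``
    flags incomplete dimer coverage (NaN entries in ``two_body``).
    """

    two_body: PairMatrix
    coop: PairMatrix
    total_coop: float
    partial: bool = False


@dataclass(frozen=True)
class DimerReference:
    """One pair's MBE two-body input, all at the complex geometry.

    ``dimer_energy`` and both ``monomer_energies`` are evaluated with the
    fragments frozen at their positions in the complex; relaxed-monomer
    energies must never be used here (they would mix geometric preparation
    into the two-body terms).
    """

    pair: Tuple[str, str]
    dimer_energy: float
    monomer_energies: Tuple[float, float]


# ---------------------------------------------------------------------------
# Weight configuration for the el-prep distribution
# ---------------------------------------------------------------------------

WEIGHT_MODES = ("abs_epsilon", "squared_epsilon", "equal")
ZERO_ROW_POLICIES = ("equal_split", "error")


@dataclass(frozen=True)
class WeightConfig:
    """How a fragment's electronic-preparation energy is shared over its pairs.

    ``abs_epsilon`` (default): proportional to |epsilon_XY| -- magnitudes,
    not signed values, so near-cancelling rows cannot produce exploding
    weights.  ``squared_epsilon`` and ``equal`` are offered for sensitivity
    analysis; every mode conserves the total by construction.

    ``zero_row_policy`` governs a fragment whose epsilon row is all zero
    (it then has essentially no el-prep either): ``equal_split`` shares
    equally over its pairs, ``error`` aborts.
    """

    mode: str = "abs_epsilon"
    zero_row_policy: str = "equal_split"

    def __post_init__(self) -> None:
        if self.mode not in WEIGHT_MODES:
            raise ValidationError(f"unknown weight mode {self.mode!r}; "
                                  f"choose from {WEIGHT_MODES}")
        if self.zero_row_policy not in ZERO_ROW_POLICIES:
            raise ValidationError(f"unknown zero_row_policy {self.zero_row_policy!r}; "
                                  f"choose from {ZERO_ROW_POLICIES}")
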