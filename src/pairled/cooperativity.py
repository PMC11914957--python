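"""Many-body cooperativity: fp map versus the two-body (MBE) matrix.

The many-body expansion approximates a binding energy starting from
isolated fragments and adding dimer ("two-body"), trimer, ... terms.  The
two-body matrix collects, for every fragment pair, the dimer interaction
energy at the *complex* geometry:

    dE2(X, Y) = E_dimer(XY) - E_monomer(X) - E_monomer(Y)

(all frozen at the complex coordinates -- relaxed-monomer energies would
mix geometric preparation into the comparison and are deliberately not
representable here).  Subtracting this from the fp interaction map
entrywise yields the cooperativity matrix: how much each pair interaction
is strengthened or weakened by the chemical environment.  Its total equals
the full many-body contribution dE_int - sum(dE2).
"""

from __future__ import annotations

from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    CooperativityResult,
    DimerReference,
    FPLEDResult,
    FragmentScheme,
    PairMatrix,
    ValidationError,
)


def two_body_matrix(dimers: Iterable[DimerReference],
                    scheme: FragmentScheme) -> PairMatrix:
    """Assemble the MBE two-body matrix from dimer references.

    Pairs without a dimer reference are flagged NaN (absent); downstream
    cooperativity totals are then reported as partial.
    """
    vals = np.full((scheme.n_fragments,) * 2, np.nan)
    np.fill_diagonal(vals, 0.0)
    m = PairMatrix(scheme.fragment_labels, vals)
    seen: set = set()
    for d in dimers:
        key = scheme.pair_key(*d.pair)
        if key in seen:
            raise ValidationError(f"duplicate dimer reference for pair {key}")
        seen.add(key)
        m.set(*key, d.dimer_energy - d.monomer_energies[0] - d.monomer_energies[1])
    return m


def cooperativity_matrix(fp: FPLEDResult,
                         two_body: PairMatrix) -> CooperativityResult:
    """Entrywise fp-minus-two-body cooperativity matrix and totals.

    ``total_coop = dE_int - sum(two_body)``; with partial dimer coverage
    the sum runs over covered pairs only and the result is flagged
    ``partial``.
    """
    if fp.fp_map.labels != two_body.labels:
        raise ValidationError("pair-set mismatch between fp map and two-body matrix")
    coop = fp.fp_map - two_body
    covered = ~np.isnan(two_body.values)
    partial = not bool(np.all(covered))
    n = len(two_body.labels)
    iu = np.triu_indices(n, k=1)
    tb_vals = two_body.values[iu]
    tb_sum = float(np.nansum(tb_vals))
    return CooperativityResult(
        two_body=two_body,
        coop=coop,
        total_coop=fp.delta_e_int - tb_sum,
        partial=partial,
    )


def pair_scan(system_factory: Callable[[float], object],
              pair: Tuple[str, str],
              distances: Sequence[float]) -> pd.DataFrame:
    """Scan a perturbing-body distance and track one pair's interaction.

    ``system_factory(d)`` must return an emulated system bundle (see
    :func:`pairled.emulator.emulate_led`) for perturber distance ``d`` in
    Angstrom.  For each distance the fp entry, the two-body entry, and
    their difference (cooperativity) for ``pair`` are tabulated -- the
    classic picture of a pair interaction strengthening as a third body
    approaches while the frozen two-body term cannot respond.
    """
    from .decomposition import fp_map as _fp_map

    distances = list(distances)
    if len(distances) < 2:
        raise ValidationError("need at least 2 distances to scan")
    if any(d <= 0 for d in distances):
        raise ValidationError("distances must be positive")

    rows: List[Dict[str, float]] = []
    for d in distances:
        system = system_factory(d)
        result = _fp_map(system.supersystem, system.references)
        tb = two_body_matrix(system.dimers, system.scheme)
        coop = cooperativity_matrix(result, tb)
        x, y = system.scheme.pair_key(*pair)
        rows.append({
            "distance": float(d),
            "fp": result.fp_map.get(x, y),
            "two_body": tb.get(x, y),
            "coop": coop.coop.get(x, y),
        })
    return pd.DataFrame(rows)
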