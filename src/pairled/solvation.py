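"""Physical-component totals and implicit-solvent dielectric distribution.

``physical_summary`` reduces the per-channel fp maps to one total per
physical component (electronic preparation, electrostatics, exchange,
dispersion, non-dispersive correlation, any extras); the totals close on
the binding energy exactly, which makes them the numbers quoted in
"decomposition of the interaction energy into physical contributions"
tables.

``distribute_dielectric`` spreads a scalar implicit-solvation energy
change over fragment pairs.  The default rule is the simplest conserving
one: a single global normalization proportional to |epsilon| over all
pairs (unlike the el-prep split, which normalizes per fragment).  The rule
is provisional and pluggable through the same :class:`WeightConfig`
machinery.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .model import (
    FPLEDResult,
    PairMatrix,
    ValidationError,
    WeightConfig,
)
from .decomposition import _weight_transform


def physical_summary(fp: FPLEDResult) -> Dict[str, float]:
    """Total per physical channel; the values sum to the binding energy."""
    return {name: m.total() for name, m in fp.channel_maps.items()}


def distribute_dielectric(dielectric_change: float, epsilon: PairMatrix,
                          cfg: Optional[WeightConfig] = None) -> PairMatrix:
    """Distribute a dielectric energy change onto fragment pairs.

    The returned map sums to ``dielectric_change`` exactly.  With the
    default ``abs_epsilon`` mode each pair receives a share proportional to
    |epsilon(X,Y)| under one global normalization; ``equal`` splits
    uniformly.  An all-zero epsilon matrix falls back to an equal split
    unless ``zero_row_policy='error'``.
    """
    cfg = cfg or WeightConfig()
    if not np.isfinite(dielectric_change):
        raise ValidationError("dielectric change must be finite")
    n = len(epsilon.labels)
    if n < 2:
        raise ValidationError("no pairs to distribute over (need at least 2 fragments)")
    iu = np.triu_indices(n, k=1)
    g = _weight_transform(epsilon.values, cfg.mode)[iu]
    total = g.sum()
    if total == 0.0:
        if cfg.zero_row_policy == "error":
            raise ValidationError(
                "all-zero epsilon matrix (zero_row_policy='error')")
        shares = np.full(g.shape, 1.0 / len(g))
    else:
        shares = g / total
    vals = np.zeros((n, n))
    vals[iu] = dielectric_change * shares
    vals = vals + vals.T
    return PairMatrix(epsilon.labels, vals)


def solvated_fp_map(fp: FPLEDResult, dielectric_change: float,
                    cfg: Optional[WeightConfig] = None) -> PairMatrix:
    """Gas-phase fp map plus the distributed dielectric map."""
    return fp.fp_map + distribute_dielectric(dielectric_change, fp.epsilon, cfg)
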