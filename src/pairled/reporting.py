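"""Heat-map rendering and plain-text/CSV reporting of decomposition results.

All exports are deterministic: CSV matrices round-trip to the exact
in-memory values, fragment order always follows the input scheme, and no
timestamps are written, so re-running on the same inputs reproduces the
output byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Union

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import __version__
from .model import CooperativityResult, FPLEDResult, PairMatrix, ValidationError
from .io import write_matrix_csv
from .units import HARTREE_TO_KCAL


def render_heatmap(matrix: PairMatrix, path: Union[str, Path],
                   units: str = "kcal/mol", title: Optional[str] = None,
                   cmap: str = "RdBu_r") -> None:
    """Render an annotated symmetric heat map of a pair matrix.

    Cell annotations are printed in the requested units (``"hartree"`` or
    ``"kcal/mol"``); the color scale is symmetric about zero so attractive
    (negative) and repulsive (positive) entries are visually comparable.
    """
    labels = matrix.labels
    if len(labels) == 0:
        raise ValidationError("cannot render a heat map without labels")
    unit = units.lower()
    if unit == "kcal/mol":
        vals = matrix.values * HARTREE_TO_KCAL
    elif unit == "hartree":
        vals = matrix.values.copy()
    else:
        raise ValidationError(f"unknown units {units!r}")

    n = len(labels)
    vmax = float(np.nanmax(np.abs(vals))) or 1.0
    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * n, 1.0 + 0.8 * n))
    im = ax.imshow(vals, cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(n), labels, rotation=45, ha="right")
    ax.set_yticks(range(n), labels)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            v = vals[i, j]
            txt = "n/a" if np.isnan(v) else f"{v:.2f}"
            ax.text(j, i, txt, ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label=units)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _top_pairs(matrix: PairMatrix, k: int, attractive: bool):
    entries = [((x, y), v) for (x, y), v in matrix.items() if not np.isnan(v)]
    entries.sort(key=lambda t: t[1], reverse=not attractive)
    return entries[:k]


def report(fp: FPLEDResult, path: Union[str, Path],
           coop: Optional[CooperativityResult] = None,
           top_k: int = 5, units: str = "kcal/mol") -> Dict[str, Path]:
    """Write the full report bundle for a decomposition result.

    Produces ``summary.txt`` (binding energy, channel totals, strongest
    attractive/repulsive pairs), ``fp_map.csv``, ``epsilon.csv``,
    ``channels/<name>.csv``, optionally ``two_body.csv``/``coop.csv``, and
    ``provenance.json`` (package version, weight mode, tolerances).
    Returns the paths written.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    factor = HARTREE_TO_KCAL if units.lower() == "kcal/mol" else 1.0

    def fmt(v: float) -> str:
        return f"{v * factor:12.6f}"

    lines = []
    lines.append("fragment-pairwise interaction energy decomposition")
    lines.append(f"fragments: {', '.join(fp.scheme.fragment_labels)}")
    lines.append(f"subsystems: {', '.join(fp.scheme.subsystems)}")
    lines.append(f"weight mode: {fp.weight_mode}")
    lines.append(f"energies in {units}")
    lines.append("")
    lines.append(f"binding energy dE_int      = {fmt(fp.delta_e_int)}")
    lines.append(f"el-prep total              = {fmt(fp.el_prep_sum())}")
    lines.append("")
    lines.append("channel totals (sum = dE_int):")
    for name in sorted(fp.channel_maps):
        lines.append(f"  {name:12s} {fmt(fp.channel_maps[name].total())}")
    lines.append("")
    lines.append(f"strongest attractive pairs (top {top_k}):")
    for (x, y), v in _top_pairs(fp.fp_map, top_k, attractive=True):
        lines.append(f"  {x:8s} {y:8s} {fmt(v)}")
    lines.append(f"strongest repulsive pairs (top {top_k}):")
    for (x, y), v in _top_pairs(fp.fp_map, top_k, attractive=False):
        lines.append(f"  {x:8s} {y:8s} {fmt(v)}")
    if coop is not None:
        lines.append("")
        tag = " (partial dimer coverage)" if coop.partial else ""
        lines.append(f"total cooperativity{tag}   = {fmt(coop.total_coop)}")
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written["summary"] = summary

    write_matrix_csv(fp.fp_map, outdir / "fp_map.csv")
    written["fp_map"] = outdir / "fp_map.csv"
    write_matrix_csv(fp.epsilon, outdir / "epsilon.csv")
    written["epsilon"] = outdir / "epsilon.csv"
    chan_dir = outdir / "channels"
    chan_dir.mkdir(exist_ok=True)
    for name, m in fp.channel_maps.items():
        safe = name.replace("/", "_")
        write_matrix_csv(m, chan_dir / f"{safe}.csv")
        written[f"channel:{name}"] = chan_dir / f"{safe}.csv"
    if coop is not None:
        write_matrix_csv(coop.two_body, outdir / "two_body.csv")
        write_matrix_csv(coop.coop, outdir / "coop.csv")
        written["two_body"] = outdir / "two_body.csv"
        written["coop"] = outdir / "coop.csv"

    prov = {
        "pairled_version": __version__,
        "weight_mode": fp.weight_mode,
        "units": units,
        "metadata": {k: v for k, v in sorted(fp.metadata.items())},
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=1, sort_keys=True) + "\n")
    written["provenance"] = prov_path
    return written
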