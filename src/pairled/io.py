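"""Readers and writers for LED datasets and pair matrices.

Two on-disk representations are supported:

* the **canonical JSON format** (``format: "pairled-led", format_version: 1``),
  the package's own structured dialect: key-sorted, full-precision, and
  round-trip value-identical;
* a **plain-text block dialect** for program-output-style files
  (``parse_program_output``), documented in ``docs/formats.md``.

Energies in files carry an explicit unit declaration (``hartree`` or
``kcal/mol``); everything is converted to Hartree on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import pandas as pd

from .model import (
    EnergyChannels,
    FragmentScheme,
    LEDDataset,
    PairMatrix,
    SubsystemReferenceSet,
    ValidationError,
    DEFAULT_COMPLETENESS_TOL,
)
from .units import HARTREE_TO_KCAL, KNOWN_UNITS

PAIR_SEP = "|"
FORMAT_NAME = "pairled-led"
FORMAT_VERSION = 1


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


def _unit_factor_to_hartree(unit: str) -> float:
    unit = unit.lower()
    if unit not in KNOWN_UNITS:
        raise FormatError(f"unknown unit {unit!r}; expected one of {KNOWN_UNITS}")
    return 1.0 if unit == "hartree" else 1.0 / HARTREE_TO_KCAL


# ---------------------------------------------------------------------------
# Canonical JSON format
# ---------------------------------------------------------------------------

def read_led_file(path: Union[str, Path], unit_hint: Optional[str] = None,
                  completeness_tol: Optional[float] = None) -> LEDDataset:
    """Read a canonical-format LED dataset and validate it.

    ``unit_hint`` supplies the unit only if the file does not declare one.
    The returned dataset is in Hartree and has passed ``validate()``
    (including the completeness identity).
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != FORMAT_NAME:
        raise FormatError(f"{path}: not a {FORMAT_NAME} file")
    unit = doc.get("unit") or unit_hint
    if unit is None:
        raise FormatError(f"{path}: no unit declared and no unit hint given")
    f = _unit_factor_to_hartree(unit)

    frags = doc.get("fragments")
    if not frags:
        raise FormatError(f"{path}: missing fragments section")
    labels = tuple(fr["label"] for fr in frags)
    subsystem_of = {fr["label"]: fr.get("subsystem", fr["label"]) for fr in frags}
    atoms = None
    if all("atoms" in fr for fr in frags):
        atoms = tuple(tuple(fr["atoms"]) for fr in frags)
    scheme = FragmentScheme(labels, subsystem_of, atoms)

    intra = {x: float(v) * f for x, v in doc["intra"].items()}
    inter: Dict[Tuple[str, str], EnergyChannels] = {}
    for key, ch in doc["inter"].items():
        parts = key.split(PAIR_SEP)
        if len(parts) != 2:
            raise FormatError(f"{path}: malformed pair key {key!r}")
        inter[(parts[0], parts[1])] = EnergyChannels(
            elstat=float(ch.get("elstat", 0.0)) * f,
            exch=float(ch.get("exch", 0.0)) * f,
            disp=float(ch.get("disp", 0.0)) * f,
            no_disp=float(ch.get("no_disp", 0.0)) * f,
            extra={n: float(v) * f for n, v in ch.get("extra", {}).items()},
        )

    dielectric = doc.get("dielectric")
    tol = completeness_tol
    if tol is None:
        tol = float(doc.get("completeness_tol", DEFAULT_COMPLETENESS_TOL))
    ds = LEDDataset(
        scheme=scheme,
        total_energy=float(doc["total_energy"]) * f,
        intra=intra,
        inter=inter,
        method_label=doc.get("method", ""),
        dielectric=None if dielectric is None else float(dielectric) * f,
        completeness_tol=tol,
    )
    return ds.validate()


def write_led_file(dataset: LEDDataset, path: Union[str, Path],
                   unit: str = "hartree") -> None:
    """Write a dataset in the canonical JSON format (key-sorted, full precision)."""
    f = 1.0 / _unit_factor_to_hartree(unit)  # Hartree -> requested unit
    scheme = dataset.scheme
    frags = []
    for i, lab in enumerate(scheme.fragment_labels):
        entry: Dict[str, object] = {"label": lab, "subsystem": scheme.subsystem_of[lab]}
        if scheme.atom_indices is not None:
            entry["atoms"] = list(scheme.atom_indices[i])
        frags.append(entry)
    inter: Dict[str, Dict[str, object]] = {}
    for (x, y), ch in dataset.inter.items():
        rec: Dict[str, object] = {
            "elstat": ch.elstat * f, "exch": ch.exch * f,
            "disp": ch.disp * f, "no_disp": ch.no_disp * f,
        }
        if ch.extra:
            rec["extra"] = {n: v * f for n, v in sorted(ch.extra.items())}
        inter[f"{x}{PAIR_SEP}{y}"] = rec
    doc: Dict[str, object] = {
        "format": FORMAT_NAME,
        "format_version": FORMAT_VERSION,
        "unit": unit.lower(),
        "method": dataset.method_label,
        "fragments": frags,
        "total_energy": dataset.total_energy * f,
        "intra": {x: dataset.intra[x] * f for x in scheme.fragment_labels},
        "inter": inter,
        "completeness_tol": dataset.completeness_tol,
    }
    if dataset.dielectric is not None:
        doc["dielectric"] = dataset.dielectric * f
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_reference_set(parent: LEDDataset,
                       paths: Dict[str, Union[str, Path]]) -> SubsystemReferenceSet:
    """Read one isolated-subsystem dataset per subsystem label and validate."""
    refs = {sub: read_led_file(p) for sub, p in paths.items()}
    return SubsystemReferenceSet(parent_scheme=parent.scheme,
                                 references=refs).validate()


# ---------------------------------------------------------------------------
# Plain-text program-output dialect
# ---------------------------------------------------------------------------

BLOCK_START = "LED SUMMARY"
BLOCK_END = "END LED SUMMARY"


def parse_program_output(path: Union[str, Path],
                         dialect: str = "pairled-v1") -> LEDDataset:
    """Extract an LED dataset from a plain-text output file.

    The grammar (``docs/formats.md``) is line-oriented: a block opens with
    ``LED SUMMARY``, closes with ``END LED SUMMARY``, and contains ``UNIT``,
    ``METHOD``, ``FRAGMENTS <n>``, ``FRAGMENT <label> SUBSYSTEM <label>``,
    ``TOTAL ENERGY <v>``, ``INTRA <label> <v>``, ``DIELECTRIC <v>`` and
    ``PAIR <x> <y> ELSTAT <v> EXCH <v> DISP <v> NODISP <v> [<NAME> <v> ...]``
    records.  Anything outside the block is ignored; unrecognized records
    inside it are collected as warnings on the dataset metadata.
    """
    if dialect != "pairled-v1":
        raise FormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    lines = path.read_text().splitlines()

    start = None
    for i, line in enumerate(lines):
        if line.strip().startswith(BLOCK_START):
            start = i
            break
    if start is None:
        raise FormatError(f"{path}: no LED block found")

    unit: Optional[str] = None
    method = ""
    n_declared: Optional[int] = None
    labels: list = []
    subsystem_of: Dict[str, str] = {}
    total_energy: Optional[float] = None
    intra: Dict[str, float] = {}
    inter: Dict[Tuple[str, str], EnergyChannels] = {}
    dielectric: Optional[float] = None
    warnings: list = []
    closed = False

    for lineno in range(start + 1, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if line.startswith(BLOCK_END):
            closed = True
            break
        tok = line.split()
        try:
            if tok[0] == "UNIT":
                unit = " ".join(tok[1:]).lower()
            elif tok[0] == "METHOD":
                method = " ".join(tok[1:])
            elif tok[0] == "FRAGMENTS":
                n_declared = int(tok[1])
            elif tok[0] == "FRAGMENT":
                if len(tok) != 4 or tok[2] != "SUBSYSTEM":
                    raise FormatError("malformed FRAGMENT record")
                labels.append(tok[1])
                subsystem_of[tok[1]] = tok[3]
            elif tok[0] == "TOTAL" and len(tok) >= 3 and tok[1] == "ENERGY":
                total_energy = float(tok[2])
            elif tok[0] == "INTRA":
                intra[tok[1]] = float(tok[2])
            elif tok[0] == "DIELECTRIC":
                dielectric = float(tok[1])
            elif tok[0] == "PAIR":
                x, y = tok[1], tok[2]
                fields = tok[3:]
                if len(fields) % 2 != 0:
                    raise FormatError("odd channel field count in PAIR record")
                chans: Dict[str, float] = {}
                for k in range(0, len(fields), 2):
                    chans[fields[k].upper()] = float(fields[k + 1])
                base = {"ELSTAT", "EXCH", "DISP", "NODISP"}
                missing = base - set(chans)
                if missing:
                    raise FormatError(f"PAIR record missing channels {sorted(missing)}")
                inter[(x, y)] = EnergyChannels(
                    elstat=chans.pop("ELSTAT"), exch=chans.pop("EXCH"),
                    disp=chans.pop("DISP"), no_disp=chans.pop("NODISP"),
                    extra={n.lower(): v for n, v in chans.items()},
                )
            else:
                warnings.append(f"line {lineno + 1}: unrecognized record {tok[0]!r}")
        except (FormatError, ValueError, IndexError) as exc:
            raise FormatError(f"{path}: line {lineno + 1}: {exc}") from None

    if not closed:
        raise FormatError(
            f"{path}: truncated LED block (no '{BLOCK_END}' before line {len(lines)})")
    if unit is None:
        raise FormatError(f"{path}: LED block declares no UNIT")
    if n_declared is not None and n_declared != len(labels):
        raise FormatError(
            f"{path}: header declares {n_declared} fragments but "
            f"{len(labels)} FRAGMENT records found")
    if total_energy is None:
        raise FormatError(f"{path}: LED block has no TOTAL ENERGY record")

    f = _unit_factor_to_hartree(unit)
    ds = LEDDataset(
        scheme=FragmentScheme(tuple(labels), subsystem_of),
        total_energy=total_energy * f,
        intra={x: v * f for x, v in intra.items()},
        inter={p: ch.scaled(f) for p, ch in inter.items()},
        method_label=method,
        dielectric=None if dielectric is None else dielectric * f,
    )
    ds.validate()
    if warnings:
        # surface unparsed-but-present records without failing the read
        import warnings as _w
        for msg in warnings:
            _w.warn(f"{path}: {msg}", stacklevel=2)
    return ds


# ---------------------------------------------------------------------------
# CSV matrices
# ---------------------------------------------------------------------------

def write_matrix_csv(matrix: PairMatrix, path: Union[str, Path]) -> None:
    """Write a pair matrix as a labelled CSV (full float precision).

    Values are written with ``repr`` so that reading the file restores the
    exact in-memory doubles.
    """
    labels = matrix.labels
    with open(path, "w") as fh:
        fh.write("," + ",".join(labels) + "\n")
        for i, lab in enumerate(labels):
            row = ",".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{lab},{row}\n")


def read_matrix_csv(path: Union[str, Path]) -> PairMatrix:
    """Read a labelled CSV written by :func:`write_matrix_csv`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    try:
        return PairMatrix.from_dataframe(df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from None
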