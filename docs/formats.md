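# File formats

## Canonical dataset format (JSON), version 1

The package's structured exchange format for one LED calculation.
`format` and `format_version` are mandatory; serialization is key-sorted
and full-precision, so write/read round-trips are value-identical.

```json
{
 "format": "pairled-led",
 "format_version": 1,
 "unit": "hartree",
 "method": "DLPNO-CCSD(T)",
 "fragments": [
  {"label": "W1", "subsystem": "A", "atoms": [1, 2, 3]},
  {"label": "W2", "subsystem": "B", "atoms": [4, 5, 6]}
 ],
 "total_energy": -152.6,
 "intra": {"W1": -76.3, "W2": -76.29},
 "inter": {
  "W1|W2": {"elstat": -0.008, "exch": 0.002, "disp": -0.003, "no_disp": -0.001,
            "extra": {"triples": 0.0}}
 },
 "dielectric": -0.0005,
 "completeness_tol": 1e-06
}
```

Rules:

* `unit` is `hartree` or `kcal/mol` (1 Hartree = 627.509474 kcal/mol,
  fixed). Everything is converted to Hartree on read.
* Fragment order in `fragments` defines matrix order everywhere.
* `atoms` lists are optional, 1-based, non-empty, pairwise disjoint.
* `inter` keys are `X|Y` pairs; exactly one entry per unordered pair of
  distinct fragments (no self-pairs). Absent `extra` means no extra
  channels.
* Completeness: `total_energy` must equal the sum of all `intra` terms,
  all `inter` channel totals, and `dielectric` (if present) within
  `completeness_tol` (default 1e-6 Hartree, accounts for
  printed-precision rounding in upstream outputs).

## Plain-text block dialect, `pairled-v1`

A best-effort line-oriented grammar for LED summary blocks embedded in
program-output-style text files. Everything outside the block is ignored.

```
LED SUMMARY
UNIT Hartree
METHOD DLPNO-CCSD(T)
FRAGMENTS 2
FRAGMENT W1 SUBSYSTEM A
FRAGMENT W2 SUBSYSTEM B
TOTAL ENERGY -152.6
INTRA W1 -76.3
INTRA W2 -76.29
DIELECTRIC -0.0005
PAIR W1 W2 ELSTAT -0.008 EXCH 0.002 DISP -0.003 NODISP -0.0095
END LED SUMMARY
```

* The block opens at the first line starting with `LED SUMMARY` and must
  close with `END LED SUMMARY` (a missing terminator is a truncation
  error reported with the line number).
* `PAIR` records require `ELSTAT`, `EXCH`, `DISP`, `NODISP`; further
  `NAME value` pairs become extra channels (names lower-cased).
* `FRAGMENTS <n>` (optional header) must match the number of `FRAGMENT`
  records.
* Unrecognized records inside the block are surfaced as warnings, not
  errors.
* The grammar is frozen per dialect version; new upstream layouts get a
  new dialect name rather than silent changes.

## Pair-matrix CSV

Symmetric matrices (fp map, channel maps, cooperativity, ...) are
exported as labelled CSV with fragment labels as both header row and
index column, full float precision; `read_matrix_csv` restores the exact
in-memory values. `NaN` marks pairs without data (e.g. missing dimer
references).
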