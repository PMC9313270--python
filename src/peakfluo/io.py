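"""Plate / layout / results file formats.

- Plate CSV (wide): header ``cycle,<well_id_1>,...``; one row per cycle;
  fluorescence written with 6 significant digits.
- Layout CSV: ``well_id,role,concentration_ng_ml,replicate_group``; the
  concentration cell is left empty for blinded unknowns.
- Results are JSON with sorted keys so identical runs are byte-identical.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .errors import PlateFormatError
from .trace import FluorescenceTrace, PlateLayout, WellSpec


def write_plate(traces: Sequence[FluorescenceTrace], path: str | Path) -> None:
    if not traces:
        raise ValueError("no traces to write")
    first = traces[0]
    for t in traces[1:]:
        first.require_same_grid(t)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cycle"] + [t.well_id for t in traces])
        for i, cycle in enumerate(first.cycles):
            writer.writerow(
                [int(cycle)] + [format(t.fluorescence[i], ".6g") for t in traces]
            )


def read_plate(path: str | Path) -> list[FluorescenceTrace]:
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise PlateFormatError(f"{path}: empty file")
    header = rows[0]
    if not header or header[0] != "cycle":
        raise PlateFormatError(f"{path}: first column must be 'cycle'")
    wells = header[1:]
    if not wells:
        raise PlateFormatError(f"{path}: no well columns")
    if len(set(wells)) != len(wells):
        dupes = sorted({w for w in wells if wells.count(w) > 1})
        raise PlateFormatError(f"{path}: duplicate well columns {dupes}")
    cycles, data = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise PlateFormatError(
                f"{path}:{lineno}: expected {len(header)} cells, got {len(row)}"
            )
        try:
            cycles.append(int(row[0]))
            data.append([float(v) for v in row[1:]])
        except ValueError as exc:
            raise PlateFormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from exc
    cycles_arr = np.asarray(cycles)
    if len(cycles_arr) == 0:
        raise PlateFormatError(f"{path}: no data rows")
    if cycles_arr[0] != 1 or not np.all(np.diff(cycles_arr) == 1):
        raise PlateFormatError(f"{path}: cycle column must run contiguously from 1")
    matrix = np.asarray(data)
    return [
        FluorescenceTrace(well, cycles_arr.copy(), matrix[:, j])
        for j, well in enumerate(wells)
    ]


def write_layout(
    layout: PlateLayout, path: str | Path, blind_unknowns: bool = False
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well_id", "role", "concentration_ng_ml", "replicate_group"])
        for w in layout.wells:
            conc = w.concentration
            if blind_unknowns and w.role == "unknown":
                conc = None
            writer.writerow(
                [w.well_id, w.role, "" if conc is None else format(conc, "g"), w.replicate_group]
            )


def read_layout(path: str | Path) -> PlateLayout:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"well_id", "role", "concentration_ng_ml", "replicate_group"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise PlateFormatError(
                f"{path}: layout header must contain {sorted(required)}"
            )
        wells = []
        for lineno, row in enumerate(reader, start=2):
            raw = (row["concentration_ng_ml"] or "").strip()
            try:
                conc = float(raw) if raw else None
            except ValueError as exc:
                raise PlateFormatError(
                    f"{path}:{lineno}: bad concentration {raw!r}"
                ) from exc
            wells.append(
                WellSpec(row["well_id"], row["role"], conc, row["replicate_group"])
            )
    return PlateLayout(tuple(wells))


def canonical_json(obj: Any) -> str:
    return json.dumps(obj, sort_keys=True, indent=2, allow_nan=True)


def config_hash(config_dict: dict) -> str:
    digest = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, separators=(",", ":"), default=str).encode()
    )
    return digest.hexdigest()[:16]


def write_results(report: dict, path: str | Path) -> None:
    Path(path).write_text(canonical_json(report) + "\n")
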