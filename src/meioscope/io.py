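"""Readers and writers for the canonical tabular exchange formats.

``bivalents.csv`` holds one row per bivalent::

    genotype,cell_id,pair_index,stage,config,n_class1_foci,focus_positions,
    n_chiasmata,n_labeled_chiasmata,length_um

Focus positions are a ";"-separated list in one column, stored as fractions
of bivalent length to six decimal places.  When ``length_um`` is present the
positions in the file are micrometre coordinates and are divided by the
bivalent length on ingest (and multiplied back on write), so round trips
are stable.  Missing optional fields are empty strings, never sentinel
numbers.

``intensity.csv`` holds one row per measurement::

    genotype,cell_id,stage,raw_intensity,background

Result objects are written as JSON (nested) plus a flat CSV twin carrying
identical numbers.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
import yaml

from .records import (
    BivalentConfig,
    BivalentRecord,
    CellRecord,
    GenomeSpec,
    IntensityRecord,
    Stage,
    ValidationError,
    parse_config,
    parse_stage,
)

BIVALENT_COLUMNS = [
    "genotype",
    "cell_id",
    "pair_index",
    "stage",
    "config",
    "n_class1_foci",
    "focus_positions",
    "n_chiasmata",
    "n_labeled_chiasmata",
    "length_um",
]

INTENSITY_COLUMNS = ["genotype", "cell_id", "stage", "raw_intensity", "background"]


def _opt_int(value: str, row: int, column: str) -> Optional[int]:
    if value == "":
        return None
    try:
        return int(value)
    except ValueError:
        raise ValidationError(
            f"row {row}: column {column!r} must be an integer (got {value!r})"
        ) from None


def _opt_float(value: str, row: int, column: str) -> Optional[float]:
    if value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise ValidationError(
            f"row {row}: column {column!r} must be a number (got {value!r})"
        ) from None


def read_bivalent_table(
    path: Union[str, Path],
    genome: Optional[GenomeSpec] = None,
    *,
    on_incomplete: str = "error",
) -> List[CellRecord]:
    """Read a ``bivalents.csv`` file into validated :class:`CellRecord`s.

    Cells whose bivalents do not cover all ``genome.n_pairs`` pair indices
    are rejected (``on_incomplete="error"``) or padded with unknown-config
    zero-focus records (``on_incomplete="pad"``).  Every type invariant is
    re-validated on ingest; violations raise :class:`ValidationError`
    naming the offending row.
    """
    if on_incomplete not in ("error", "pad"):
        raise ValidationError("on_incomplete must be 'error' or 'pad'")
    genome = genome or GenomeSpec()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != BIVALENT_COLUMNS:
        raise ValidationError(
            f"unexpected header {list(df.columns)}; expected {BIVALENT_COLUMNS}"
        )

    by_cell: Dict[tuple, List[BivalentRecord]] = {}
    order: List[tuple] = []
    for idx, raw in enumerate(df.itertuples(index=False), start=2):  # header = row 1
        try:
            stage = parse_stage(raw.stage)
            config = parse_config(raw.config)
            n_foci = _opt_int(raw.n_class1_foci, idx, "n_class1_foci")
            if n_foci is None:
                raise ValidationError("column 'n_class1_foci' is required")
            length_um = _opt_float(raw.length_um, idx, "length_um")
            pos_field = raw.focus_positions.strip()
            positions: Optional[tuple]
            if pos_field == "":
                positions = () if n_foci == 0 else None
            else:
                vals = [
                    _opt_float(tok, idx, "focus_positions")
                    for tok in pos_field.split(";")
                    if tok != ""
                ]
                if length_um is not None:
                    vals = [v / length_um for v in vals]
                positions = tuple(vals)
            record = BivalentRecord(
                genotype_label=raw.genotype,
                cell_id=raw.cell_id,
                pair_index=_opt_int(raw.pair_index, idx, "pair_index"),
                stage=stage,
                config=config,
                n_class1_foci=n_foci,
                focus_positions=positions,
                n_chiasmata=_opt_int(raw.n_chiasmata, idx, "n_chiasmata"),
                n_labeled_chiasmata=_opt_int(
                    raw.n_labeled_chiasmata, idx, "n_labeled_chiasmata"
                ),
                length_um=length_um,
            )
        except ValidationError as err:
            raise ValidationError(f"row {idx}: {err}") from None
        key = (raw.genotype, raw.cell_id, stage)
        if key not in by_cell:
            by_cell[key] = []
            order.append(key)
        by_cell[key].append(record)

    cells: List[CellRecord] = []
    for key in order:
        genotype, cell_id, stage = key
        bivs = by_cell[key]
        present = {b.pair_index for b in bivs}
        missing = set(range(genome.n_pairs)) - present
        if missing:
            if on_incomplete == "error":
                raise ValidationError(
                    f"cell {cell_id!r} is missing pair indices {sorted(missing)}"
                )
            for j in sorted(missing):
                bivs.append(
                    BivalentRecord(
                        genotype_label=genotype,
                        cell_id=cell_id,
                        pair_index=j,
                        stage=stage,
                        config=BivalentConfig.UNKNOWN,
                        n_class1_foci=0,
                        focus_positions=(),
                    )
                )
        bivs.sort(key=lambda b: b.pair_index)
        cell = CellRecord(
            genotype_label=genotype, cell_id=cell_id, stage=stage, bivalents=bivs
        )
        cell.validate_against(genome)
        cells.append(cell)
    return cells


def _format_positions(record: BivalentRecord) -> str:
    if record.focus_positions is None:
        return ""
    scale = record.length_um if record.length_um is not None else 1.0
    return ";".join(f"{p * scale:.6f}" for p in record.focus_positions)


def write_bivalent_table(
    cells: Sequence[CellRecord], path: Union[str, Path]
) -> None:
    """Write cells to the canonical ``bivalents.csv`` schema."""
    if not cells:
        raise ValidationError("refusing to write an empty bivalent table")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(BIVALENT_COLUMNS)
        for cell in cells:
            for b in cell.bivalents:
                writer.writerow(
                    [
                        b.genotype_label,
                        b.cell_id,
                        b.pair_index,
                        b.stage.value,
                        b.config.value,
                        b.n_class1_foci,
                        _format_positions(b),
                        "" if b.n_chiasmata is None else b.n_chiasmata,
                        ""
                        if b.n_labeled_chiasmata is None
                        else b.n_labeled_chiasmata,
                        "" if b.length_um is None else f"{b.length_um:.6f}",
                    ]
                )


def read_intensity_table(path: Union[str, Path]) -> List[IntensityRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != INTENSITY_COLUMNS:
        raise ValidationError(
            f"unexpected header {list(df.columns)}; expected {INTENSITY_COLUMNS}"
        )
    records = []
    for idx, raw in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                IntensityRecord(
                    genotype_label=raw.genotype,
                    cell_id=raw.cell_id,
                    stage=parse_stage(raw.stage),
                    raw_intensity=float(raw.raw_intensity),
                    background=float(raw.background),
                )
            )
        except (ValidationError, ValueError) as err:
            raise ValidationError(f"row {idx}: {err}") from None
    return records


def write_intensity_table(
    records: Sequence[IntensityRecord], path: Union[str, Path]
) -> None:
    if not records:
        raise ValidationError("refusing to write an empty intensity table")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(INTENSITY_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.genotype_label,
                    r.cell_id,
                    r.stage.value,
                    repr(r.raw_intensity),
                    repr(r.background),
                ]
            )


def _flatten(prefix: str, value, row: Dict[str, object]) -> None:
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        value = dataclasses.asdict(value)
    if isinstance(value, dict):
        for k, v in value.items():
            _flatten(f"{prefix}{k}." if prefix else f"{k}.", v, row)
        return
    key = prefix[:-1] if prefix.endswith(".") else prefix
    if isinstance(value, (list, tuple)):
        row[key] = ";".join(str(v) for v in value)
    else:
        row[key] = value


def write_results(
    results: Union[object, Sequence[object]], path_base: Union[str, Path]
) -> None:
    """Serialize result objects as twin JSON (nested) and CSV (flat) files.

    ``path_base`` is the path without extension; ``path_base.json`` and
    ``path_base.csv`` are produced with identical numbers.  An empty result
    set is an error, never an empty file.
    """
    if results is None:
        raise ValidationError("refusing to write empty results")
    items = list(results) if isinstance(results, (list, tuple)) else [results]
    if not items:
        raise ValidationError("refusing to write empty results")
    payload = []
    for item in items:
        if dataclasses.is_dataclass(item) and not isinstance(item, type):
            payload.append(dataclasses.asdict(item))
        elif isinstance(item, dict):
            payload.append(item)
        else:
            raise ValidationError(
                f"cannot serialize result of type {type(item).__name__}"
            )
    base = Path(path_base)
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(payload if len(payload) > 1 else payload[0], fh, indent=2, default=str)
        fh.write("\n")
    rows = []
    for item in payload:
        row: Dict[str, object] = {}
        _flatten("", item, row)
        rows.append(row)
    pd.DataFrame(rows).to_csv(base.with_suffix(".csv"), index=False)


def read_results_json(path_base: Union[str, Path]):
    with open(Path(path_base).with_suffix(".json")) as fh:
        return json.load(fh)


def read_genome_yaml(path: Union[str, Path]) -> GenomeSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return GenomeSpec(
        n_pairs=int(data.get("n_pairs", 19)),
        lengths=tuple(data.get("lengths", ())),
        centromere_fractions=tuple(data.get("centromere_fractions", ())),
    )


def write_genome_yaml(genome: GenomeSpec, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "n_pairs": genome.n_pairs,
                "lengths": list(genome.lengths),
                "centromere_fractions": list(genome.centromere_fractions),
            },
            fh,
        )
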