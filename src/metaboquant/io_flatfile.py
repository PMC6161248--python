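"""Parsing of instrument flat-text quantification exports and workbook output.

Vendor quantification software for targeted LC-MS/MS emits one text block per
compound, each block repeating the full injection list with that compound's
peak area, internal-standard area, retention time and back-calculated
concentration (ppb).  This module parses that block dialect into structured
per-injection records, pivots them into sample x metabolite matrices, and
writes processed results to an Excel workbook with diff-able CSV mirrors.

Dialect (tab-separated, UTF-8)::

    Compound 1:  Alanine
    #	Name	Sample Text	Type	Std. Conc	RT	Area	IS Area	Conc.
    1	b01_001	CAL1	Standard	0.977	2.31	1021.5	9988.0	0.95
    2	b01_002	S01	Sample		2.30	20571.2	10102.3	19.44
    ...

Empty fields and the literal ``N/F`` (not found) both denote missing values.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import FlatFileError
from .panel import Panel

if TYPE_CHECKING:  # pragma: no cover
    from .quantify import QuantTable

HEADER_FIELDS = [
    "#", "Name", "Sample Text", "Type", "Std. Conc", "RT", "Area", "IS Area", "Conc.",
]

_COMPOUND_RE = re.compile(r"^Compound\s+(\d+):\s*(.+?)\s*$")

_TYPE_MAP = {
    "standard": "standard",
    "qc": "qc",
    "blank": "blank",
    "sample": "sample",
    "analyte": "sample",
}

METADATA_COLUMNS = [
    "sample_id", "sample_type", "phenotype_group", "matrix_type",
    "dilution_factor", "tissue_weight_mg", "cell_count", "qc_lot",
    "calibration_level",
]


@dataclass(frozen=True)
class Measurement:
    """One compound's readouts for one injection (NaN where missing)."""

    peak_area: float = np.nan
    is_area: float = np.nan
    retention_time: float = np.nan
    conc_ppb: float = np.nan


@dataclass
class InjectionRecord:
    sample_id: str
    file_name: str
    injection_index: int
    sample_type: str  # standard | qc | blank | sample
    calibration_level: float | None = None  # nominal conc for standards
    phenotype_group: str | None = None
    measurements: dict[str, Measurement] = field(default_factory=dict)


@dataclass
class SampleMetadata:
    sample_id: str
    sample_type: str
    phenotype_group: str | None = None
    matrix_type: str = "biofluid"
    dilution_factor: float = 1.0
    tissue_weight_mg: float | None = None
    cell_count: float | None = None
    qc_lot: str | None = None
    calibration_level: float | None = None


@dataclass
class BatchData:
    """All injections of one acquisition batch plus per-sample metadata."""

    batch_id: str
    records: list[InjectionRecord]
    metadata: dict[str, SampleMetadata] = field(default_factory=dict)
    run_date: date | None = None
    compounds: list[str] = field(default_factory=list)  # column order

    def records_of_type(self, *types: str) -> list[InjectionRecord]:
        return [r for r in self.records if r.sample_type in types]

    @property
    def sample_types(self) -> pd.Series:
        return pd.Series(
            {r.sample_id: r.sample_type for r in self.records}, name="sample_type"
        )


def _parse_num(tok: str, path: Path, lineno: int, fieldname: str) -> float:
    tok = tok.strip()
    if tok == "" or tok.upper() == "N/F":
        return np.nan
    try:
        return float(tok)
    except ValueError as exc:
        raise FlatFileError(
            f"{path}:{lineno}: unparseable numeric field {fieldname!r}: {tok!r}"
        ) from exc


def parse_flatfile(
    path: str | Path,
    panel: Panel,
    metadata: dict[str, SampleMetadata] | None = None,
    batch_id: str | None = None,
    run_date: date | None = None,
) -> BatchData:
    """Parse a block-dialect flat file into a :class:`BatchData`.

    Every compound block must list the same injections in the same order; a
    divergence raises :class:`FlatFileError` naming the first divergent
    block.  Compounds absent from the panel raise a warning and are kept,
    keyed by their compound name instead of an HMDB id.
    """
    path = Path(path)
    if not path.exists():
        raise FlatFileError(f"flat file not found: {path}")
    text = path.read_text(encoding="utf-8")

    blocks: list[tuple[str, list[tuple[int, list[str]]]]] = []
    current: list[tuple[int, list[str]]] | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        m = _COMPOUND_RE.match(stripped)
        if m:
            current = []
            blocks.append((m.group(2), current))
            continue
        if not stripped:
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0].strip() == "#":
            expected = [f.strip() for f in fields]
            if expected != HEADER_FIELDS:
                raise FlatFileError(
                    f"{path}:{lineno}: unexpected block header {expected}"
                )
            continue
        if current is None:
            raise FlatFileError(f"{path}:{lineno}: data line outside a compound block")
        current.append((lineno, fields))
    if not blocks:
        raise FlatFileError(f"{path}: no compound blocks found")

    # Reconcile injection lists across blocks against the first block.
    def injections(rows: list[tuple[int, list[str]]]) -> list[tuple[str, str]]:
        return [(r[1][0].strip(), r[1][2].strip()) for r in rows]

    ref_name, ref_rows = blocks[0]
    ref_inj = injections(ref_rows)
    for name, rows in blocks[1:]:
        if injections(rows) != ref_inj:
            raise FlatFileError(
                f"{path}: block {name!r} lists a different injection sequence "
                f"than block {ref_name!r}"
            )

    name_to_id = {e.name: e.hmdb_id for e in panel.entries}
    records: list[InjectionRecord] = []
    for lineno, fields in ref_rows:
        if len(fields) < 9:
            raise FlatFileError(f"{path}:{lineno}: expected 9 fields, got {len(fields)}")
        idx = int(_parse_num(fields[0], path, lineno, "#"))
        raw_type = fields[3].strip().lower()
        if raw_type not in _TYPE_MAP:
            raise FlatFileError(f"{path}:{lineno}: unknown sample type {fields[3]!r}")
        std_conc = _parse_num(fields[4], path, lineno, "Std. Conc")
        records.append(
            InjectionRecord(
                sample_id=fields[2].strip(),
                file_name=fields[1].strip(),
                injection_index=idx,
                sample_type=_TYPE_MAP[raw_type],
                calibration_level=None if np.isnan(std_conc) else std_conc,
            )
        )
    if len({r.injection_index for r in records}) != len(records):
        raise FlatFileError(f"{path}: duplicate injection indices within batch")

    compounds: list[str] = []
    for name, rows in blocks:
        key = name_to_id.get(name)
        if key is None:
            warnings.warn(
                f"compound {name!r} not in panel; kept under its compound name",
                stacklevel=2,
            )
            key = name
        compounds.append(key)
        for record, (lineno, fields) in zip(records, rows):
            record.measurements[key] = Measurement(
                peak_area=_parse_num(fields[6], path, lineno, "Area"),
                is_area=_parse_num(fields[7], path, lineno, "IS Area"),
                retention_time=_parse_num(fields[5], path, lineno, "RT"),
                conc_ppb=_parse_num(fields[8], path, lineno, "Conc."),
            )

    # column order follows the panel; unknown compounds trail in file order
    panel_ids = set(compounds)
    compounds = [h for h in panel.hmdb_ids if h in panel_ids] + [
        c for c in compounds if c not in set(panel.hmdb_ids)
    ]

    meta = metadata or {}
    for rec in records:
        sm = meta.get(rec.sample_id)
        if sm is not None:
            rec.phenotype_group = sm.phenotype_group
    return BatchData(
        batch_id=batch_id or path.stem,
        records=records,
        metadata=meta,
        run_date=run_date,
        compounds=compounds,
    )


def load_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    """Read the batch-metadata CSV keyed by sample id."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in ("sample_id", "sample_type") if c not in df.columns]
    if missing:
        raise FlatFileError(f"metadata file {path} missing columns: {missing}")

    def opt(row, col, cast=float):
        if col not in df.columns or pd.isna(row.get(col)) or row.get(col) == "":
            return None
        return cast(row[col])

    out: dict[str, SampleMetadata] = {}
    for _, row in df.iterrows():
        out[str(row["sample_id"])] = SampleMetadata(
            sample_id=str(row["sample_id"]),
            sample_type=str(row["sample_type"]),
            phenotype_group=opt(row, "phenotype_group", str),
            matrix_type=opt(row, "matrix_type", str) or "biofluid",
            dilution_factor=opt(row, "dilution_factor") or 1.0,
            tissue_weight_mg=opt(row, "tissue_weight_mg"),
            cell_count=opt(row, "cell_count"),
            qc_lot=opt(row, "qc_lot", str),
            calibration_level=opt(row, "calibration_level"),
        )
    return out


def write_metadata(metadata: dict[str, SampleMetadata], path: str | Path) -> Path:
    rows = []
    for sm in metadata.values():
        rows.append({
            "sample_id": sm.sample_id,
            "sample_type": sm.sample_type,
            "phenotype_group": sm.phenotype_group,
            "matrix_type": sm.matrix_type,
            "dilution_factor": sm.dilution_factor,
            "tissue_weight_mg": sm.tissue_weight_mg,
            "cell_count": sm.cell_count,
            "qc_lot": sm.qc_lot,
            "calibration_level": sm.calibration_level,
        })
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, index=False)
    return Path(path)


_VALUE_FIELDS = {
    "conc_ppb": "conc_ppb",
    "peak_area": "peak_area",
    "is_area": "is_area",
    "rt": "retention_time",
}


def assemble_matrix(
    batch: BatchData,
    value: str = "conc_ppb",
    sample_types: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Pivot a batch into an injection-ordered sample x metabolite matrix.

    Missing measurements stay NaN, never zero.  ``sample_types`` restricts
    rows (e.g. ``("sample",)`` drops standards, QCs and blanks).
    """
    if value not in _VALUE_FIELDS:
        raise ValueError(
            f"unknown value selector {value!r}; choose from {sorted(_VALUE_FIELDS)}"
        )
    attr = _VALUE_FIELDS[value]
    recs = sorted(batch.records, key=lambda r: r.injection_index)
    if sample_types is not None:
        recs = [r for r in recs if r.sample_type in sample_types]
    data = {
        r.sample_id: {k: getattr(m, attr) for k, m in r.measurements.items()}
        for r in recs
    }
    df = pd.DataFrame.from_dict(data, orient="index")
    # column order follows the panel/compound order, not dict insertion quirks
    cols = [c for c in batch.compounds if c in df.columns]
    df = df.reindex(columns=cols)
    df.index.name = "sample_id"
    return df


def write_workbook(results: "QuantTable", path: str | Path) -> Path:
    """Write a processed-results workbook plus CSV mirrors.

    Sheets: ``concentrations`` (samples rearranged by phenotypic group, the
    randomized acquisition order kept in its own column), ``qc_summary``
    (per-metabolite QC mean and %CV) and ``flags``.  Cells flagged as 1-SD
    outliers are filled yellow, 2-SD outliers red.
    """
    from openpyxl.styles import PatternFill

    path = Path(path)
    if results.values.empty:
        raise ValueError("refusing to write an empty results table")

    conc = results.values.copy()
    conc.insert(0, "phenotype_group", results.groups.reindex(conc.index))
    conc.insert(1, "acquisition_order", np.arange(1, len(conc) + 1))
    conc = conc.sort_values(
        by=["phenotype_group"], kind="stable", na_position="last"
    )

    qc = results.qc_summary if results.qc_summary is not None else pd.DataFrame(
        columns=["hmdb_id", "mean", "cv_pct"]
    ).set_index("hmdb_id")

    flags = results.flags.map(lambda s: ";".join(sorted(s)) if s else "")
    flags = flags.loc[conc.index]

    fill_1sd = PatternFill("solid", fgColor="FFF2CC")  # yellow
    fill_2sd = PatternFill("solid", fgColor="F4CCCC")  # red

    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        conc.to_excel(writer, sheet_name="concentrations")
        qc.to_excel(writer, sheet_name="qc_summary")
        flags.to_excel(writer, sheet_name="flags")
        ws = writer.sheets["concentrations"]
        col_offset = 4  # index col + 2 inserted cols + 1-based
        for i, sid in enumerate(conc.index):
            for j, met in enumerate(results.values.columns):
                cell_flags = results.flags.at[sid, met]
                if "outlier_2sd" in cell_flags:
                    ws.cell(row=i + 2, column=j + col_offset).fill = fill_2sd
                elif "outlier_1sd" in cell_flags:
                    ws.cell(row=i + 2, column=j + col_offset).fill = fill_1sd

    stem = path.with_suffix("")
    conc.to_csv(f"{stem}_concentrations.csv")
    qc.to_csv(f"{stem}_qc_summary.csv")
    flags.to_csv(f"{stem}_flags.csv")
    return path
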