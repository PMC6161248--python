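"""Metabolite panel definition and packaged serum reference database.

A *panel* is the list of metabolites an assay targets: identity (name and
HMDB accession), chemical class, average molecular weight (g/mol, used to
convert ppb = µg/L to µmol/L), the stable-isotope-labelled internal standard
assigned to the metabolite's class group, the process-efficiency factor used
for semiquantification of metabolites without their own labelled analogue,
and a default dilution factor.

The packaged default panel covers 102 polar metabolites from 24 chemical
classes and ships with a healthy-adult serum reference database: the
population median concentration of each metabolite with its 95% credibility
interval, estimated from a long-running pooled-serum QC programme.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import PanelError

PANEL_COLUMNS = [
    "name",
    "hmdb_id",
    "class",
    "molecular_weight",
    "internal_standard",
    "process_efficiency",
    "default_dilution",
]

REFERENCE_COLUMNS = ["hmdb_id", "median_umol_l", "ci_lower", "ci_upper"]


@dataclass(frozen=True)
class PanelEntry:
    """One targeted metabolite."""

    name: str
    hmdb_id: str
    class_name: str
    molecular_weight: float
    internal_standard: str | None = None
    process_efficiency: float = 1.0
    default_dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise PanelError(
                f"{self.hmdb_id} ({self.name}): molecular weight must be "
                f"positive, got {self.molecular_weight}"
            )
        if not 0 < self.process_efficiency <= 2:
            raise PanelError(
                f"{self.hmdb_id} ({self.name}): process efficiency must lie "
                f"in (0, 2], got {self.process_efficiency}"
            )
        if self.default_dilution < 1:
            raise PanelError(
                f"{self.hmdb_id} ({self.name}): dilution factor must be >= 1"
            )


@dataclass(frozen=True)
class ReferenceEntry:
    """Population median concentration with a 95% credibility interval."""

    hmdb_id: str
    median: float
    ci_lower: float
    ci_upper: float

    def __post_init__(self) -> None:
        if not (0 < self.ci_lower <= self.median <= self.ci_upper):
            raise PanelError(
                f"{self.hmdb_id}: require 0 < lower <= median <= upper, got "
                f"[{self.ci_lower}, {self.median}, {self.ci_upper}]"
            )


@dataclass
class Panel:
    """A validated metabolite panel plus optional reference database."""

    entries: list[PanelEntry]
    references: list[ReferenceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.hmdb_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PanelError(f"duplicate HMDB ids in panel: {sorted(dupes)}")
        known = set(ids)
        orphans = [r.hmdb_id for r in self.references if r.hmdb_id not in known]
        if orphans:
            raise PanelError(
                f"reference entries without a panel entry: {sorted(orphans)}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, hmdb_id: str) -> bool:
        return any(e.hmdb_id == hmdb_id for e in self.entries)

    @property
    def hmdb_ids(self) -> list[str]:
        return [e.hmdb_id for e in self.entries]

    @property
    def class_names(self) -> list[str]:
        """Distinct class labels in panel order."""
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.class_name, None)
        return list(seen)

    @property
    def internal_standards(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            if e.internal_standard:
                seen.setdefault(e.internal_standard, None)
        return list(seen)

    def entry(self, hmdb_id: str) -> PanelEntry:
        for e in self.entries:
            if e.hmdb_id == hmdb_id:
                return e
        raise KeyError(f"{hmdb_id} not in panel")

    def by_name(self, name: str) -> PanelEntry | None:
        for e in self.entries:
            if e.name == name:
                return e
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": e.name,
                    "hmdb_id": e.hmdb_id,
                    "class": e.class_name,
                    "molecular_weight": e.molecular_weight,
                    "internal_standard": e.internal_standard or "",
                    "process_efficiency": e.process_efficiency,
                    "default_dilution": e.default_dilution,
                }
                for e in self.entries
            ],
            columns=PANEL_COLUMNS,
        )


def _sniff_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def load_panel(path: str | Path, reference_path: str | Path | None = None) -> Panel:
    """Read a panel file (CSV or TSV, autodetected by extension).

    Raises :class:`PanelError` naming the offending row on missing columns,
    duplicate HMDB ids, or non-positive molecular weights.
    """
    path = Path(path)
    if not path.exists():
        raise PanelError(f"panel file not found: {path}")
    delim = _sniff_delimiter(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in PANEL_COLUMNS if c not in header]
        if missing:
            raise PanelError(f"panel file {path} missing columns: {missing}")
        entries = []
        for lineno, row in enumerate(reader, start=2):
            try:
                entries.append(
                    PanelEntry(
                        name=row["name"].strip(),
                        hmdb_id=row["hmdb_id"].strip(),
                        class_name=row["class"].strip(),
                        molecular_weight=float(row["molecular_weight"]),
                        internal_standard=row["internal_standard"].strip() or None,
                        process_efficiency=float(row["process_efficiency"] or 1.0),
                        default_dilution=float(row["default_dilution"] or 1.0),
                    )
                )
            except (ValueError, PanelError) as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
    references = load_references(reference_path) if reference_path else []
    return Panel(entries=entries, references=references)


def write_panel(panel: Panel, path: str | Path) -> Path:
    """Write a panel back to delimited text; inverse of :func:`load_panel`."""
    path = Path(path)
    panel.to_frame().to_csv(path, sep=_sniff_delimiter(path), index=False)
    return path


def load_references(path: str | Path) -> list[ReferenceEntry]:
    df = pd.read_csv(path)
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"reference file {path} missing columns: {missing}")
    return [
        ReferenceEntry(
            hmdb_id=r.hmdb_id,
            median=float(r.median_umol_l),
            ci_lower=float(r.ci_lower),
            ci_upper=float(r.ci_upper),
        )
        for r in df.itertuples()
    ]


def lookup_reference(panel: Panel, hmdb_id: str) -> ReferenceEntry:
    """Return the packaged population median and 95% credibility bounds."""
    for ref in panel.references:
        if ref.hmdb_id == hmdb_id:
            return ref
    raise KeyError(f"no reference entry for {hmdb_id}")


def default_panel() -> Panel:
    """The packaged 102-metabolite serum panel with Table-style references.

    Molecular weights are average (not monoisotopic) weights curated from
    public HMDB records; internal-standard assignments are placeholder class
    slots (IS01..IS12) that users override in their own panel files.
    """
    data = resources.files("metaboquant") / "data"
    with resources.as_file(data / "panel_default.csv") as panel_path, \
            resources.as_file(data / "reference_serum.csv") as ref_path:
        return load_panel(panel_path, ref_path)


def toy_panel(hmdb_ids: Iterable[str] | None = None, n: int = 3) -> Panel:
    """Small synthetic panel for tests and examples (MW 100 g/mol each)."""
    ids = list(hmdb_ids) if hmdb_ids is not None else [
        f"HMDB{7000000 + i:07d}" for i in range(n)
    ]
    classes = ["Synthetic Class A", "Synthetic Class B", "Synthetic Class C"]
    entries = [
        PanelEntry(
            name=f"synthetic-{i}",
            hmdb_id=h,
            class_name=classes[i % len(classes)],
            molecular_weight=100.0,
            internal_standard=f"IS{i % 2 + 1:02d}",
        )
        for i, h in enumerate(ids)
    ]
    return Panel(entries=entries)
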