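"""Ground-truth-known synthetic data for every pipeline stage.

The generator emulates the statistical structure of a targeted LC-MS/MS
batch without any instrument: heteroscedastic calibration responses
(multiplicative Gaussian noise, truncated at -1, matching the proportional
variance that motivates 1/x weighting), matrix-effect and recovery
distortions applied to group-structured sample truths, lot-shifted
log-normal QC concentrations, slow retention-time drift with jitter, and
carryover into blank injections.  Everything is a pure function of
(config, seed), and batches are emitted in the exact flat-text dialect the
parser consumes, so parse -> quantify -> flag closes end-to-end against
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationSeries, make_serial_dilution
from .io_flatfile import HEADER_FIELDS, SampleMetadata, write_metadata
from .panel import Panel, PanelEntry
from .qc_monitor import QCHistory, build_layout, double_randomize


@dataclass
class SimulationConfig:
    """All knobs of the synthetic batch generator.

    Per-metabolite maps are keyed by HMDB id.  ``noise_cv`` is the
    proportional measurement noise in percent; ``lot_sd_log`` the QC
    lot-effect SD on the natural-log scale.
    """

    seed: int
    groups: dict[str, dict[str, float]]  # group -> hmdb -> true conc (µmol/L)
    n_per_group: int | dict[str, int] = 6
    noise_cv: float = 5.0
    lot_sd_log: float = 0.1
    extraction_efficiency: dict[str, float] = field(default_factory=dict)
    matrix_factor: dict[str, float] = field(default_factory=dict)
    rt_true: dict[str, float] = field(default_factory=dict)
    rt_drift_cv: float = 1.0
    carryover_frac: float = 0.0
    dilution_factor: float = 1.0
    qc_median: dict[str, float] = field(default_factory=dict)
    calibration_top: float = 1000.0
    calibration_n_levels: int = 11
    calibration_factor: float = 2.0
    is_area_mean: float = 10_000.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.noise_cv < 0 or self.rt_drift_cv < 0 or self.lot_sd_log < 0:
            raise ValueError("noise parameters must be non-negative")
        for name, m in (("extraction_efficiency", self.extraction_efficiency),
                        ("matrix_factor", self.matrix_factor)):
            for h, v in m.items():
                if not 0 < v <= 2:
                    raise ValueError(f"{name}[{h}]={v} outside (0, 2]")
        if not 0 <= self.carryover_frac < 1:
            raise ValueError("carryover fraction must be in [0, 1)")


def _mult_noise(rng: np.random.Generator, size, cv_pct: float) -> np.ndarray:
    """1 + eps with eps ~ N(0, cv), redrawn where a factor would go negative."""
    sd = cv_pct / 100.0
    eps = rng.normal(0.0, sd, size=size)
    bad = eps <= -1
    while np.any(bad):
        eps[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = eps <= -1
    return 1.0 + eps


# ---------------------------------------------------------------------------
# calibration series


def simulate_calibration(
    seed: int,
    hmdb_id: str = "HMDB7000000",
    top_conc: float = 1000.0,
    n_levels: int = 11,
    factor: float = 2.0,
    noise_cv: float = 5.0,
    slope: float = 1.0,
    intercept: float = 0.0,
    quad: float = 0.0,
) -> tuple[CalibrationSeries, dict]:
    """Serial-dilution responses with proportional noise, plus truth.

    The true curve is ``response = intercept + slope*c + quad*c**2``; each
    level's response is multiplied by an independent 1 + N(0, noise_cv)
    factor (truncated at -1).
    """
    rng = np.random.default_rng(seed)
    nominal = make_serial_dilution(top_conc, n_levels, factor)
    clean = intercept + slope * nominal + quad * nominal**2
    response = clean * _mult_noise(rng, len(nominal), noise_cv)
    truth = {"intercept": intercept, "slope": slope, "quad": quad,
             "noise_cv": noise_cv}
    return CalibrationSeries(hmdb_id, nominal, response), truth


# ---------------------------------------------------------------------------
# full batch in the flat-file dialect


@dataclass
class SimulatedBatch:
    """A rendered synthetic batch plus its generating truth."""

    flatfile_text: str
    metadata: dict[str, SampleMetadata]
    truth: dict
    panel: Panel
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        flat = out / "batch_flatfile.txt"
        flat.write_text(self.flatfile_text, encoding="utf-8")
        meta = write_metadata(self.metadata, out / "batch_metadata.csv")
        return flat, meta


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return f"{x:.6g}"


def render_flatfile(
    rows_by_compound: dict[str, list[dict]], panel: Panel
) -> str:
    """Render per-compound injection rows into the block dialect."""
    id_to_name = {e.hmdb_id: e.name for e in panel.entries}
    lines: list[str] = []
    for i, (hmdb_id, rows) in enumerate(rows_by_compound.items(), start=1):
        lines.append(f"Compound {i}:  {id_to_name.get(hmdb_id, hmdb_id)}")
        lines.append("\t".join(HEADER_FIELDS))
        for r in rows:
            lines.append("\t".join([
                str(r["index"]), r["file_name"], r["sample_id"], r["type"],
                _fmt(r.get("std_conc")), _fmt(r.get("rt")),
                _fmt(r.get("area")), _fmt(r.get("is_area")),
                _fmt(r.get("conc_ppb")),
            ]))
        lines.append("")
    return "\n".join(lines)


def simulate_batch(config: SimulationConfig, panel: Panel) -> SimulatedBatch:
    """Generate one full acquisition batch: standards, blanks, QCs, samples.

    The vendor-reported ppb for a sample is
    ``true_uM * MW * efficiency * matrix_factor / dilution`` with
    multiplicative noise — exactly what the correction chain must undo
    given the panel's process-efficiency factors.  Blanks carry
    ``carryover_frac`` of the top standard's peak area.
    """
    rng = np.random.default_rng(config.seed)
    mets = panel.hmdb_ids
    mw = {e.hmdb_id: e.molecular_weight for e in panel.entries}
    eff = {h: config.extraction_efficiency.get(h, 1.0) for h in mets}
    mfac = {h: config.matrix_factor.get(h, 1.0) for h in mets}
    rt_true = {h: config.rt_true.get(h, 2.0 + 0.1 * i)
               for i, h in enumerate(mets)}
    resp_per_ppb = {h: 10 ** rng.uniform(-1, 1) for h in mets}  # response factor

    def n_of(g: str) -> int:
        n = config.n_per_group
        return n[g] if isinstance(n, dict) else n

    group_of: dict[str, str] = {}
    truths: dict[str, dict[str, float]] = {}
    sample_ids: list[str] = []
    for gname, gconc in config.groups.items():
        for _ in range(n_of(gname)):
            sid = f"S{len(sample_ids) + 1:03d}"
            sample_ids.append(sid)
            group_of[sid] = gname
            truths[sid] = gconc

    _, injection_order = double_randomize(sample_ids, group_of, seed=config.seed)
    layout = build_layout(injection_order, n_standards=config.calibration_n_levels)

    nominal_ppb = make_serial_dilution(
        config.calibration_top, config.calibration_n_levels,
        config.calibration_factor,
    )
    qc_median = {h: config.qc_median.get(h, 10.0) for h in mets}
    qc_lot_shift = {
        h: float(np.exp(rng.normal(0.0, config.lot_sd_log))) for h in mets
    }

    n_inj = len(layout.plan)
    drift = rng.uniform(-1.0, 1.0)  # slow linear RT trend, bounded by rt_drift_cv
    rows_by_compound: dict[str, list[dict]] = {h: [] for h in mets}
    for pos, role, sid in layout.plan:
        frac = pos / n_inj
        for h in mets:
            rt = rt_true[h] * (
                1.0
                + 0.5 * (config.rt_drift_cv / 100.0) * drift * (2 * frac - 1)
            ) * _mult_noise(rng, None, config.rt_drift_cv / 2.0)
            row = {"index": pos, "file_name": f"inj{pos:03d}",
                   "sample_id": sid, "rt": float(rt),
                   "is_area": float(config.is_area_mean
                                    * _mult_noise(rng, None, config.noise_cv / 2))}
            if role == "standard":
                level = int(sid[3:])  # CAL<i>
                ppb = float(nominal_ppb[level - 1]
                            * _mult_noise(rng, None, config.noise_cv))
                row.update(type="Standard", std_conc=float(nominal_ppb[level - 1]),
                           conc_ppb=ppb,
                           area=ppb * resp_per_ppb[h] * row["is_area"] / 1e4)
            elif role == "blank":
                top_area = (float(nominal_ppb[-1]) * resp_per_ppb[h]
                            * config.is_area_mean / 1e4)
                row.update(type="Blank",
                           area=config.carryover_frac * top_area,
                           conc_ppb=config.carryover_frac * float(nominal_ppb[-1]))
            elif role == "qc":
                um = (qc_median[h] * qc_lot_shift[h]
                      * _mult_noise(rng, None, config.noise_cv))
                ppb = float(um * mw[h])
                row.update(type="QC", conc_ppb=ppb,
                           area=ppb * resp_per_ppb[h] * row["is_area"] / 1e4)
            else:
                um_true = truths[sid].get(h, 0.0)
                ppb = float(
                    um_true * mw[h] * eff[h] * mfac[h] / config.dilution_factor
                    * _mult_noise(rng, None, config.noise_cv)
                )
                row.update(type="Sample", conc_ppb=ppb,
                           area=ppb * resp_per_ppb[h] * row["is_area"] / 1e4)
            rows_by_compound[h].append(row)

    metadata: dict[str, SampleMetadata] = {}
    for sid in sample_ids:
        metadata[sid] = SampleMetadata(
            sample_id=sid, sample_type="sample",
            phenotype_group=group_of[sid], matrix_type="biofluid",
            dilution_factor=config.dilution_factor,
        )
    for pos, role, sid in layout.plan:
        if role == "qc":
            metadata[sid] = SampleMetadata(
                sample_id=sid, sample_type="qc", qc_lot="LOT1",
            )

    truth = {
        "group_conc": {g: dict(c) for g, c in config.groups.items()},
        "sample_group": group_of,
        "extraction_efficiency": eff,
        "matrix_factor": mfac,
        "qc_median": qc_median,
        "qc_lot_shift": qc_lot_shift,
        "rt_true": rt_true,
        "nominal_ppb": nominal_ppb.tolist(),
        "noise_cv": config.noise_cv,
    }
    return SimulatedBatch(
        flatfile_text=render_flatfile(rows_by_compound, panel),
        metadata=metadata, truth=truth, panel=panel, config=config,
    )


# ---------------------------------------------------------------------------
# QC histories


def simulate_qc_history(
    seed: int,
    hmdb_ids: list[str],
    true_median: dict[str, float] | float = 100.0,
    lot_sd_log: float = 0.1,
    noise_sd_log: float = 0.2,
    n_lots: int = 6,
    batches_per_lot: int = 9,
    reps_per_batch: int = 10,
) -> tuple[QCHistory, dict]:
    """Lot-structured log-normal QC history plus generating truth.

    Defaults give 6 lots x 9 batches x 10 replicates = 540 records per
    metabolite — the scale of a multi-year pooled-serum QC programme.
    """
    if n_lots < 1:
        raise ValueError("need at least one lot")
    rng = np.random.default_rng(seed)
    med = ({h: float(true_median) for h in hmdb_ids}
           if np.isscalar(true_median) else dict(true_median))
    rows = []
    lot_effects: dict[str, dict[str, float]] = {h: {} for h in hmdb_ids}
    for h in hmdb_ids:
        for j in range(n_lots):
            lot = f"LOT{j + 1}"
            b = float(rng.normal(0.0, lot_sd_log))
            lot_effects[h][lot] = b
            for k in range(batches_per_lot):
                batch = f"B{j * batches_per_lot + k + 1:03d}"
                run_date = f"2020-{(j * batches_per_lot + k) % 12 + 1:02d}-15"
                eps = rng.normal(0.0, noise_sd_log, size=reps_per_batch)
                for conc in np.exp(np.log(med[h]) + b + eps):
                    rows.append({
                        "qc_lot": lot, "batch_id": batch, "run_date": run_date,
                        "hmdb_id": h, "conc_umol_l": float(conc),
                    })
    history = QCHistory(pd.DataFrame(rows))
    truth = {"median": med, "lot_sd_log": lot_sd_log,
             "noise_sd_log": noise_sd_log, "lot_effects": lot_effects}
    return history, truth


# ---------------------------------------------------------------------------
# presets


def make_panel(n: int = 10, pe: dict[str, float] | None = None) -> Panel:
    """Synthetic n-metabolite panel across 3 classes with set PE factors."""
    pe = pe or {}
    classes = ["Synthetic Class A", "Synthetic Class B", "Synthetic Class C"]
    entries = []
    for i in range(n):
        h = f"HMDB{7000000 + i:07d}"
        entries.append(PanelEntry(
            name=f"synthetic-{i}", hmdb_id=h, class_name=classes[i % 3],
            molecular_weight=100.0 + 10.0 * i,
            internal_standard=f"IS{i % 2 + 1:02d}",
            process_efficiency=pe.get(h, 1.0),
        ))
    return Panel(entries=entries)


def small_preset(seed: int, noise_cv: float = 5.0) -> tuple[SimulationConfig, Panel]:
    """10 metabolites, 3 classes, 2 phenotype groups x 6 samples.

    Extraction efficiencies and matrix factors vary per metabolite and the
    panel's process-efficiency column is set to their product, so the
    correction chain can fully undo the distortion.
    """
    rng = np.random.default_rng(seed)
    ids = [f"HMDB{7000000 + i:07d}" for i in range(10)]
    eff = {h: float(rng.uniform(0.5, 1.0)) for h in ids}
    mfac = {h: float(rng.uniform(0.7, 1.4)) for h in ids}
    panel = make_panel(10, pe={h: eff[h] * mfac[h] for h in ids})
    groups = {
        "control": {h: float(rng.uniform(5, 50)) for h in ids},
        "case": {h: float(rng.uniform(5, 50)) for h in ids},
    }
    config = SimulationConfig(
        seed=seed, groups=groups, n_per_group=6, noise_cv=noise_cv,
        extraction_efficiency=eff, matrix_factor=mfac,
        qc_median={h: float(rng.uniform(5, 50)) for h in ids},
        carryover_frac=0.05,
    )
    return config, panel


def full_scale_preset(seed: int, noise_cv: float = 5.0) -> tuple[SimulationConfig, Panel]:
    """100 metabolites, 85 experimental samples — one realistic full batch."""
    from .panel import default_panel

    base = default_panel()
    entries = base.entries[:100]
    panel = Panel(entries=list(entries))
    ids = panel.hmdb_ids
    rng = np.random.default_rng(seed)
    groups = {
        "group1": {h: float(rng.uniform(1, 100)) for h in ids},
        "group2": {h: float(rng.uniform(1, 100)) for h in ids},
    }
    config = SimulationConfig(
        seed=seed, groups=groups,
        n_per_group={"group1": 43, "group2": 42},  # 85 experimental samples
        noise_cv=noise_cv,
        qc_median={h: float(rng.uniform(1, 100)) for h in ids},
        carryover_frac=0.02,
    )
    return config, panel
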