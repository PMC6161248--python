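"""Correction and normalization chain from raw ppb values to final
per-matrix concentrations.

The chain applies, in a fixed order (all steps are multiplicative, so the
order is mathematically irrelevant but fixed for reproducible provenance):

1. intake — vendor ppb values, or back-calculation of peak-area response
   ratios through a fitted calibration curve;
2. molecular-weight normalization: ppb (µg/L) / MW (g/mol) = µmol/L;
3. process-efficiency correction (divide by PE) for metabolites without
   their own labelled internal standard;
4. dilution-factor correction (multiply);
5. matrix-specific normalization — per gram of tissue or per million cells,
   using the extraction volume; biofluids stay in µmol/L.

Every multiplicative factor is recorded per cell so the raw value is exactly
recoverable.  Values outside the calibrated [LLOQ, ULOQ] window are flagged
but retained, never imputed or zeroed.  Phenotype-group statistics mark
values more than 1 (and additionally 2) sample standard deviations from the
group mean as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CurveFit
from .errors import QuantificationError
from .io_flatfile import BatchData
from .panel import Panel

#: litres of extract a biological sample is reconstituted in (protocol default)
DEFAULT_EXTRACT_VOLUME_L = 1e-4

_TISSUE_WEIGHT_BOUNDS_G = (1e-3, 50.0)


# ---------------------------------------------------------------------------
# elementary corrections


def mw_normalize(conc_ppb: float, molecular_weight: float) -> float:
    """ppb (µg/L) to µmol/L: divide by molecular weight (g/mol)."""
    if molecular_weight <= 0:
        raise QuantificationError("molecular weight must be positive")
    if conc_ppb < 0:
        raise QuantificationError("concentration cannot be negative")
    return conc_ppb / molecular_weight


def apply_process_efficiency(conc: float, pe: float) -> float:
    """Divide by the process-efficiency fraction (recovery x matrix effect)."""
    if pe <= 0:
        raise QuantificationError("process efficiency must be positive")
    return conc / pe


def apply_dilution(conc: float, dilution_factor: float) -> float:
    if dilution_factor < 1:
        raise QuantificationError("dilution factor must be >= 1")
    return conc * dilution_factor


def normalize_per_cells(conc: float, extract_volume: float, cell_count: float) -> float:
    """µmol/L of extract to µmol per million cells."""
    if extract_volume <= 0:
        raise QuantificationError("extract volume must be positive")
    if cell_count <= 0:
        raise QuantificationError("cell count must be positive")
    return conc * extract_volume * 1e6 / cell_count


def normalize_per_tissue(conc: float, extract_volume: float, tissue_weight: float) -> float:
    """µmol/L of extract to µmol per gram of tissue (weight in grams)."""
    if extract_volume <= 0:
        raise QuantificationError("extract volume must be positive")
    lo, hi = _TISSUE_WEIGHT_BOUNDS_G
    if not lo <= tissue_weight <= hi:
        raise QuantificationError(
            f"tissue weight {tissue_weight} g outside plausible range "
            f"[{lo}, {hi}] g — check the unit (grams expected)"
        )
    return conc * extract_volume / tissue_weight


# ---------------------------------------------------------------------------
# batch quantification


@dataclass
class QuantTable:
    """Sample x metabolite concentrations with flags and full provenance.

    ``values`` holds the final concentrations (µmol/L for biofluids,
    µmol/g for tissues, µmol per 10^6 cells for cell samples; the unit per
    sample is in ``units``).  ``raw`` holds the intake values (ppb) and
    ``factors`` one DataFrame per multiplicative correction, such that
    ``values = raw * prod(factors)`` holds cell-exactly.
    """

    values: pd.DataFrame
    raw: pd.DataFrame
    flags: pd.DataFrame  # cells are frozensets of flag strings
    factors: dict[str, pd.DataFrame]
    units: pd.Series
    groups: pd.Series
    qc_values: pd.DataFrame | None = None
    qc_summary: pd.DataFrame | None = None
    group_summary: pd.DataFrame | None = None
    errors: list[str] = field(default_factory=list)

    def provenance_product(self) -> pd.DataFrame:
        prod = None
        for f in self.factors.values():
            prod = f if prod is None else prod * f
        return prod

    def reconstruct(self) -> pd.DataFrame:
        """Recompute final values from raw x recorded factors, in the
        recorded application order (bit-exact by construction)."""
        out = self.raw.copy()
        for f in self.factors.values():
            out = out * f
        return out

    def add_flag(self, sample_id: str, hmdb_id: str, flag: str) -> None:
        self.flags.at[sample_id, hmdb_id] = frozenset(
            self.flags.at[sample_id, hmdb_id] | {flag}
        )


def _empty_flags(index, columns) -> pd.DataFrame:
    df = pd.DataFrame(index=index, columns=columns, dtype=object)
    for c in columns:
        df[c] = [frozenset() for _ in range(len(index))]
    return df


def quantify_batch(
    batch: BatchData,
    panel: Panel,
    fits: dict[str, CurveFit] | None = None,
    from_areas: bool = False,
    extract_volume_l: float = DEFAULT_EXTRACT_VOLUME_L,
) -> QuantTable:
    """Run the full correction chain over a parsed batch.

    With ``from_areas=True`` intake is the analyte/IS peak-area ratio
    back-calculated through the metabolite's :class:`CurveFit` (a metabolite
    with no fit is skipped with a warning entry); otherwise the vendor ppb
    column is taken as-is.  Samples without metadata produce per-sample
    error entries instead of silently defaulting.
    """
    import warnings as _warnings

    fits = fits or {}
    mets = [h for h in panel.hmdb_ids if h in set(batch.compounds)]
    if from_areas:
        skipped = [h for h in mets if h not in fits]
        for h in skipped:
            _warnings.warn(f"no calibration fit for {h}; metabolite skipped")
        mets = [h for h in mets if h in fits]

    quant_recs = [r for r in batch.records if r.sample_type in ("sample", "qc")]
    errors: list[str] = []
    usable = []
    for rec in quant_recs:
        if rec.sample_type == "sample" and rec.sample_id not in batch.metadata:
            errors.append(f"{rec.sample_id}: no metadata; sample not quantified")
        else:
            usable.append(rec)

    index = [r.sample_id for r in usable if r.sample_type == "sample"]
    qc_index = [r.sample_id for r in usable if r.sample_type == "qc"]
    values = pd.DataFrame(np.nan, index=index, columns=mets)
    raw = pd.DataFrame(np.nan, index=index, columns=mets)
    flags = _empty_flags(index, mets)
    factors = {
        name: pd.DataFrame(np.nan, index=index, columns=mets)
        for name in ("mw", "pe", "dilution", "matrix")
    }
    units = pd.Series("", index=index, dtype=object)
    groups = pd.Series(index=index, dtype=object)
    qc_values = pd.DataFrame(np.nan, index=qc_index, columns=mets)

    table = QuantTable(
        values=values, raw=raw, flags=flags, factors=factors,
        units=units, groups=groups, qc_values=qc_values, errors=errors,
    )

    for rec in usable:
        meta = batch.metadata.get(rec.sample_id)
        is_qc = rec.sample_type == "qc"
        for h in mets:
            m = rec.measurements.get(h)
            if m is None:
                continue
            entry = panel.entry(h)
            fit = fits.get(h)
            if from_areas:
                denom = m.is_area if entry.internal_standard else 1.0
                ratio = m.peak_area / denom if denom else np.nan
                intake = fit.back_calculate(ratio) if fit is not None else np.nan
            else:
                intake = m.conc_ppb

            if is_qc:
                if not np.isnan(intake):
                    conc = mw_normalize(intake, entry.molecular_weight)
                    conc = apply_process_efficiency(conc, entry.process_efficiency)
                    qc_values.at[rec.sample_id, h] = conc
                continue

            sid = rec.sample_id
            if np.isnan(intake):
                table.add_flag(sid, h, "missing")
                continue

            dilution = meta.dilution_factor if meta else entry.default_dilution
            # derive each multiplicative factor through the elementary
            # operation applied to 1.0 — runs its domain validation and
            # makes the provenance product reproduce the value bit-exactly
            f_mw = mw_normalize(1.0, entry.molecular_weight)
            f_pe = apply_process_efficiency(1.0, entry.process_efficiency)
            f_dil = apply_dilution(1.0, dilution)
            matrix = meta.matrix_type if meta else "biofluid"
            if matrix == "tissue":
                if meta is None or meta.tissue_weight_mg is None:
                    errors.append(f"{sid}/{h}: tissue sample without weight")
                    continue
                matrix_factor = normalize_per_tissue(
                    1.0, extract_volume_l, meta.tissue_weight_mg / 1000.0
                )
                unit = "umol/g"
            elif matrix == "cells":
                if meta is None or meta.cell_count is None:
                    errors.append(f"{sid}/{h}: cell sample without cell count")
                    continue
                matrix_factor = normalize_per_cells(
                    1.0, extract_volume_l, meta.cell_count
                )
                unit = "umol/1e6cells"
            else:
                matrix_factor = 1.0
                unit = "umol/L"
            conc = intake * f_mw * f_pe * f_dil * matrix_factor

            values.at[sid, h] = conc
            raw.at[sid, h] = intake
            factors["mw"].at[sid, h] = f_mw
            factors["pe"].at[sid, h] = f_pe
            factors["dilution"].at[sid, h] = f_dil
            factors["matrix"].at[sid, h] = matrix_factor
            units.at[sid] = unit
            groups.at[sid] = meta.phenotype_group if meta else None

            if fit is not None and not fit.rejected:
                if intake < fit.lloq:
                    table.add_flag(sid, h, "below_lloq")
                elif intake > fit.uloq:
                    table.add_flag(sid, h, "above_uloq")

    if len(qc_index) >= 2:
        mean = qc_values.mean()
        sd = qc_values.std(ddof=1)
        table.qc_summary = pd.DataFrame(
            {"mean": mean, "cv_pct": 100.0 * sd / mean}
        ).rename_axis("hmdb_id")
    elif len(qc_index) == 1:
        table.qc_summary = pd.DataFrame(
            {"mean": qc_values.iloc[0], "cv_pct": np.nan}
        ).rename_axis("hmdb_id")
    return table


def group_stats(
    table: QuantTable,
    groups: dict[str, str] | pd.Series | None = None,
    sd_thresholds: tuple[float, float] = (1.0, 2.0),
) -> pd.DataFrame:
    """Per-phenotype-group mean/SD/RSD and outlier flagging.

    A value more than ``sd_thresholds[0]`` sample standard deviations from
    its group mean is flagged ``outlier_1sd``; beyond ``sd_thresholds[1]``
    it additionally gets ``outlier_2sd``.  The candidate point stays in the
    mean/SD computation (marking, not trimming).  Groups of size 1 get no
    statistics and no flags.
    """
    if groups is not None:
        table.groups = pd.Series(dict(groups)).reindex(table.values.index)
    g = table.groups
    rows = []
    for group, idx in table.values.groupby(g, dropna=True).groups.items():
        sub = table.values.loc[idx]
        for h in table.values.columns:
            vals = sub[h].dropna()
            if len(vals) < 2:
                rows.append({"group": group, "hmdb_id": h, "n": len(vals),
                             "mean": np.nan, "sd": np.nan, "rsd_pct": np.nan})
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            rsd = 100.0 * sd / mean if mean != 0 else np.nan
            rows.append({"group": group, "hmdb_id": h, "n": len(vals),
                         "mean": mean, "sd": sd, "rsd_pct": rsd})
            if sd == 0:
                continue
            dev = (vals - mean).abs() / sd
            for sid in vals.index[dev > sd_thresholds[0]]:
                table.add_flag(sid, h, "outlier_1sd")
            for sid in vals.index[dev > sd_thresholds[1]]:
                table.add_flag(sid, h, "outlier_2sd")
    summary = pd.DataFrame(
        rows, columns=["group", "hmdb_id", "n", "mean", "sd", "rsd_pct"]
    )
    table.group_summary = summary
    return summary
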