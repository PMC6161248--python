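"""Bioanalytical method-validation statistics.

Implements the standard validation metrics for a targeted assay: accuracy
(measured/nominal), intra- and inter-batch precision (%CV), extraction
recovery and matrix effect from spike-before/spike-after designs with
endogenous-background subtraction, process efficiency, stability ratios,
and a panel-level validation report with configurable acceptance bands.

Spike design arms
-----------------
``spiked_before_extraction``
    matrix samples spiked with the standard mixture, then extracted —
    carries extraction losses and matrix ionization effects;
``spiked_after_extraction``
    matrix extracted first, spiked afterwards — matrix effects only;
``aqueous_spiked``
    pure diluent spiked at the same level — neither;
``unspiked_endogenous``
    un-spiked matrix, measuring the endogenous background that must be
    subtracted from the spiked matrix arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationDesignError
from .panel import Panel

#: default acceptance bands, all overridable per report
RECOVERY_GOOD_PCT = (50.0, 120.0)
RECOVERY_UNRELIABLE_PCT = 30.0
STABILITY_BAND_PCT = (85.0, 115.0)
CV_TIERS_PCT = (15.0, 20.0, 25.0)


def accuracy_pct(measured: float, nominal: float) -> float:
    """Measured over nominal, as a percentage."""
    if nominal <= 0:
        raise ValidationDesignError("nominal concentration must be positive")
    return 100.0 * measured / nominal


def _cv(values: Sequence[float]) -> float:
    if len(values) < 2:
        raise ValidationDesignError("need >= 2 replicates for a CV")
    m = mean(values)
    if m == 0:
        return float("nan")
    return 100.0 * stdev(values) / m


def precision_cv(
    replicates: Sequence[float] | Mapping[str, Sequence[float]],
    grouping: str = "intra",
):
    """Coefficient of variation, 100 x sample SD / mean.

    ``grouping="intra"`` takes a flat replicate list and returns its %CV.
    ``grouping="inter"`` takes a mapping batch -> replicates and returns
    ``(pooled_cv, {batch: cv})`` where the pooled CV is computed over all
    values across batches.
    """
    if grouping == "intra":
        if isinstance(replicates, Mapping):
            raise ValidationDesignError("intra grouping expects a flat list")
        return _cv(list(replicates))
    if grouping != "inter":
        raise ValidationDesignError(f"unknown grouping {grouping!r}")
    if not isinstance(replicates, Mapping):
        raise ValidationDesignError("inter grouping expects a batch mapping")
    per_batch = {b: _cv(list(v)) for b, v in replicates.items()}
    pooled = _cv([x for v in replicates.values() for x in v])
    return pooled, per_batch


@dataclass
class SpikeDesign:
    """One spike-recovery/matrix-effect experiment at one level."""

    hmdb_id: str
    level: str  # low | medium | high
    nominal_spike: float
    spiked_before_extraction: list[float] = field(default_factory=list)
    spiked_after_extraction: list[float] = field(default_factory=list)
    aqueous_spiked: list[float] = field(default_factory=list)
    unspiked_endogenous: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.nominal_spike <= 0:
            raise ValidationDesignError("nominal spike must be positive")

    def _mean(self, arm: str) -> float:
        vals = getattr(self, arm)
        if not vals:
            raise ValidationDesignError(f"{self.hmdb_id}/{self.level}: empty arm {arm}")
        return mean(vals)


@dataclass
class StabilityDesign:
    """Stored-versus-fresh comparison under one storage condition."""

    hmdb_id: str
    condition: str  # wet_extract | freeze_thaw | stock_solution | intermediate_solution
    level: str
    stored: list[float] = field(default_factory=list)
    fresh: list[float] = field(default_factory=list)
    cycles_or_duration: str | None = None


@dataclass
class RecoveryResult:
    recovery_pct: float
    replicate_cv_pct: float
    defined: bool = True


def recovery_pct(design: SpikeDesign) -> RecoveryResult:
    """Extraction recovery with endogenous-background subtraction.

    recovery = 100 x (mean(before) - mean(endog)) / (mean(after) - mean(endog)).
    The endogenous mean is subtracted from both spiked-matrix arms, since
    both contain the matrix background.  An after-arm mean at or below the
    endogenous mean leaves recovery undefined (flagged, NaN).
    """
    endog = design._mean("unspiked_endogenous") if design.unspiked_endogenous else 0.0
    before = design._mean("spiked_before_extraction")
    after = design._mean("spiked_after_extraction")
    if after - endog <= 0:
        return RecoveryResult(float("nan"), float("nan"), defined=False)
    rec = 100.0 * (before - endog) / (after - endog)
    cv = (
        _cv(design.spiked_before_extraction)
        if len(design.spiked_before_extraction) >= 2
        else float("nan")
    )
    return RecoveryResult(rec, cv)


@dataclass
class MatrixEffectResult:
    ratio: float
    interpretation: str  # suppression | enhancement | neutral


def matrix_effect(design: SpikeDesign) -> MatrixEffectResult:
    """Matrix-effect ratio: spiked-after-extraction response (endogenous
    subtracted) over the aqueous-spike response.

    Below 1 indicates ion suppression, above 1 ion enhancement.  Only the
    matrix arm is background-subtracted — the aqueous arm contains no
    endogenous analyte by construction.
    """
    aqueous = design._mean("aqueous_spiked")
    if aqueous <= 0:
        raise ValidationDesignError("aqueous arm mean must be positive")
    endog = design._mean("unspiked_endogenous") if design.unspiked_endogenous else 0.0
    after = design._mean("spiked_after_extraction")
    me = (after - endog) / aqueous
    if me < 1:
        interp = "suppression"
    elif me > 1:
        interp = "enhancement"
    else:
        interp = "neutral"
    return MatrixEffectResult(me, interp)


def process_efficiency(recovery: float, me: float) -> float:
    """Total attenuation: recovery fraction x matrix-effect ratio.

    Feeds the panel file's process-efficiency column for metabolites that
    lack their own internal standard.
    """
    if recovery <= 0 or me <= 0:
        raise ValidationDesignError("recovery and matrix effect must be positive")
    return recovery * me


@dataclass
class StabilityResult:
    stability_pct: float
    passed: bool
    band: tuple[float, float] = STABILITY_BAND_PCT


def stability_pct(
    design: StabilityDesign, band: tuple[float, float] = STABILITY_BAND_PCT
) -> StabilityResult:
    """Stored over fresh mean, as a percentage; pass iff inside ``band``."""
    if not design.fresh or not design.stored:
        raise ValidationDesignError(
            f"{design.hmdb_id}/{design.condition}: both arms must be populated"
        )
    fresh = mean(design.fresh)
    if fresh <= 0:
        return StabilityResult(float("nan"), False, band)
    pct = 100.0 * mean(design.stored) / fresh
    return StabilityResult(pct, band[0] <= pct <= band[1], band)


def validation_report(
    panel: Panel,
    spike_designs: Iterable[SpikeDesign] = (),
    stability_designs: Iterable[StabilityDesign] = (),
    recovery_good: tuple[float, float] = RECOVERY_GOOD_PCT,
    recovery_unreliable: float = RECOVERY_UNRELIABLE_PCT,
    stability_band: tuple[float, float] = STABILITY_BAND_PCT,
) -> dict:
    """Assemble per-metabolite validation tables with pass/fail summaries.

    Returns a dict with ``recovery``, ``matrix_effect`` and ``stability``
    DataFrames (sections with no designs are omitted, with a notice), plus a
    ``summary`` of counts: metabolites with recovery inside the good band,
    below the unreliable threshold, etc.
    """
    report: dict = {"notices": []}
    spike_designs = list(spike_designs)
    stability_designs = list(stability_designs)

    if spike_designs:
        rec_rows, me_rows = [], []
        for d in spike_designs:
            rr = recovery_pct(d)
            rec_rows.append({
                "hmdb_id": d.hmdb_id, "level": d.level,
                "recovery_pct": rr.recovery_pct, "cv_pct": rr.replicate_cv_pct,
                "defined": rr.defined,
                "good": rr.defined and recovery_good[0] <= rr.recovery_pct <= recovery_good[1],
                "unreliable": rr.defined and rr.recovery_pct < recovery_unreliable,
            })
            mr = matrix_effect(d)
            me_rows.append({
                "hmdb_id": d.hmdb_id, "level": d.level,
                "matrix_effect": mr.ratio, "interpretation": mr.interpretation,
            })
        report["recovery"] = pd.DataFrame(rec_rows)
        report["matrix_effect"] = pd.DataFrame(me_rows)
        per_met = report["recovery"].groupby("hmdb_id")
        n_total = per_met.ngroups
        good = per_met["good"].all()
        unreliable = per_met["unreliable"].any()
        report["summary"] = {
            "n_metabolites": n_total,
            "n_recovery_good": int(good.sum()),
            "fraction_recovery_good": float(good.mean()) if n_total else np.nan,
            "n_recovery_unreliable": int(unreliable.sum()),
            "unreliable_metabolites": sorted(unreliable[unreliable].index),
        }
    else:
        report["notices"].append("no spike designs provided; recovery and "
                                 "matrix-effect sections omitted")

    if stability_designs:
        rows = []
        for d in stability_designs:
            sr = stability_pct(d, stability_band)
            rows.append({
                "hmdb_id": d.hmdb_id, "condition": d.condition, "level": d.level,
                "stability_pct": sr.stability_pct, "passed": sr.passed,
            })
        report["stability"] = pd.DataFrame(rows)
    else:
        report["notices"].append("no stability designs provided; stability "
                                 "section omitted")
    return report


def load_spike_designs(path) -> list[SpikeDesign]:
    """Read spike designs from CSV: hmdb_id,level,arm,replicate,response,nominal_spike."""
    df = pd.read_csv(path)
    designs: dict[tuple[str, str], SpikeDesign] = {}
    for _, row in df.iterrows():
        key = (row["hmdb_id"], row["level"])
        if key not in designs:
            designs[key] = SpikeDesign(
                hmdb_id=row["hmdb_id"], level=row["level"],
                nominal_spike=float(row.get("nominal_spike", 1.0)),
            )
        getattr(designs[key], row["arm"]).append(float(row["response"]))
    return list(designs.values())
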