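"""Batch design and QC drift surveillance.

A long-running assay interleaves pooled-serum QC replicates and solvent
blanks into every acquisition batch: a QC injection after every tenth
experimental sample and a blank at every fifth post-standard run position
(when the two rules collide on a position the blank wins and the QC shifts
to the next free slot).  Samples are double-randomized — once before
extraction and once before injection — to decorrelate phenotype from both
bench order and acquisition order.

QC concentrations accumulate in an append-only history keyed by QC lot,
batch and run date; per-batch QC relative standard deviations are compared
against the historical inter-day RSD to flag drifting batches, and
reproducibility across batches is summarised as the fraction of metabolites
whose QC concentration CV stays under 25%, plus retention-time and
calibration-R² CVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HISTORY_COLUMNS = ["qc_lot", "batch_id", "run_date", "hmdb_id", "conc_umol_l"]

#: relative excess of batch RSD over historical inter-day RSD tolerated
#: before a batch is flagged (percent)
DEFAULT_RSD_TOLERANCE_PCT = 20.0


@dataclass
class QCHistory:
    """Lot/batch/date-stamped QC concentration records."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=HISTORY_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in HISTORY_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"QC history missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_csv(cls, path: str | Path) -> "QCHistory":
        return cls(pd.read_csv(path, dtype={"qc_lot": str, "batch_id": str}))

    def to_csv(self, path: str | Path) -> Path:
        self.frame.to_csv(path, index=False)
        return Path(path)

    def append(self, records: pd.DataFrame) -> "QCHistory":
        """Return a new history with ``records`` appended (append-only)."""
        return QCHistory(
            pd.concat([self.frame, records[HISTORY_COLUMNS]], ignore_index=True)
        )

    @property
    def lots(self) -> list[str]:
        return sorted(self.frame["qc_lot"].unique())

    def interday_rsd(self) -> pd.Series:
        """Per-metabolite RSD (%) of per-batch mean concentrations."""
        by_batch = (
            self.frame.groupby(["hmdb_id", "batch_id"])["conc_umol_l"].mean()
        )
        out = by_batch.groupby("hmdb_id").agg(
            lambda v: 100.0 * v.std(ddof=1) / v.mean() if len(v) > 1 else np.nan
        )
        out.name = "interday_rsd_pct"
        return out


# ---------------------------------------------------------------------------
# batch design


def double_randomize(
    sample_ids: list[str],
    groups: dict[str, str] | None = None,
    seed: int = 0,
    max_attempts: int = 1000,
) -> tuple[list[str], list[str]]:
    """Two independent seeded permutations: extraction order and injection order.

    When phenotype groups are given, each permutation is redrawn until no
    group occupies a contiguous block longer than
    ``ceil(2 * n_group / n_groups)`` — a guard against accidental blocking
    that would confound phenotype with run order.
    """
    if not sample_ids:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)

    def longest_run_ok(order: list[str]) -> bool:
        if not groups or len(set(groups.values())) < 2:
            return True
        counts: dict[str, int] = {}
        for g in groups.values():
            counts[g] = counts.get(g, 0) + 1
        n_groups = len(counts)
        best: dict[str, int] = {}
        prev, run_len = None, 0
        for sid in order:
            g = groups.get(sid)
            if g == prev:
                run_len += 1
            else:
                prev, run_len = g, 1
            if g is not None:
                best[g] = max(best.get(g, 0), run_len)
        return all(
            best.get(g, 0) <= math.ceil(2 * counts[g] / n_groups) for g in counts
        )

    def draw() -> list[str]:
        for _ in range(max_attempts):
            order = list(rng.permutation(sample_ids))
            if longest_run_ok(order):
                return order
        return order  # pathological group structure: return last draw

    return draw(), draw()


@dataclass
class BatchLayout:
    """Ordered injection plan: (position, role, sample_id)."""

    plan: list[tuple[int, str, str]]

    def positions(self, role: str) -> list[int]:
        return [p for p, r, _ in self.plan if r == role]

    def count(self, role: str) -> int:
        return len(self.positions(role))


def build_layout(
    samples: list[str],
    n_standards: int = 11,
    qc_every: int = 10,
    blank_every: int = 5,
) -> BatchLayout:
    """Deterministic injection plan from an injection-ordered sample list.

    Calibration standards come first.  In the post-standard segment a blank
    occupies every ``blank_every``-th position and a QC is inserted after
    each run of ``qc_every`` experimental samples; on a collision the blank
    keeps the slot and the QC shifts to the next position.  Blank positions
    count from the first post-standard injection (standards excluded).
    """
    plan: list[tuple[int, str, str]] = []
    pos = 0
    for i in range(n_standards):
        pos += 1
        plan.append((pos, "standard", f"CAL{i + 1}"))

    queue = list(samples)
    post = 0  # post-standard position counter
    since_qc = 0
    qc_pending = False
    n_qc = 0
    n_blank = 0
    while queue or qc_pending:
        pos += 1
        post += 1
        if post % blank_every == 0:
            n_blank += 1
            plan.append((pos, "blank", f"BLANK{n_blank}"))
            continue
        if qc_pending:
            n_qc += 1
            plan.append((pos, "qc", f"QC{n_qc}"))
            qc_pending = False
            since_qc = 0
            continue
        if queue:
            plan.append((pos, "sample", queue.pop(0)))
            since_qc += 1
            if since_qc == qc_every:
                qc_pending = True
    return BatchLayout(plan)


# ---------------------------------------------------------------------------
# per-batch statistics and drift checks


def qc_batch_stats(qc_conc: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite mean and %CV of a batch's QC replicates.

    ``qc_conc`` is QC-replicate x metabolite.  CV uses the sample standard
    deviation and is missing with fewer than 2 replicates.
    """
    mean = qc_conc.mean()
    if len(qc_conc) >= 2:
        cv = 100.0 * qc_conc.std(ddof=1) / mean
    else:
        cv = pd.Series(np.nan, index=qc_conc.columns)
    return pd.DataFrame({"mean": mean, "cv_pct": cv}).rename_axis("hmdb_id")


def compare_to_history(
    batch_stats: pd.DataFrame,
    history: QCHistory,
    tolerance_pct: float = DEFAULT_RSD_TOLERANCE_PCT,
) -> pd.DataFrame:
    """Flag metabolites whose batch RSD exceeds the historical inter-day RSD.

    Status is ``pass`` when batch RSD <= history RSD x (1 + tolerance/100),
    ``warn`` otherwise, and ``unknown`` for metabolites without history.
    """
    hist_rsd = history.interday_rsd()
    rows = []
    for h, row in batch_stats.iterrows():
        ref = hist_rsd.get(h, np.nan)
        if np.isnan(ref):
            status = "unknown"
        elif np.isnan(row["cv_pct"]):
            status = "unknown"
        elif row["cv_pct"] <= ref * (1 + tolerance_pct / 100.0):
            status = "pass"
        else:
            status = "warn"
        rows.append({
            "hmdb_id": h, "batch_rsd_pct": row["cv_pct"],
            "history_rsd_pct": ref, "status": status,
        })
    return pd.DataFrame(rows).set_index("hmdb_id")


def reproducibility_summary(
    history: QCHistory,
    rt_by_batch: pd.DataFrame | None = None,
    r2_by_batch: pd.DataFrame | None = None,
    cv_tiers_pct: tuple[float, float, float] = (3.0, 4.0, 25.0),
) -> dict:
    """Cross-batch reproducibility: QC concentration CVs, RT CVs, R² CVs.

    Returns per-metabolite CV tables plus the headline fractions: share of
    metabolites with QC concentration CV below the 25% tier, and (when RT /
    R² tables are given, batch x metabolite) shares below the 4% and 3%
    tiers respectively.
    """
    r2_tier, rt_tier, conc_tier = cv_tiers_pct
    if history.frame["batch_id"].nunique() < 2:
        raise ValueError("need at least two batches for reproducibility")
    conc_cv = history.interday_rsd().rename("conc_cv_pct")
    out: dict = {
        "conc_cv": conc_cv,
        "fraction_conc_cv_below_tier": float((conc_cv < conc_tier).mean()),
        "tiers_pct": {"r2": r2_tier, "rt": rt_tier, "conc": conc_tier},
    }

    def _cv_cols(df: pd.DataFrame) -> pd.Series:
        return 100.0 * df.std(ddof=1) / df.mean()

    if rt_by_batch is not None:
        rt_cv = _cv_cols(rt_by_batch).rename("rt_cv_pct")
        out["rt_cv"] = rt_cv
        out["fraction_rt_cv_below_tier"] = float((rt_cv < rt_tier).mean())
    if r2_by_batch is not None:
        r2_cv = _cv_cols(r2_by_batch).rename("r2_cv_pct")
        out["r2_cv"] = r2_cv
        out["fraction_r2_cv_below_tier"] = float((r2_cv < r2_tier).mean())
    return out
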