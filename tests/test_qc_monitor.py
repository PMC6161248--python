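"""Batch layout, double randomization and QC drift surveillance."""

import math

import numpy as np
import pandas as pd
import pytest

from metaboquant.qc_monitor import (
    QCHistory,
    build_layout,
    compare_to_history,
    double_randomize,
    qc_batch_stats,
    reproducibility_summary,
)
from metaboquant.synthetic import simulate_qc_history


class TestDoubleRandomize:
    def test_deterministic_for_fixed_seed(self):
        ids = [f"s{i}" for i in range(20)]
        groups = {s: ("a" if i < 10 else "b") for i, s in enumerate(ids)}
        assert double_randomize(ids, groups, seed=5) == double_randomize(
            ids, groups, seed=5
        )

    def test_orders_are_independent_permutations(self):
        ids = [f"s{i}" for i in range(30)]
        ext, inj = double_randomize(ids, seed=1)
        assert sorted(ext) == sorted(inj) == sorted(ids)
        assert ext != inj

    def test_single_sample(self):
        assert double_randomize(["only"], seed=0) == (["only"], ["only"])

    def test_blocking_guard_over_many_seeds(self):
        """2 groups x 10 samples: no group block exceeds ceil(2n_g/G) in
        1000 seeded draws."""
        ids = [f"s{i}" for i in range(20)]
        groups = {s: ("a" if i < 10 else "b") for i, s in enumerate(ids)}
        limit = math.ceil(2 * 10 / 2)
        for seed in range(1000):
            for order in double_randomize(ids, groups, seed=seed):
                run, prev, worst = 0, None, 0
                for s in order:
                    run = run + 1 if groups[s] == prev else 1
                    prev = groups[s]
                    worst = max(worst, run)
                assert worst <= limit


class TestBuildLayout:
    def test_ten_samples_one_qc(self):
        layout = build_layout([f"s{i}" for i in range(10)])
        assert layout.count("qc") == 1

    def test_no_samples_standards_only(self):
        layout = build_layout([], n_standards=5)
        assert [r for _, r, _ in layout.plan] == ["standard"] * 5

    def test_25_samples_qc_and_blank_cadence(self):
        """25 experimental samples: 2 QCs; blanks at every 5th post-standard
        position (hand-enumerated from the interleaving rule)."""
        n_std = 11
        layout = build_layout([f"s{i}" for i in range(25)], n_standards=n_std)
        post = [(p - n_std, r) for p, r, _ in layout.plan if p > n_std]
        blanks = [p for p, r in post if r == "blank"]
        assert blanks == [p for p, _ in post if p % 5 == 0]
        assert layout.count("qc") == 2
        samples = [p for p, r in post if r == "sample"]
        assert len(samples) == 25

    def test_pure_function(self):
        ids = [f"s{i}" for i in range(13)]
        assert build_layout(ids).plan == build_layout(ids).plan

    def test_collision_blank_wins_qc_shifts(self):
        # with qc_every=4 and blank_every=5 the first QC would land on
        # post-standard position 5: the blank keeps it, QC moves to 6
        layout = build_layout([f"s{i}" for i in range(8)], n_standards=0,
                              qc_every=4, blank_every=5)
        roles = {p: r for p, r, _ in layout.plan}
        assert roles[5] == "blank"
        assert roles[6] == "qc"


class TestQCStats:
    def test_mean_and_cv(self):
        df = pd.DataFrame({"m1": [9.0, 10.0, 11.0], "m2": [5.0, 5.0, 5.0]})
        stats = qc_batch_stats(df)
        assert stats.loc["m1", "mean"] == 10.0
        assert stats.loc["m1", "cv_pct"] == pytest.approx(10.0)
        assert stats.loc["m2", "cv_pct"] == 0.0

    def test_single_replicate_cv_missing(self):
        stats = qc_batch_stats(pd.DataFrame({"m1": [10.0]}))
        assert np.isnan(stats.loc["m1", "cv_pct"])

    def test_matches_direct_recomputation_on_synthetic_lots(self):
        history, _ = simulate_qc_history(3, ["m1"], 50.0, 0.05, 0.1, 2, 3, 6)
        sub = history.frame[history.frame["batch_id"] == "B001"]
        df = sub.pivot_table(index=sub.groupby("hmdb_id").cumcount(),
                             columns="hmdb_id", values="conc_umol_l")
        stats = qc_batch_stats(df)
        vals = sub["conc_umol_l"].to_numpy()
        assert stats.loc["m1", "cv_pct"] == pytest.approx(
            100 * vals.std(ddof=1) / vals.mean()
        )


class TestCompareToHistory:
    def _history(self, batch_means):
        rows = [
            {"qc_lot": "L1", "batch_id": f"B{i}", "run_date": "2020-01-01",
             "hmdb_id": "m1", "conc_umol_l": m}
            for i, m in enumerate(batch_means)
        ]
        return QCHistory(pd.DataFrame(rows))

    def _stats(self, cv):
        return pd.DataFrame({"mean": [10.0], "cv_pct": [cv]},
                            index=pd.Index(["m1"], name="hmdb_id"))

    def test_pass_below_history(self):
        hist = self._history([90.0, 100.0, 110.0])  # inter-day RSD 10%
        status = compare_to_history(self._stats(8.0), hist, tolerance_pct=0.0)
        assert status.loc["m1", "status"] == "pass"

    def test_warn_above_tolerance(self):
        hist = self._history([90.0, 100.0, 110.0])
        status = compare_to_history(self._stats(15.0), hist, tolerance_pct=20.0)
        assert status.loc["m1", "status"] == "warn"  # 15 > 10 * 1.2

    def test_unknown_metabolite(self):
        hist = self._history([90.0, 100.0, 110.0])
        stats = pd.DataFrame({"mean": [1.0], "cv_pct": [5.0]},
                             index=pd.Index(["m2"], name="hmdb_id"))
        status = compare_to_history(stats, hist)
        assert status.loc["m2", "status"] == "unknown"

    def test_noise_free_sensitivity_and_specificity(self):
        """Noise-free limit: exactly the batches with injected excess
        variability are flagged."""
        hist = self._history([99.0, 100.0, 101.0])  # RSD 1%
        quiet = compare_to_history(self._stats(1.0), hist, tolerance_pct=0.0)
        loud = compare_to_history(self._stats(5.0), hist, tolerance_pct=0.0)
        assert quiet.loc["m1", "status"] == "pass"
        assert loud.loc["m1", "status"] == "warn"


class TestHistory:
    def test_append_only_preserves_earlier_records(self):
        h1, _ = simulate_qc_history(1, ["m1"], 50.0, 0.05, 0.1, 2, 2, 4)
        new = h1.frame.iloc[:4].assign(batch_id="B999")
        h2 = h1.append(new)
        pd.testing.assert_frame_equal(h2.frame.iloc[: len(h1)], h1.frame)
        assert len(h2) == len(h1) + 4

    def test_interday_rsd_matches_oracle(self):
        history, _ = simulate_qc_history(5, ["m1"], 80.0, 0.1, 0.15, 3, 4, 5)
        rsd = history.interday_rsd()["m1"]
        means = history.frame.groupby("batch_id")["conc_umol_l"].mean()
        assert rsd == pytest.approx(100 * means.std(ddof=1) / means.mean())

    def test_csv_round_trip(self, tmp_path):
        history, _ = simulate_qc_history(2, ["m1", "m2"], 10.0, 0.1, 0.2, 2, 2, 3)
        path = history.to_csv(tmp_path / "qc.csv")
        reread = QCHistory.from_csv(path)
        pd.testing.assert_frame_equal(reread.frame, history.frame)


class TestReproducibility:
    def test_synthetic_25_batches_low_noise(self):
        """25-batch history at 3% concentration noise: >= 95% of metabolites
        under the 25% CV tier."""
        ids = [f"m{i}" for i in range(20)]
        history, _ = simulate_qc_history(
            11, ids, 50.0, lot_sd_log=0.0, noise_sd_log=0.03,
            n_lots=5, batches_per_lot=5, reps_per_batch=4,
        )
        out = reproducibility_summary(history)
        assert out["fraction_conc_cv_below_tier"] >= 0.95

    def test_constant_rt_and_r2_have_zero_cv(self):
        ids = ["m1"]
        history, _ = simulate_qc_history(1, ids, 10.0, 0.0, 0.05, 2, 2, 3)
        rt = pd.DataFrame({"m1": [2.5, 2.5, 2.5]})
        r2 = pd.DataFrame({"m1": [0.999, 0.999]})
        out = reproducibility_summary(history, rt_by_batch=rt, r2_by_batch=r2)
        assert out["rt_cv"]["m1"] == 0.0
        assert out["r2_cv"]["m1"] == 0.0

    def test_needs_two_batches(self):
        history, _ = simulate_qc_history(1, ["m1"], 10.0, 0.0, 0.05, 1, 1, 5)
        with pytest.raises(ValueError):
            reproducibility_summary(history)
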