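import numpy as np
import pandas as pd
import pytest

from methtriad import dmr
from methtriad.config import PipelineConfig


class TestTiling:
    def test_stated_example(self):
        w = dmr.tile_windows({"c1": 2500}, 1000, 500)
        assert list(w["start"]) == [0, 500, 1000, 1500, 2000]
        assert tuple(w.iloc[-1][["start", "end"]]) == (2000, 2500)

    def test_short_chromosome_single_truncated_window(self):
        w = dmr.tile_windows({"c1": 800}, 1000, 500)
        assert len(w) == 2  # starts 0 and 500, both truncated at 800
        assert tuple(w.iloc[0][["start", "end"]]) == (0, 800)

    def test_window_count_matches_brute_force(self, rng):
        lengths = {f"c{i}": int(rng.integers(100, 20_000)) for i in range(8)}
        w = dmr.tile_windows(lengths, 1000, 500)
        expected = sum(int(np.ceil(ln / 500)) for ln in lengths.values())
        assert len(w) == expected
        # brute force: every window starts at a multiple of step, inside chrom
        for chrom, ln in lengths.items():
            sub = w[w["chrom"] == chrom]
            assert (sub["start"] % 500 == 0).all()
            assert (sub["start"] < ln).all() and (sub["end"] <= ln).all()

    def test_invalid_step_errors(self):
        with pytest.raises(ValueError):
            dmr.tile_windows({"c1": 100}, 500, 1000)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert dmr.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert dmr.bh_adjust([0.3]) == pytest.approx([0.3])

    def test_empty_input(self):
        assert len(dmr.bh_adjust([])) == 0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            dmr.bh_adjust([0.5, 1.2])

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            expected = multipletests(p, method="fdr_bh")[1]
            assert dmr.bh_adjust(p) == pytest.approx(expected)


def _calls(chrom, pos, meth, total, context="CG"):
    return pd.DataFrame({
        "chrom": chrom, "pos": pos, "strand": "+",
        "context": context, "meth": meth, "total": total})


class TestWindowTest:
    def test_identical_pools_give_p_one(self):
        windows = dmr.tile_windows({"c1": 1000}, 1000, 500)
        calls = _calls("c1", [100, 300], [5, 7], [10, 14])
        stats = dmr.window_test(windows, calls, calls.copy(), "CG")
        assert stats["p"].to_numpy() == pytest.approx(1.0)

    def test_windows_without_coverage_in_either_sample_dropped(self):
        windows = dmr.tile_windows({"c1": 4000}, 1000, 1000)
        a = _calls("c1", [100], [5], [10])
        b = _calls("c1", [100, 2100], [2, 3], [10, 10])
        stats = dmr.window_test(windows, a, b, "CG")
        assert list(stats["start"]) == [0]

    def test_batch_fisher_equals_scalar_fisher(self, rng):
        ma = rng.integers(0, 40, 150)
        ta = ma + rng.integers(1, 40, 150)
        mb = rng.integers(0, 40, 150)
        tb = mb + rng.integers(1, 40, 150)
        batch = dmr.fisher_2x2_batch(ma, ta, mb, tb)
        from methtriad.methylome import fisher_2x2
        scalar = [fisher_2x2(int(a), int(t1 - a), int(b), int(t2 - b))
                  for a, t1, b, t2 in zip(ma, ta, mb, tb)]
        assert batch == pytest.approx(scalar, abs=1e-10)

    def test_strands_are_pooled(self):
        windows = dmr.tile_windows({"c1": 1000}, 1000, 1000)
        a = _calls("c1", [100, 200], [10, 0], [10, 10])
        a.loc[1, "strand"] = "-"
        b = _calls("c1", [100, 200], [5, 5], [10, 10])
        stats = dmr.window_test(windows, a, b, "CG")
        assert stats.loc[0, "meth_A"] == 10 and stats.loc[0, "total_A"] == 20


class TestFilterAndMerge:
    def _stats(self, rows):
        base = {"chrom": "c1", "context": "CG"}
        recs = []
        for r in rows:
            rec = dict(base)
            rec.update(r)
            rec["level_A"] = rec["meth_A"] / rec["total_A"]
            rec["level_B"] = rec["meth_B"] / rec["total_B"]
            recs.append(rec)
        return pd.DataFrame(recs)

    def _mk_calls(self, stats_df):
        """One synthetic cytosine per window midpoint carrying its counts."""
        rows_a, rows_b = [], []
        for _, r in stats_df.iterrows():
            mid = (r["start"] + r["end"]) // 2
            rows_a.append(("c1", mid, "+", "CG", r["meth_A"], r["total_A"]))
            rows_b.append(("c1", mid, "+", "CG", r["meth_B"], r["total_B"]))
        cols = ["chrom", "pos", "strand", "context", "meth", "total"]
        return (pd.DataFrame(rows_a, columns=cols),
                pd.DataFrame(rows_b, columns=cols))

    def test_passing_window_is_kept_with_direction(self, pipeline_config):
        stats = self._stats([{
            "start": 0, "end": 1000, "meth_A": 28, "total_A": 40,
            "meth_B": 12, "total_B": 40, "p": 0.001, "q": 0.01}])
        a, b = self._mk_calls(stats)
        out = dmr.filter_and_merge(stats, a, b, pipeline_config)
        assert len(out) == 1
        rec = out.iloc[0]
        assert rec["direction"] == "hyper"
        assert rec["delta"] == pytest.approx(40.0)
        assert rec["fold_change"] == pytest.approx(0.7 / 0.3)

    def test_small_level_difference_dropped_despite_p(self, pipeline_config):
        stats = self._stats([{
            "start": 0, "end": 1000, "meth_A": 400, "total_A": 1000,
            "meth_B": 300, "total_B": 1000, "p": 1e-6, "q": 1e-5}])
        a, b = self._mk_calls(stats)
        assert len(dmr.filter_and_merge(stats, a, b, pipeline_config)) == 0

    def test_low_coverage_window_dropped(self, pipeline_config):
        stats = self._stats([{
            "start": 0, "end": 1000, "meth_A": 14, "total_A": 20,
            "meth_B": 6, "total_B": 40, "p": 0.001, "q": 0.01}])
        a, b = self._mk_calls(stats)
        assert len(dmr.filter_and_merge(stats, a, b, pipeline_config)) == 0

    def test_lower_fold_bound_keeps_hypo(self, pipeline_config):
        stats = self._stats([{
            "start": 0, "end": 1000, "meth_A": 18, "total_A": 40,
            "meth_B": 40, "total_B": 60, "p": 0.001, "q": 0.01}])
        # levels 0.45 vs ~0.667: fc = 0.675 -> dropped; adjust to fc < 0.5
        stats.loc[0, ["meth_A", "total_A"]] = [12, 40]
        stats["level_A"] = stats["meth_A"] / stats["total_A"]
        a, b = self._mk_calls(stats)
        out = dmr.filter_and_merge(stats, a, b, pipeline_config)
        assert len(out) == 1 and out.iloc[0]["direction"] == "hypo"
        assert out.iloc[0]["fold_change"] < 0.5

    def test_three_overlapping_windows_merge_into_one_region(self, pipeline_config):
        rows = [{"start": s, "end": s + 1000, "meth_A": 28, "total_A": 40,
                 "meth_B": 12, "total_B": 40, "p": 0.001, "q": 0.01}
                for s in (0, 500, 1000)]
        stats = self._stats(rows)
        a, b = self._mk_calls(stats)
        out = dmr.filter_and_merge(stats, a, b, pipeline_config)
        assert len(out) == 1
        rec = out.iloc[0]
        assert (rec["start"], rec["end"]) == (0, 2000)
        assert rec["n_merged_windows"] == 3

    def test_merge_pools_distinct_cytosines_once(self, pipeline_config):
        rows = [{"start": s, "end": s + 1000, "meth_A": 28, "total_A": 40,
                 "meth_B": 12, "total_B": 40, "p": 0.001, "q": 0.01}
                for s in (0, 500)]
        stats = self._stats(rows)
        a, b = self._mk_calls(stats)  # one cytosine per window: pos 500, 1000
        out = dmr.filter_and_merge(stats, a, b, pipeline_config)
        assert out.iloc[0]["total_A"] == 80  # 2 distinct sites, not 3 window hits

    def test_opposite_directions_do_not_merge(self, pipeline_config):
        rows = [
            {"start": 0, "end": 1000, "meth_A": 28, "total_A": 40,
             "meth_B": 12, "total_B": 40, "p": 0.001, "q": 0.01},
            {"start": 1000, "end": 2000, "meth_A": 12, "total_A": 40,
             "meth_B": 28, "total_B": 40, "p": 0.001, "q": 0.01},
        ]
        stats = self._stats(rows)
        a, b = self._mk_calls(stats)
        out = dmr.filter_and_merge(stats, a, b, pipeline_config)
        assert len(out) == 2
        assert set(out["direction"]) == {"hyper", "hypo"}


class TestSwapSymmetry:
    def test_swapping_conditions_mirrors_every_dmr(self, small_sim):
        cfg = PipelineConfig()
        lengths = small_sim.annotation.chrom_lengths
        d1, _ = dmr.call_dmrs(small_sim.calls_a, small_sim.calls_b, lengths, cfg)
        d2, _ = dmr.call_dmrs(small_sim.calls_b, small_sim.calls_a, lengths, cfg)
        key = ["chrom", "start", "end", "context"]
        a = d1.sort_values(key).reset_index(drop=True)
        b = d2.sort_values(key).reset_index(drop=True)
        assert a[key].equals(b[key])
        assert (a["direction"].map({"hyper": "hypo", "hypo": "hyper"})
                == b["direction"]).all()
        assert a["p"].to_numpy() == pytest.approx(b["p"].to_numpy(), abs=1e-12)
        assert a["q"].to_numpy() == pytest.approx(b["q"].to_numpy(), abs=1e-12)
        assert a["delta"].to_numpy() == pytest.approx(-b["delta"].to_numpy())


class TestRecoverySmoke:
    def test_planted_dmrs_recovered_on_reduced_dataset(self, small_sim):
        cfg = PipelineConfig()
        dmrs, _ = dmr.call_dmrs(small_sim.calls_a, small_sim.calls_b,
                                small_sim.annotation.chrom_lengths, cfg)
        planted = small_sim.truth.dmrs
        hits = sum(
            ((dmrs["chrom"] == d["chrom"]) & (dmrs["start"] < d["end"])
             & (dmrs["end"] > d["start"])
             & (dmrs["direction"] == d["direction"])).any()
            for d in planted)
        assert hits >= 0.8 * len(planted)
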