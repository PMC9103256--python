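import numpy as np
import pandas as pd
import pytest

from methtriad.config import ConfigurationError, SimConfig
from methtriad import simulate as sim
from methtriad.integration import classify_negative


def _negative_pattern_label(t):
    return classify_negative(*t)


class TestGenome:
    def test_fixed_seed_reproduces_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(seed=5, n_chroms=1, chrom_len=200_000, n_genes=10,
                        n_mirna_loci=6, n_planted_dmrs=4,
                        n_planted_neg_triads=1, n_distractor_triads=1,
                        n_planted_degs=4, n_planted_ders=4)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        sim.simulate_all(cfg).write_all(out1)
        sim.simulate_all(cfg).write_all(out2)
        for f in sorted(out1.iterdir()):
            assert f.read_bytes() == (out2 / f.name).read_bytes(), f.name

    def test_zero_genes_is_valid_empty_annotation(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_len=100_000, n_genes=0,
                        n_mirna_loci=0, n_planted_dmrs=0, n_planted_degs=0,
                        n_planted_ders=0, n_planted_neg_triads=0,
                        n_distractor_triads=0)
        ann, sites = sim.simulate_genome(cfg)
        assert ann.genes == [] and len(ann.mirna_loci) == 0
        assert len(sites) > 0

    def test_all_features_within_chromosome_bounds(self):
        cfg = SimConfig(seed=3)
        ann, sites = sim.simulate_genome(cfg)
        for g in ann.genes:
            assert 0 <= g.start < g.end <= ann.chrom_lengths[g.chrom]
            for s, e in g.exons:
                assert g.start <= s < e <= g.end
        for _, m in ann.mirna_loci.iterrows():
            assert 0 <= m["start"] < m["end"] <= ann.chrom_lengths[m["chrom"]]
        for chrom, grp in sites.groupby("chrom"):
            assert grp["pos"].between(0, ann.chrom_lengths[chrom] - 1).all()
            assert grp["pos"].is_unique

    def test_genes_do_not_overlap_each_others_flanks(self):
        cfg = SimConfig(seed=9)
        ann, _ = sim.simulate_genome(cfg)
        by_chrom = {}
        for g in ann.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.start)
            for g1, g2 in zip(genes, genes[1:]):
                assert g2.start - g1.end >= 2 * cfg.flank

    def test_overcrowded_genome_is_a_configuration_error(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_len=50_000, n_genes=50)
        with pytest.raises(ConfigurationError, match="cannot place"):
            sim.simulate_genome(cfg)


class TestMethylation:
    def test_large_concentration_approaches_binomial_variance(self):
        cfg = SimConfig(seed=2, bb_overdispersion=1e7)
        rng = np.random.default_rng(0)
        n = 40_000
        sites = pd.DataFrame({
            "chrom": "c1", "pos": np.arange(n), "strand": "+",
            "context": "CHG"})
        truth = sim.SimTruth()
        a, _ = sim.simulate_methylation(sites, truth, cfg, rng)
        # empirical variance of meth counts at fixed coverage vs binomial
        grp = a.groupby("total")["meth"]
        mu = cfg.baseline_levels["CHG"]
        checked = 0
        for cov, vals in grp:
            if len(vals) < 1500:
                continue
            binom_var = cov * mu * (1 - mu)
            assert abs(vals.var() - binom_var) / binom_var < 0.10
            checked += 1
        assert checked >= 3

    def test_planted_hyper_region_reaches_shifted_mean(self):
        cfg = SimConfig(seed=4, baseline_levels={"CG": 0.65, "CHG": 0.3,
                                                 "CHH": 0.10})
        rng = np.random.default_rng(4)
        n = 800
        sites = pd.DataFrame({
            "chrom": "c1", "pos": np.arange(n), "strand": "+",
            "context": "CHG"})
        truth = sim.SimTruth(dmrs=[{
            "chrom": "c1", "start": 0, "end": n, "context": "CHG",
            "direction": "hyper"}])
        a, b = sim.simulate_methylation(sites, truth, cfg, rng)
        level_a = a["meth"].sum() / a["total"].sum()
        level_b = b["meth"].sum() / b["total"].sum()
        assert level_a == pytest.approx(0.70, abs=0.02)
        assert level_b == pytest.approx(0.30, abs=0.02)

    def test_null_genomes_agree_genome_wide(self):
        cfg = SimConfig(seed=6, n_planted_dmrs=0, n_planted_neg_triads=0,
                        n_distractor_triads=0)
        rng = np.random.default_rng(6)
        n = 100_000
        sites = pd.DataFrame({
            "chrom": "c1", "pos": np.arange(n), "strand": "+",
            "context": np.tile(["CG", "CHG", "CHH"], n)[:n]})
        a, b = sim.simulate_methylation(sites, sim.SimTruth(), cfg, rng)
        la = a["meth"].sum() / a["total"].sum()
        lb = b["meth"].sum() / b["total"].sum()
        assert abs(la - lb) < 0.01

    def test_infeasible_shift_is_a_configuration_error(self):
        cfg = SimConfig(seed=1, dmr_delta=0.4)
        rng = np.random.default_rng(0)
        sites = pd.DataFrame({"chrom": ["c1"], "pos": [10], "strand": ["+"],
                              "context": ["CG"]})
        truth = sim.SimTruth(dmrs=[{"chrom": "c1", "start": 0, "end": 100,
                                    "context": "CG", "direction": "hyper"}])
        with pytest.raises(ConfigurationError):
            sim.simulate_methylation(sites, truth, cfg, rng)


class TestCounts:
    def test_null_features_rarely_called(self):
        cfg = SimConfig(seed=3)
        rng = np.random.default_rng(3)
        fids = [f"f{i}" for i in range(1000)]
        counts = sim.simulate_counts(fids, {}, cfg, rng)
        from methtriad.diffexpr import der_from_counts
        res = der_from_counts(counts, ["A"] * 3 + ["B"] * 3)
        called = (res["direction"] != "ns").mean()
        assert called <= 0.05

    def test_planted_fold_change_visible_in_counts(self):
        cfg = SimConfig(seed=8)
        hits = 0
        n_trials = 200
        for s in range(n_trials):
            rng = np.random.default_rng(100 + s)
            counts = sim.simulate_counts(
                ["f0"], {"f0": "up"}, cfg, rng,
                planted_baseline_range=(500.0, 500.0))
            mean_a = counts.iloc[0, :3].mean()
            mean_b = counts.iloc[0, 3:].mean()
            lfc = np.log2((mean_a + 1) / (mean_b + 1))
            hits += 1.5 <= lfc <= 2.5
        assert hits >= 0.85 * n_trials

    def test_zero_replicates_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            SimConfig(seed=1, reps_per_condition=0)


class TestTriadPlanting:
    def test_requested_triads_are_fully_negative_by_construction(self, small_sim):
        truth = small_sim.truth
        assert len(truth.neg_triads) == 3
        for t in truth.neg_triads:
            tup = (truth.de_mrna[t["gene_id"]], t["dmr_dir"],
                   truth.de_mirna[t["mirna_id"]])
            assert _negative_pattern_label(tup) == "fully_negative"

    def test_distractors_are_never_fully_negative(self, small_sim):
        truth = small_sim.truth
        assert len(truth.distractor_triads) == 3
        for t in truth.distractor_triads:
            tup = (truth.de_mrna[t["gene_id"]], t["dmr_dir"],
                   truth.de_mirna[t["mirna_id"]])
            assert _negative_pattern_label(tup) != "fully_negative"

    def test_planted_dmr_intervals_are_disjoint(self, small_sim):
        by_chrom = {}
        for d in small_sim.truth.dmrs:
            by_chrom.setdefault(d["chrom"], []).append((d["start"], d["end"]))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(e1 <= s2 for (_, e1), (s2, _) in zip(ivs, ivs[1:]))

    def test_request_exceeding_features_is_a_configuration_error(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_len=300_000, n_genes=4,
                        n_mirna_loci=4, n_planted_neg_triads=4,
                        n_distractor_triads=4)
        with pytest.raises(ConfigurationError, match="triads"):
            sim.simulate_all(cfg)

    def test_emitted_files_revalidate_through_readers(self, small_sim, tmp_path):
        from methtriad import io as mio
        small_sim.write_all(tmp_path)
        a = mio.read_cytosine_report(tmp_path / "treatment.cx.tsv")
        assert len(a) == len(small_sim.calls_a)
        genes = mio.read_gff3_genes(tmp_path / "genes.gff3")
        assert len(genes) == len(small_sim.annotation.genes)
        loci = mio.read_bed(tmp_path / "mirna_loci.bed")
        assert len(loci) == len(small_sim.annotation.mirna_loci)
        counts = mio.read_counts(tmp_path / "mirna_counts.tsv")
        pd.testing.assert_frame_equal(counts, small_sim.mirna_counts,
                                      check_names=False)
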