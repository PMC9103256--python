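"""End-to-end orchestration: from inputs (or a simulation) to the key-gene table.

Stages: context summaries + Fisher comparison -> sliding-window DMR calling
-> miRNA DER test and mRNA DEG thresholds -> DMR-gene and miRNA-mC
association -> triad building and negative-correlation classification ->
enrichment of the key genes. Every stage's table lands in ``outdir`` when
one is given.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate, diffexpr, dmr, enrichment, integration, io as mio, methylome
from .config import PipelineConfig
from .models import GeneModel
from .simulate import SimConfig, SimResult, simulate_all

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    context_summary_a: pd.DataFrame
    context_summary_b: pd.DataFrame
    context_comparison: pd.DataFrame
    regional_profile_a: pd.DataFrame
    regional_profile_b: pd.DataFrame
    dmrs: pd.DataFrame
    window_stats: pd.DataFrame
    ders: pd.DataFrame
    degs: pd.DataFrame
    dmr_gene_links: pd.DataFrame
    gene_dmr_directions: pd.DataFrame
    dmr_expression: pd.DataFrame
    mirna_mc: pd.DataFrame
    mirna_mc_summary: dict
    triads: pd.DataFrame
    key_genes: pd.DataFrame
    enrichment: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write_all(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_table(self.context_summary_a, outdir / "context_summary_treatment.tsv")
        mio.write_table(self.context_summary_b, outdir / "context_summary_control.tsv")
        mio.write_table(self.context_comparison, outdir / "context_comparison.tsv")
        mio.write_table(self.regional_profile_a, outdir / "regional_profile_treatment.tsv")
        mio.write_table(self.regional_profile_b, outdir / "regional_profile_control.tsv")
        mio.write_table(self.window_stats, outdir / "window_stats.tsv")
        mio.write_table(self.dmrs, outdir / "dmrs.tsv")
        if len(self.dmrs):
            mio.write_bed(self.dmrs, outdir / "dmrs.bed")
        mio.write_table(self.ders, outdir / "ders.tsv")
        mio.write_table(self.degs, outdir / "degs.tsv")
        mio.write_table(self.dmr_gene_links, outdir / "dmr_gene_links.tsv")
        mio.write_table(self.gene_dmr_directions, outdir / "gene_dmr_directions.tsv")
        self.dmr_expression.to_csv(outdir / "dmr_expression_summary.tsv", sep="\t")
        mio.write_table(self.mirna_mc, outdir / "mirna_mc.tsv")
        mio.write_table(self.triads, outdir / "triads.tsv")
        mio.write_table(self.key_genes, outdir / "key_genes.tsv")
        if len(self.enrichment):
            mio.write_table(self.enrichment, outdir / "key_gene_enrichment.tsv")


def run_pipeline(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    genes: list[GeneModel],
    chrom_lengths: dict[str, int],
    mirna_loci: pd.DataFrame,
    mirna_counts: pd.DataFrame,
    mrna_de: pd.DataFrame,
    target_pairs: pd.DataFrame,
    config: PipelineConfig | None = None,
    term_map: pd.DataFrame | None = None,
    groups: list[str] | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs.

    ``mrna_de`` is either a raw count matrix (columns = replicates; the
    built-in stand-in test is applied) or a precomputed DE table with
    feature_id/log2fc/q columns (only thresholds are applied). Condition A
    is the treatment.
    """
    config = config or PipelineConfig()

    sum_a = methylome.summarize_contexts(calls_a, config.min_meth_reads)
    sum_b = methylome.summarize_contexts(calls_b, config.min_meth_reads)
    comparison = methylome.compare_context_counts(sum_a, sum_b)
    prof_a = methylome.regional_profile(calls_a, genes, config.flank, "treatment")
    prof_b = methylome.regional_profile(calls_b, genes, config.flank, "control")

    dmrs, window_stats = dmr.call_dmrs(calls_a, calls_b, chrom_lengths, config)

    if groups is None:
        reps = mirna_counts.shape[1] // 2
        groups = ["A"] * reps + ["B"] * (mirna_counts.shape[1] - reps)
    ders = diffexpr.der_from_counts(mirna_counts, groups, config)

    if "log2fc" in mrna_de.columns and "q" in mrna_de.columns:
        degs = diffexpr.apply_deg_thresholds(mrna_de, config)
    else:
        mgroups = (["A"] * (mrna_de.shape[1] // 2)
                   + ["B"] * (mrna_de.shape[1] - mrna_de.shape[1] // 2))
        degs = diffexpr.deg_standin_test(mrna_de, mgroups, config)

    links = annotate.link_dmrs_to_genes(dmrs, genes, config.flank)
    gene_dirs = annotate.gene_dmr_directions(links)
    dmr_expr = annotate.dmr_expression_summary(gene_dirs, degs)
    mirna_mc, mirna_mc_summary = annotate.mirna_mc_association(
        mirna_loci, calls_a, config.min_meth_reads)

    der_dir = ders.set_index("feature_id")["direction"]
    der_targets = target_pairs.copy()
    der_targets["mirna_dir"] = [
        der_dir.get(m, "ns") for m in der_targets["mirna_id"]]
    triads = integration.build_triads(degs, gene_dirs, der_targets)
    key_genes = integration.key_gene_table(triads)

    enrich = pd.DataFrame()
    if term_map is not None and len(key_genes):
        key_set = sorted(set(key_genes.loc[key_genes["is_key_gene"], "gene_id"]))
        if key_set:
            background = [g.gene_id for g in genes]
            enrich = enrichment.hypergeom_enrich(key_set, background, term_map,
                                                 alpha=config.alpha_p)

    return PipelineResult(
        context_summary_a=sum_a, context_summary_b=sum_b,
        context_comparison=comparison,
        regional_profile_a=prof_a, regional_profile_b=prof_b,
        dmrs=dmrs, window_stats=window_stats, ders=ders, degs=degs,
        dmr_gene_links=links, gene_dmr_directions=gene_dirs,
        dmr_expression=dmr_expr, mirna_mc=mirna_mc,
        mirna_mc_summary=mirna_mc_summary, triads=triads,
        key_genes=key_genes, enrichment=enrich,
    )


def run_all_synthetic(sim_config: SimConfig | None = None,
                      config: PipelineConfig | None = None,
                      outdir: str | Path | None = None
                      ) -> tuple[PipelineResult, SimResult]:
    """Simulate a dataset and run the full pipeline on it."""
    sim = simulate_all(sim_config or SimConfig())
    reps = sim.config.reps_per_condition
    result = run_pipeline(
        calls_a=sim.calls_a, calls_b=sim.calls_b,
        genes=sim.annotation.genes,
        chrom_lengths=sim.annotation.chrom_lengths,
        mirna_loci=sim.annotation.mirna_loci,
        mirna_counts=sim.mirna_counts,
        mrna_de=sim.mrna_counts,
        target_pairs=sim.target_pairs,
        config=config,
        term_map=sim.term_map,
        groups=["A"] * reps + ["B"] * reps,
    )
    if outdir is not None:
        outdir = Path(outdir)
        sim.write_all(outdir / "inputs")
        result.write_all(outdir / "results")
    return result, sim


def triad_recovery(result: PipelineResult, truth) -> dict:
    """Precision/recall of called fully-negative triads against the truth.

    A triad is identified by its (gene, miRNA) pair. Also reports how many
    planted distractors were (wrongly) labelled fully negative.
    """
    kg = result.key_genes
    called = set()
    if len(kg):
        called = {
            (r["gene_id"], r["mirna_id"])
            for _, r in kg[kg["is_key_gene"]].iterrows()
        }
    planted = {(t["gene_id"], t["mirna_id"]) for t in truth.neg_triads}
    distractors = {(t["gene_id"], t["mirna_id"]) for t in truth.distractor_triads}
    tp = len(called & planted)
    return {
        "n_called": len(called),
        "n_planted": len(planted),
        "tp": tp,
        "precision": tp / len(called) if called else float("nan"),
        "recall": tp / len(planted) if planted else float("nan"),
        "distractors_called": len(called & distractors),
    }
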