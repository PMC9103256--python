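"""Synthetic two-condition tri-omics data with planted ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a small annotated genome (non-overlapping multi-exon genes with intergenic
  margins, intergenic miRNA precursor loci, cytosine sites in the three
  contexts at configurable densities);
* one pooled bisulfite sample per condition with beta-binomially
  overdispersed methylated counts — each site carries one latent
  Beta-distributed level shared by both conditions, and only sites inside a
  planted DMR of the matching context get an independent, shifted draw in
  the treatment condition;
* negative-binomial miRNA/mRNA count matrices (3 replicates per condition,
  jittered library sizes) with planted differential features;
* coherently planted negative triads — (hypo DMR, down miRNA, up gene) or
  the mirrored pattern — plus distractor triads violating exactly one
  direction, so classifier specificity is testable.

All outputs are a deterministic function of ``SimConfig.seed``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .config import ConfigurationError, SimConfig
from .models import CONTEXTS, GeneModel

log = logging.getLogger(__name__)

_MIN_GAP_FACTOR = 2  # intergenic gap >= 2*flank + extra, keeps gene flanks apart
_EXTRA_GAP = 2000


@dataclass
class Annotation:
    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    mirna_loci: pd.DataFrame  # chrom, start, end, name


@dataclass
class SimTruth:
    """Planted ground truth, JSON-serializable for recovery tests."""

    dmrs: list[dict] = field(default_factory=list)       # chrom,start,end,context,direction[,gene_id]
    de_mrna: dict[str, str] = field(default_factory=dict)   # gene_id -> up/down
    de_mirna: dict[str, str] = field(default_factory=dict)  # mirna_id -> up/down
    neg_triads: list[dict] = field(default_factory=list)    # gene_id,dmr_dir,mirna_id
    distractor_triads: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# direction -> (context, shift sign); chosen so baseline +/- delta stays in
# [0, 1] at the default baselines (CG 0.65 down, CHG 0.35 up)
PLANT_SCHEMES = (("hypo", "CG", -1.0), ("hyper", "CHG", +1.0))


def _check_plant_feasible(config: SimConfig) -> None:
    for direction, ctx, sign in PLANT_SCHEMES:
        target = config.baseline_levels[ctx] + sign * config.dmr_delta
        if not (0.0 <= target <= 1.0):
            raise ConfigurationError(
                f"planted {direction} DMRs in {ctx} would need mean {target:.2f} "
                "outside [0, 1]; adjust baseline_levels or dmr_delta")


def simulate_genome(config: SimConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[Annotation, pd.DataFrame]:
    """Build the annotation and the cytosine site list.

    Genes are placed left to right with intergenic gaps of at least
    2*flank + 2 kb (randomized slack), so no gene's flank touches another
    gene; miRNA loci go into the gaps. Sites is a frame with chrom, pos,
    strand, context.
    """
    rng = rng or np.random.default_rng(config.seed)
    chrom_lengths = {f"chr{i+1}": config.chrom_len for i in range(config.n_chroms)}
    per_chrom = _split_counts(config.n_genes, config.n_chroms)
    mirna_per_chrom = _split_counts(config.n_mirna_loci, config.n_chroms)

    genes: list[GeneModel] = []
    mirna_rows = []
    for ci, (chrom, ln) in enumerate(chrom_lengths.items()):
        n = per_chrom[ci]
        structures = [_gene_structure(rng) for _ in range(n)]
        spans = [s[-1][1] for s in structures]  # end of last exon
        min_gap = _MIN_GAP_FACTOR * config.flank + _EXTRA_GAP
        margin = config.flank + _EXTRA_GAP
        needed = sum(spans) + (n + 1) * min_gap + 2 * margin
        if needed > ln:
            raise ConfigurationError(
                f"cannot place {n} genes on {chrom} (len {ln}): need {needed} bp; "
                "reduce n_genes or increase chrom_len")
        slack = ln - needed
        extra = np.diff(np.sort(np.concatenate(
            [[0.0, float(slack)], rng.uniform(0, slack, n)]))) if n else np.array([slack])
        cursor = margin
        gaps: list[tuple[int, int]] = []
        prev_end = cursor
        for gi in range(n):
            cursor += min_gap + int(extra[gi])
            gaps.append((prev_end, cursor))
            exons = [(cursor + s, cursor + e) for s, e in structures[gi]]
            start, end = exons[0][0], exons[-1][1]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(
                gene_id=f"gene_{chrom}_{gi+1:04d}", chrom=chrom,
                start=start, end=end, strand=strand, exons=exons))
            prev_end = end
            cursor = end
        gaps.append((prev_end, ln - margin))
        mirna_rows.extend(_place_mirnas(
            chrom, gaps, mirna_per_chrom[ci], config, rng))

    mirna_loci = pd.DataFrame(
        mirna_rows, columns=["chrom", "start", "end", "name"])
    sites = _simulate_sites(chrom_lengths, config, rng)
    log.info("simulated genome: %d genes, %d miRNA loci, %d cytosines",
             len(genes), len(mirna_loci), len(sites))
    return Annotation(chrom_lengths, genes, mirna_loci), sites


def _split_counts(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _gene_structure(rng: np.random.Generator) -> list[tuple[int, int]]:
    """Exon intervals relative to the gene start (1-5 exons)."""
    n_exons = int(rng.integers(1, 6))
    pos = 0
    exons = []
    for i in range(n_exons):
        if i > 0:
            pos += int(rng.integers(100, 401))  # intron
        length = int(rng.integers(150, 601))
        exons.append((pos, pos + length))
        pos += length
    return exons


def _place_mirnas(chrom, gaps, n, config: SimConfig, rng) -> list[list]:
    """Drop miRNA loci into intergenic gaps, clear of every gene's flank."""
    usable = []
    for (s, e) in gaps:
        lo, hi = s + config.flank + 200, e - config.flank - 200
        if hi - lo >= 200:
            usable.append((lo, hi))
    if not usable:
        if n > 0:
            raise ConfigurationError("no intergenic space for miRNA loci")
        return []
    rows = []
    for mi in range(n):
        lo, hi = usable[mi % len(usable)]
        length = int(rng.integers(80, 161))
        start = int(rng.integers(lo, max(lo + 1, hi - length)))
        rows.append([chrom, start, start + length, f"mirna_{chrom}_{mi+1:03d}"])
    return rows


def _simulate_sites(chrom_lengths, config: SimConfig, rng) -> pd.DataFrame:
    dens = config.cytosine_density
    total_density = sum(dens.values())
    probs = np.array([dens[c] / total_density for c in CONTEXTS])
    frames = []
    for chrom, ln in chrom_lengths.items():
        n_sites = int(round(ln * total_density))
        pos = np.sort(rng.choice(ln, size=n_sites, replace=False))
        ctx = rng.choice(np.array(CONTEXTS), size=n_sites, p=probs)
        strand = rng.choice(np.array(["+", "-"]), size=n_sites)
        frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": pos, "strand": strand, "context": ctx}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# planting


def plant_truth(annotation: Annotation, config: SimConfig,
                rng: np.random.Generator) -> SimTruth:
    """Plant DMRs, DE features and coherent/distractor triads."""
    _check_plant_feasible(config)
    truth = SimTruth()
    genes = list(annotation.genes)
    mirnas = list(annotation.mirna_loci["name"])
    rng.shuffle(genes)
    rng.shuffle(mirnas)
    plant_neg_triads(truth, annotation, config, rng, genes, mirnas)

    # extra planted DEGs/DERs beyond the triad features
    extra_degs = config.n_planted_degs - len(truth.de_mrna)
    for i in range(max(0, extra_degs)):
        if not genes:
            break
        g = genes.pop()
        truth.de_mrna[g.gene_id] = "up" if i % 2 == 0 else "down"
    extra_ders = config.n_planted_ders - len(truth.de_mirna)
    for i in range(max(0, extra_ders)):
        if not mirnas:
            break
        truth.de_mirna[mirnas.pop()] = "down" if i % 2 == 0 else "up"

    # remaining planted DMRs go to intergenic space, clear of all gene flanks
    _plant_intergenic_dmrs(truth, annotation, config, rng)
    _validate_disjoint(truth)
    return truth


def plant_neg_triads(truth: SimTruth, annotation: Annotation, config: SimConfig,
                     rng: np.random.Generator,
                     free_genes: list[GeneModel] | None = None,
                     free_mirnas: list[str] | None = None) -> SimTruth:
    """Plant fully-negative triads and single-direction-flipped distractors.

    Each planted triad gets a promoter/body DMR in its gene, a DE direction
    for the gene, and a DE direction for a dedicated targeting miRNA.
    Distractors flip exactly one of the three directions (cycling through
    gene, DMR, miRNA) so that no distractor is fully negative.
    """
    if free_genes is None:
        free_genes = [g for g in annotation.genes
                      if g.gene_id not in truth.de_mrna]
        rng.shuffle(free_genes)
    if free_mirnas is None:
        free_mirnas = [m for m in annotation.mirna_loci["name"]
                       if m not in truth.de_mirna]
        rng.shuffle(free_mirnas)
    n_needed = config.n_planted_neg_triads + config.n_distractor_triads
    if n_needed > len(free_genes) or n_needed > len(free_mirnas):
        raise ConfigurationError(
            f"need {n_needed} unplanted genes and miRNAs for triads; have "
            f"{len(free_genes)} genes, {len(free_mirnas)} miRNAs")

    for i in range(config.n_planted_neg_triads):
        gene, mirna = free_genes.pop(), free_mirnas.pop()
        scheme = PLANT_SCHEMES[i % 2]
        gene_dir, dmr_dir, mirna_dir = _negative_pattern(scheme[0])
        _plant_gene_dmr(truth, gene, scheme, config)
        truth.de_mrna[gene.gene_id] = gene_dir
        truth.de_mirna[mirna] = mirna_dir
        truth.neg_triads.append(
            {"gene_id": gene.gene_id, "dmr_dir": dmr_dir, "mirna_id": mirna})

    flip_cycle = ("gene", "dmr", "mirna")
    for i in range(config.n_distractor_triads):
        gene, mirna = free_genes.pop(), free_mirnas.pop()
        scheme = PLANT_SCHEMES[i % 2]
        gene_dir, dmr_dir, mirna_dir = _negative_pattern(scheme[0])
        flip = flip_cycle[i % 3]
        if flip == "gene":
            gene_dir = "down" if gene_dir == "up" else "up"
        elif flip == "dmr":
            scheme = PLANT_SCHEMES[(i + 1) % 2]
            dmr_dir = scheme[0]
        else:
            mirna_dir = "down" if mirna_dir == "up" else "up"
        _plant_gene_dmr(truth, gene, scheme, config)
        truth.de_mrna[gene.gene_id] = gene_dir
        truth.de_mirna[mirna] = mirna_dir
        truth.distractor_triads.append(
            {"gene_id": gene.gene_id, "dmr_dir": dmr_dir, "mirna_id": mirna,
             "flipped": flip})
    return truth


def _negative_pattern(dmr_dir: str) -> tuple[str, str, str]:
    """The two fully-negative patterns: (up, hypo, down) and (down, hyper, up)."""
    if dmr_dir == "hypo":
        return "up", "hypo", "down"
    return "down", "hyper", "up"


def _plant_gene_dmr(truth: SimTruth, gene: GeneModel, scheme, config: SimConfig) -> None:
    """A planted DMR covering the gene's promoter, aligned to the step grid."""
    direction, ctx, _ = scheme
    step = 500
    if gene.strand == "+":
        start = (max(0, gene.start - config.dmr_length) // step) * step
    else:
        # promoter sits right of the gene end on the minus strand
        start = ((gene.end + step - 1) // step) * step
    truth.dmrs.append({
        "chrom": gene.chrom, "start": int(start),
        "end": int(start + config.dmr_length),
        "context": ctx, "direction": direction, "gene_id": gene.gene_id,
    })


def _plant_intergenic_dmrs(truth: SimTruth, annotation: Annotation,
                           config: SimConfig, rng) -> None:
    n_extra = config.n_planted_dmrs - len(truth.dmrs)
    if n_extra <= 0:
        return
    step = 500
    clearance = config.flank + 2 * step
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in annotation.chrom_lengths}
    for g in annotation.genes:
        occupied[g.chrom].append((g.start - clearance, g.end + clearance))
    for d in truth.dmrs:
        occupied[d["chrom"]].append((d["start"] - 2 * step, d["end"] + 2 * step))
    placed = 0
    chroms = list(annotation.chrom_lengths)
    attempts = 0
    while placed < n_extra and attempts < 10000:
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        ln = annotation.chrom_lengths[chrom]
        start = int(rng.integers(2, max(3, (ln - config.dmr_length) // step))) * step
        end = start + config.dmr_length
        if any(s < end and start < e for s, e in occupied[chrom]):
            continue
        scheme = PLANT_SCHEMES[placed % 2]
        truth.dmrs.append({"chrom": chrom, "start": start, "end": end,
                           "context": scheme[1], "direction": scheme[0]})
        occupied[chrom].append((start - 2 * step, end + 2 * step))
        placed += 1
    if placed < n_extra:
        raise ConfigurationError(
            f"could only place {placed}/{n_extra} intergenic DMRs; genome too dense")


def _validate_disjoint(truth: SimTruth) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for d in truth.dmrs:
        by_chrom.setdefault(d["chrom"], []).append((d["start"], d["end"]))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ConfigurationError(
                    f"planted DMRs overlap on {chrom}: [{s1},{e1}) and [{s2},{e2})")


# ---------------------------------------------------------------------------
# observation models


def simulate_methylation(sites: pd.DataFrame, truth: SimTruth, config: SimConfig,
                         rng: np.random.Generator
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the two cytosine-call tables (treatment A, control B).

    Coverage ~ Poisson(coverage_mean) truncated to >= 1 per site and sample;
    methylated counts ~ Binomial(coverage, level) with the site's latent
    level ~ Beta(mean * c, (1 - mean) * c), c = bb_overdispersion. The
    latent level is shared between conditions except inside planted DMRs of
    the matching context, where the treatment condition draws an independent
    level around baseline +/- dmr_delta.
    """
    n = len(sites)
    ctx = sites["context"].to_numpy()
    mu = np.empty(n)
    for c in CONTEXTS:
        mu[ctx == c] = config.baseline_levels[c]
    shift = np.zeros(n)
    chrom_arr = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    for d in truth.dmrs:
        sign = +1.0 if d["direction"] == "hyper" else -1.0
        mask = ((chrom_arr == d["chrom"]) & (pos >= d["start"]) & (pos < d["end"])
                & (ctx == d["context"]))
        shift[mask] = sign * config.dmr_delta
    mu_treat = mu + shift
    if ((mu_treat < 0) | (mu_treat > 1)).any():
        raise ConfigurationError("baseline +/- dmr_delta falls outside [0, 1]")

    c = config.bb_overdispersion
    eps = 1e-9
    p_shared = rng.beta(np.clip(mu, eps, 1 - eps) * c,
                        np.clip(1 - mu, eps, 1 - eps) * c)
    shifted = shift != 0
    p_treat = p_shared.copy()
    if shifted.any():
        mt = np.clip(mu_treat[shifted], eps, 1 - eps)
        p_treat[shifted] = rng.beta(mt * c, (1 - mt) * c)

    def draw(p):
        cov = np.maximum(rng.poisson(config.coverage_mean, n), 1)
        meth = rng.binomial(cov, p)
        return cov, meth

    cov_a, meth_a = draw(p_treat)
    cov_b, meth_b = draw(p_shared)
    base = sites[["chrom", "pos", "strand", "context"]]
    calls_a = base.assign(meth=meth_a, total=cov_a)
    calls_b = base.assign(meth=meth_b, total=cov_b)
    return calls_a, calls_b


def simulate_counts(feature_ids: list[str], de_map: dict[str, str],
                    config: SimConfig, rng: np.random.Generator,
                    baseline_range: tuple[float, float] = (10.0, 1e4),
                    planted_baseline_range: tuple[float, float] = (1e2, 1e4),
                    ) -> pd.DataFrame:
    """Negative-binomial count matrix, features x (treatment+control reps).

    Baseline means are log-uniform over ``baseline_range``; planted DE
    features draw from ``planted_baseline_range`` (effects are modeled on
    robustly expressed features) and get mean x 2^(+/-de_log2fc) in the
    treatment condition. Library sizes are jittered +/-20% per replicate.
    """
    if config.reps_per_condition < 1:
        raise ConfigurationError("reps_per_condition must be >= 1")
    nfeat = len(feature_ids)
    lo, hi = np.log10(baseline_range[0]), np.log10(baseline_range[1])
    base = 10 ** rng.uniform(lo, hi, nfeat)
    plo, phi = np.log10(planted_baseline_range[0]), np.log10(planted_baseline_range[1])
    fold = np.ones(nfeat)
    for i, fid in enumerate(feature_ids):
        d = de_map.get(fid)
        if d in ("up", "down"):
            base[i] = 10 ** rng.uniform(plo, phi)
            fold[i] = 2.0 ** (config.de_log2fc if d == "up" else -config.de_log2fc)
    reps = config.reps_per_condition
    lib = rng.uniform(0.8, 1.2, 2 * reps)  # per-replicate library factor
    mean = np.empty((nfeat, 2 * reps))
    mean[:, :reps] = (base * fold)[:, None] * lib[:reps]
    mean[:, reps:] = base[:, None] * lib[reps:]
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)
    cols = [f"A_{i+1}" for i in range(reps)] + [f"B_{i+1}" for i in range(reps)]
    return pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"),
                        columns=cols)


def simulate_target_pairs(annotation: Annotation, truth: SimTruth,
                          rng: np.random.Generator,
                          n_decoy_pairs: int = 30) -> pd.DataFrame:
    """miRNA -> gene target table: planted triad pairs plus decoys.

    Decoy pairs join unplanted miRNAs to unplanted genes, so they exercise
    the join logic without adding unintended triads.
    """
    rows = [(t["mirna_id"], t["gene_id"])
            for t in truth.neg_triads + truth.distractor_triads]
    free_genes = [g.gene_id for g in annotation.genes
                  if g.gene_id not in truth.de_mrna]
    free_mirnas = [m for m in annotation.mirna_loci["name"]
                   if m not in truth.de_mirna]
    for _ in range(n_decoy_pairs):
        if not free_genes or not free_mirnas:
            break
        rows.append((
            free_mirnas[int(rng.integers(0, len(free_mirnas)))],
            free_genes[int(rng.integers(0, len(free_genes)))],
        ))
    return pd.DataFrame(sorted(set(rows)), columns=["mirna_id", "gene_id"])


def simulate_term_map(annotation: Annotation, rng: np.random.Generator,
                      n_terms: int = 20) -> pd.DataFrame:
    """Random gene -> term map (1-3 terms per gene)."""
    terms = [f"TERM:{i+1:04d}" for i in range(n_terms)]
    rows = []
    for g in annotation.genes:
        k = int(rng.integers(1, 4))
        for t in rng.choice(terms, size=k, replace=False):
            rows.append((g.gene_id, t))
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


@dataclass
class SimResult:
    config: SimConfig
    annotation: Annotation
    sites: pd.DataFrame
    calls_a: pd.DataFrame
    calls_b: pd.DataFrame
    mirna_counts: pd.DataFrame
    mrna_counts: pd.DataFrame
    target_pairs: pd.DataFrame
    term_map: pd.DataFrame
    truth: SimTruth

    def write_all(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_cytosine_report(self.calls_a, outdir / "treatment.cx.tsv")
        mio.write_cytosine_report(self.calls_b, outdir / "control.cx.tsv")
        mio.write_gff3(self.annotation.genes, outdir / "genes.gff3",
                       self.annotation.chrom_lengths)
        mio.write_bed(self.annotation.mirna_loci, outdir / "mirna_loci.bed")
        mio.write_counts(self.mirna_counts, outdir / "mirna_counts.tsv")
        mio.write_counts(self.mrna_counts, outdir / "mrna_counts.tsv")
        mio.write_table(self.target_pairs, outdir / "target_pairs.tsv")
        mio.write_table(self.term_map, outdir / "term_map.tsv")
        self.truth.to_json(outdir / "truth.json")
        with open(outdir / "chrom_lengths.json", "w") as fh:
            json.dump(self.annotation.chrom_lengths, fh)


def simulate_all(config: SimConfig) -> SimResult:
    """Run the whole generator under one seed."""
    rng = np.random.default_rng(config.seed)
    annotation, sites = simulate_genome(config, rng)
    truth = plant_truth(annotation, config, rng)
    calls_a, calls_b = simulate_methylation(sites, truth, config, rng)
    mirna_counts = simulate_counts(
        list(annotation.mirna_loci["name"]), truth.de_mirna, config, rng)
    mrna_counts = simulate_counts(
        [g.gene_id for g in annotation.genes], truth.de_mrna, config, rng)
    target_pairs = simulate_target_pairs(annotation, truth, rng)
    term_map = simulate_term_map(annotation, rng)
    return SimResult(config, annotation, sites, calls_a, calls_b,
                     mirna_counts, mrna_counts, target_pairs, term_map, truth)
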