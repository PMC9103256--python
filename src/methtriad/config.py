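"""Pipeline and simulation configuration.

Defaults follow the analysis protocol: 1 kb windows sliding by 500 bp, pooled
per-sample window coverage of at least 30 reads, a methylation-level difference
of more than 15 percentage points, a fold change above 2 or below 0.5, and
p and BH-adjusted q both below 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .models import CONTEXTS


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class PipelineConfig:
    window_size: int = 1000          # bp
    step_size: int = 500             # bp
    min_window_coverage: int = 30    # pooled reads per sample per window
    min_level_diff: float = 15.0     # percentage points, strict >
    fc_bounds: tuple[float, float] = (2.0, 0.5)
    alpha_p: float = 0.05
    alpha_q: float = 0.05
    deg_min_abs_log2fc: float = 1.0
    deg_log2fc_inclusive: bool = False  # default strict, |log2FC| > 1
    flank: int = 2000                # bp, promoter/downstream span
    level_filter: str = "difference"  # or "ratio": alternative reading of ">15"
    fc_floor: float = 0.005          # floor on denominator level for fold change
    min_meth_reads: int = 1          # mC site rule: meth_count >= this
    mc_binomial_rule: bool = False   # optionally also require a binomial test
    mc_error_rate: float = 0.005     # assumed conversion-error rate for that test
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.window_size >= self.step_size > 0):
            raise ConfigurationError("require window_size >= step_size > 0")
        if not (0 < self.alpha_p <= 1 and 0 < self.alpha_q <= 1):
            raise ConfigurationError("alpha_p and alpha_q must lie in (0, 1]")
        hi, lo = self.fc_bounds
        if not (hi > 1 > lo > 0):
            raise ConfigurationError("require fc_bounds[0] > 1 > fc_bounds[1] > 0")
        if self.level_filter not in ("difference", "ratio"):
            raise ConfigurationError("level_filter must be 'difference' or 'ratio'")
        if self.flank <= 0 or self.min_window_coverage < 0:
            raise ConfigurationError("flank must be > 0 and coverage >= 0")


@dataclass
class SimConfig:
    """Conditions for the synthetic two-condition tri-omics dataset.

    The generator emulates one pooled bisulfite sample per condition (no
    methylation replicates) and 3 expression replicates per condition.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 1_000_000       # bp
    n_genes: int = 120               # total, split across chromosomes
    n_mirna_loci: int = 40
    cytosine_density: dict = field(
        default_factory=lambda: {"CG": 0.02, "CHG": 0.015, "CHH": 0.045}
    )
    coverage_mean: float = 40.0      # Poisson mean, truncated >= 1
    baseline_levels: dict = field(
        default_factory=lambda: {"CG": 0.65, "CHG": 0.35, "CHH": 0.10}
    )
    bb_overdispersion: float = 30.0  # beta concentration; larger -> binomial limit
    n_planted_dmrs: int = 20
    dmr_length: int = 2000           # bp, grid-aligned to step_size
    dmr_delta: float = 0.4           # methylation-level shift inside planted DMRs
    nb_dispersion: float = 0.05      # NB: var = mu + disp * mu^2
    n_planted_degs: int = 20
    n_planted_ders: int = 12
    de_log2fc: float = 2.0
    n_planted_neg_triads: int = 5
    n_distractor_triads: int = 5
    reps_per_condition: int = 3
    flank: int = 2000                # intergenic margin kept around genes

    def __post_init__(self) -> None:
        ints = (
            self.n_chroms, self.chrom_len, self.n_genes, self.n_mirna_loci,
            self.n_planted_dmrs, self.n_planted_degs, self.n_planted_ders,
            self.n_planted_neg_triads, self.n_distractor_triads,
        )
        if any(v < 0 for v in ints):
            raise ConfigurationError("counts must be >= 0")
        if self.n_chroms == 0 or self.chrom_len <= 0:
            raise ConfigurationError("need at least one chromosome of positive length")
        if self.reps_per_condition < 1:
            raise ConfigurationError("reps_per_condition must be >= 1")
        for ctx in CONTEXTS:
            lvl = self.baseline_levels.get(ctx)
            if lvl is None or not (0.0 <= lvl <= 1.0):
                raise ConfigurationError(f"baseline level for {ctx} must be in [0,1]")
            dens = self.cytosine_density.get(ctx)
            if dens is None or not (0.0 <= dens <= 1.0):
                raise ConfigurationError(f"cytosine density for {ctx} must be in [0,1]")
        if sum(self.cytosine_density.values()) > 1.0:
            raise ConfigurationError("total cytosine density exceeds 1")
        if not (0.0 <= self.dmr_delta <= 1.0):
            raise ConfigurationError("dmr_delta must be in [0,1]")
        if self.bb_overdispersion <= 0 or self.nb_dispersion < 0:
            raise ConfigurationError("dispersion parameters must be positive")


def load_config(path: str | Path) -> tuple[PipelineConfig, SimConfig]:
    """Read a YAML file with optional ``pipeline:`` and ``simulation:`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pipe = raw.get("pipeline", {})
    if "fc_bounds" in pipe:
        pipe["fc_bounds"] = tuple(pipe["fc_bounds"])
    return PipelineConfig(**pipe), SimConfig(**raw.get("simulation", {}))


def dump_config(pipeline: PipelineConfig, sim: SimConfig, path: str | Path) -> None:
    data = {"pipeline": asdict(pipeline), "simulation": asdict(sim)}
    data["pipeline"]["fc_bounds"] = list(pipeline.fc_bounds)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
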