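"""End-to-end orchestration: counts in, ranked OTU-MGS links out.

Stages run in a fixed order — downsample shotgun counts, RPKM+TC normalize,
build MGS tracer profiles, prevalence-filter both tables, ratio+log normalize
both, cross-correlate, report best/second hits — and every stage's input and
output dimensions are logged into a machine-readable report.  Identical
configuration and seed reproduce identical output byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal

import yaml

from . import gene_abundance, io_formats, linking, mgs_profiling
from .errors import ValidationError
from .io_formats import CountMatrix, GeneLengthTable, MgsMembership
from .linking import LinkResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run; defaults are the method's defaults."""

    gene_counts: str | None = None  # TSV paths; may be supplied in memory instead
    gene_lengths: str | None = None
    membership: str | None = None
    otu_table: str | None = None  # QIIME classic OTU table
    target_depth: int | None = gene_abundance.DEFAULT_TARGET_DEPTH  # None skips
    on_shallow: str = "error"
    k_tracers: int = mgs_profiling.DEFAULT_N_TRACERS
    rho_threshold: float = mgs_profiling.DEFAULT_RHO_THRESHOLD
    pseudocount: float = linking.DEFAULT_PSEUDOCOUNT
    min_prevalence: int = linking.DEFAULT_MIN_PREVALENCE
    cutoff: float = linking.DEFAULT_CUTOFF
    direction: Literal["otu", "mgs"] = "otu"  # which table supplies the queries
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho_threshold <= 1):
            raise ValidationError("rho_threshold must lie in [0, 1]")
        if not (-1 <= self.cutoff <= 1.5):
            raise ValidationError("cutoff out of range")
        if self.k_tracers < 1:
            raise ValidationError("k_tracers must be >= 1")
        if self.min_prevalence < 0:
            raise ValidationError("min_prevalence must be >= 0")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if self.direction not in ("otu", "mgs"):
            raise ValidationError("direction must be 'otu' or 'mgs'")

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict[str, Any] | None = None):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if overrides:
            raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    links: list[LinkResult]
    report: dict[str, Any]
    mgs_profiles: Any  # MGS x samples DataFrame (mean tracer vectors)
    models: list[mgs_profiling.MgsModel]


def run_pipeline_from_matrices(
    gene_counts: CountMatrix,
    gene_lengths: GeneLengthTable,
    membership: MgsMembership,
    otu_counts: CountMatrix,
    config: RunConfig,
) -> PipelineResult:
    """Run the full linking pipeline on in-memory inputs."""
    report: dict[str, Any] = {"config": config.to_dict(), "stages": {}}

    def log_stage(name: str, **info: Any) -> None:
        report["stages"][name] = info
        logger.info("stage %s: %s", name, info)

    if set(gene_counts.sample_ids) != set(otu_counts.sample_ids):
        raise ValidationError(
            "sample ids differ between the gene and OTU tables; "
            f"gene-only: {sorted(set(gene_counts.sample_ids) - set(otu_counts.sample_ids))[:3]}, "
            f"otu-only: {sorted(set(otu_counts.sample_ids) - set(gene_counts.sample_ids))[:3]}"
        )
    otu_counts = CountMatrix(otu_counts.data.reindex(columns=gene_counts.data.columns))

    if config.target_depth is not None:
        gene_counts = gene_abundance.downsample_counts(
            gene_counts, config.target_depth, config.seed, config.on_shallow
        )
        log_stage("downsample", target_depth=config.target_depth,
                  shape=gene_counts.shape)
        # a dropped shallow sample must disappear from the OTU table too
        otu_counts = CountMatrix(otu_counts.data[gene_counts.data.columns])

    abundance, zero_samples = gene_abundance.normalize_rpkm_tc(gene_counts, gene_lengths)
    log_stage("normalize_rpkm_tc", shape=abundance.data.shape,
              zero_samples=zero_samples)

    models = mgs_profiling.build_mgs_models(
        abundance.data, membership, k=config.k_tracers,
        rho_threshold=config.rho_threshold,
    )
    mgs_profiles = mgs_profiling.mgs_abundance(abundance.data, models)
    log_stage("mgs_profiles", n_mgs=len(models), shape=mgs_profiles.shape)

    mgs_filtered, mgs_dropped = linking.prevalence_filter(
        mgs_profiles, config.min_prevalence
    )
    otu_filtered, otu_dropped = linking.prevalence_filter(
        otu_counts, config.min_prevalence
    )
    log_stage("prevalence_filter", min_prevalence=config.min_prevalence,
              mgs_kept=mgs_filtered.shape[0], mgs_dropped=mgs_dropped,
              otu_kept=otu_filtered.data.shape[0], otu_dropped=otu_dropped)
    if mgs_filtered.shape[0] == 0 or otu_filtered.data.shape[0] == 0:
        raise ValidationError("prevalence filter removed every row of one table")

    mgs_log = linking.normalize_profiles(mgs_filtered, config.pseudocount)
    otu_log = linking.normalize_profiles(otu_filtered, config.pseudocount)
    log_stage("normalize_profiles", pseudocount=config.pseudocount)

    if config.direction == "otu":
        corr = linking.pearson_cross(otu_log, mgs_log)
    else:
        corr = linking.pearson_cross(mgs_log, otu_log)
    links = linking.best_hits(corr, cutoff=config.cutoff)
    n_passing = sum(1 for l in links if l.passes_cutoff)
    log_stage("best_hits", cutoff=config.cutoff, n_queries=len(links),
              n_passing=n_passing)
    report["n_links"] = len(links)
    report["n_passing"] = n_passing
    return PipelineResult(links, report, mgs_profiles, models)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Load the configured inputs, run the pipeline, write the outputs.

    ``out_dir`` must not exist yet: every run writes to a fresh directory with
    the resolved configuration echoed alongside the results, and no stage
    mutates its input files.
    """
    out_dir = Path(out_dir)
    if out_dir.exists():
        raise ValidationError(f"output directory already exists: {out_dir}")
    for name in ("gene_counts", "gene_lengths", "membership", "otu_table"):
        if getattr(config, name) is None:
            raise ValidationError(f"config is missing required input path: {name}")

    gene_counts = io_formats.read_count_matrix(config.gene_counts)
    gene_lengths = io_formats.read_gene_lengths(config.gene_lengths)
    membership = io_formats.read_membership(config.membership)
    otu_table = io_formats.read_qiime_otu_table(config.otu_table)

    result = run_pipeline_from_matrices(
        gene_counts, gene_lengths, membership, otu_table.counts, config
    )

    out_dir.mkdir(parents=True)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    linking.write_links(result.links, out_dir / "links.tsv")
    io_formats.write_matrix(result.mgs_profiles, out_dir / "mgs_profiles.tsv",
                            index_label="mgs_id")
    (out_dir / "report.yaml").write_text(yaml.safe_dump(result.report, sort_keys=True))
    return result
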