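"""End-to-end screen analysis: normalize, QC, epsilon scores, RSA hits.

This module glues the stages together behind one call, used both by the
command-line interface and programmatically. All stage outputs are plain
tab-delimited text so runs are diffable and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import interaction, model, normalize, rsa
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Options of one analysis run (defaults follow the screen protocol)."""

    library_path: str | Path | None = None
    measurements_path: str | Path | None = None
    output_dir: str | Path = "."
    negative_roles: tuple[str, ...] = model.NEGATIVE_CONTROLS
    cytotoxicity_threshold: float = 0.20
    v_b_mode: str = "estimated"          # "estimated" | "constant"
    v_b_constant: float | None = None
    aggregation: str = "mean"            # "mean" | "median"
    rsa_cutoff: float = 0.05
    normalization_dialect: str = "proficient"  # shared scale for epsilon

    def __post_init__(self) -> None:
        if not 0 < self.cytotoxicity_threshold < 1:
            raise ConfigurationError("cytotoxicity_threshold must be in (0, 1)")
        if not 0 < self.rsa_cutoff <= 1:
            raise ConfigurationError("rsa_cutoff must be in (0, 1]")
        if self.v_b_mode not in ("estimated", "constant"):
            raise ConfigurationError(f"unknown v_b_mode {self.v_b_mode!r}")
        if self.v_b_mode == "constant" and self.v_b_constant is None:
            raise ConfigurationError("v_b_mode=constant needs v_b_constant")
        if self.normalization_dialect not in ("proficient", "within"):
            raise ConfigurationError(
                f"unknown normalization_dialect {self.normalization_dialect!r}"
            )


@dataclass
class ScreenResults:
    """In-memory results of one full analysis."""

    normalized: pd.DataFrame
    qc: normalize.QCReport
    epsilon: pd.DataFrame
    ranked: pd.DataFrame
    hits: pd.DataFrame
    v_b_by_rep: dict = field(default_factory=dict)


def analyze_screen(
    measurements: pd.DataFrame,
    library: model.SiRNALibrary,
    config: PipelineConfig | None = None,
) -> ScreenResults:
    """Run normalization, QC, epsilon scoring, and RSA hit calling."""
    cfg = config or PipelineConfig()

    # QC always uses the within-plate scale (control medians forced to 1)
    norm_within = normalize.normalize_screen(
        measurements, cfg.negative_roles, reference="within"
    )
    gene_map = dict(zip(library.entries["sirna_id"], library.entries["gene"]))
    norm_within["gene"] = norm_within["content"].map(gene_map)
    qc = normalize.qc_report(
        norm_within, cfg.negative_roles, cfg.cytotoxicity_threshold
    )
    if qc.excluded_genes:
        logger.info(
            "cytotoxicity filter excluded %d gene(s): %s",
            len(qc.excluded_genes), sorted(qc.excluded_genes),
        )

    # epsilon needs both arms on the shared (query-proficient) scale
    norm_eps = (
        norm_within
        if cfg.normalization_dialect == "within"
        else normalize.normalize_screen(
            measurements, cfg.negative_roles, reference="proficient"
        )
    )
    v_b = cfg.v_b_constant if cfg.v_b_mode == "constant" else None
    eps = interaction.epsilon_table(
        norm_eps, library, v_b=v_b,
        negative_roles=cfg.negative_roles, aggregation=cfg.aggregation,
    )
    per_rep = eps[eps["bio_rep"] != "aggregate"]
    v_b_by_rep = (
        per_rep.groupby("bio_rep")["v_b"].first().to_dict() if len(per_rep) else {}
    )

    agg = eps[eps["bio_rep"] == "aggregate"]
    agg = agg[~agg["gene"].isin(qc.excluded_genes)]
    ranked = rsa.rank_sirnas(agg)
    hits = rsa.call_hits(rsa.score_genes(ranked), cfg.rsa_cutoff)
    return ScreenResults(norm_within, qc, eps, ranked, hits, v_b_by_rep)


def run_screen_analysis(config: PipelineConfig) -> ScreenResults:
    """File-to-file pipeline: read inputs, analyze, write every artifact.

    Writes into ``config.output_dir``: normalized.tsv, qc_ssmd.tsv,
    qc_correlations.tsv, excluded_genes.txt, epsilon.tsv, ranked.tsv,
    hits.tsv and run_log.txt (all parameters of the run).
    """
    if config.library_path is None or config.measurements_path is None:
        raise ConfigurationError("library_path and measurements_path are required")
    library = model.load_library(config.library_path)
    design = model.ScreenDesign(library)
    measurements = model.load_measurements(config.measurements_path, design)

    results = analyze_screen(measurements, library, config)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.normalized.to_csv(outdir / "normalized.tsv", sep="\t", index=False)
    results.qc.plate_ssmd.to_csv(outdir / "qc_ssmd.tsv", sep="\t", index=False)
    results.qc.replicate_correlations.to_csv(
        outdir / "qc_correlations.tsv", sep="\t", index=False
    )
    (outdir / "excluded_genes.txt").write_text(
        "\n".join(sorted(results.qc.excluded_genes)) + "\n"
        if results.qc.excluded_genes else ""
    )
    interaction.write_epsilon_table(results.epsilon, outdir / "epsilon.tsv")
    results.ranked.to_csv(outdir / "ranked.tsv", sep="\t", index=False)
    model.write_hit_table(results.hits, outdir / "hits.tsv")

    log_lines = [f"{k} = {v}" for k, v in asdict(config).items()]
    log_lines += [
        f"n_measurements = {len(measurements)}",
        f"n_ranked_sirnas = {len(results.ranked)}",
        f"n_excluded_genes = {len(results.qc.excluded_genes)}",
        f"n_hits = {int(results.hits['is_hit'].sum())}",
        f"v_b_by_rep = {results.v_b_by_rep}",
    ]
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    logger.info("analysis complete: %d hits", int(results.hits["is_hit"].sum()))
    return results
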