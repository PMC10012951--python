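"""End-to-end orchestration: simulate → filter → whitelist → repair →
quantify → barnyard/profiles → report.

A single seed governs the whole run; each stage draws from its own
generator derived from that seed by a fixed index, so stages are
independently reproducible and the full run is deterministic — two runs
with the same configuration produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .barcodes import (
    RepairSummary,
    Whitelist,
    barcode_stats,
    build_whitelist,
    candidate_barcodes,
    repair_barcodes,
)
from .barnyard import (
    DoubletEstimate,
    SpeciesCallSet,
    classify_species,
    estimate_doublet_rate,
)
from .profiles import RegionSummary, region_fractions
from .quantify import ExpressionMatrix, apply_barcode_filters, count_molecules
from .readio import RejectReason, filter_fastq
from .simdrops import SimulationParams, gene_panels, simulate_encapsulation, synthesize_reads

logger = logging.getLogger("droncqc")

#: fixed stage indices for seed derivation (SeedSequence([seed, index]))
STAGE_ENCAPSULATE = 0
STAGE_READS = 1


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters for one pipeline run.

    Defaults equal the protocol's stated values: 150-gene candidate
    floor, H2 repair (max Hamming distance 2), min 1 read per gene and
    min 200 genes per nucleus, 95% species threshold, 5% occupancy and a
    1:1 species mix (the latter two via ``sim``).
    """

    sim: SimulationParams = field(default_factory=SimulationParams)
    min_genes_candidates: int = 150
    ranking_mode: str = "by_genes"
    n_expected: int | None = None  # default: round(n_droplets * occupancy)
    max_distance: int = 2
    min_reads_per_gene: int = 1
    min_genes_per_barcode: int = 200
    species_threshold: float = 0.95
    classify_unit: str = "transcripts"
    write_fastq: bool = False
    out_dir: str | None = None

    @property
    def seed(self) -> int:
        return self.sim.seed

    def resolved_n_expected(self) -> int:
        if self.n_expected is not None:
            return self.n_expected
        return max(1, round(self.sim.n_droplets * self.sim.occupancy))

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["sim"]["species_proportions"] = list(self.sim.species_proportions)
        payload["sim"]["region_probs"] = list(self.sim.region_probs)
        payload["n_expected_resolved"] = self.resolved_n_expected()
        return payload

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat-keys config file; unknown keys raise."""
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        payload.update(overrides)
        payload.pop("n_expected_resolved", None)
        sim_payload = payload.pop("sim", {})
        if "species_proportions" in sim_payload:
            sim_payload["species_proportions"] = tuple(
                sim_payload["species_proportions"]
            )
        if "region_probs" in sim_payload:
            sim_payload["region_probs"] = tuple(sim_payload["region_probs"])
        return cls(sim=SimulationParams(**sim_payload), **payload)


@dataclass
class PipelineResult:
    """All in-memory artifacts of one run; ``report`` is the serializable summary."""

    config: PipelineConfig
    droplets: pd.DataFrame
    reads: pd.DataFrame
    whitelist: Whitelist
    repair_summary: RepairSummary
    matrix: ExpressionMatrix
    matrix_filtered: ExpressionMatrix
    calls: SpeciesCallSet | None
    estimate: DoubletEstimate | None
    regions: RegionSummary
    report: dict

    def scatter_table(self) -> pd.DataFrame:
        """Per-barcode (n_human, n_murine, label) for barnyard-style plotting."""
        if self.calls is None:
            raise ValueError("no species calls in this run")
        return self.calls.calls[["barcode", "n_human", "n_murine", "label"]].copy()


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full synthetic pipeline and assemble the run report.

    Stages: droplet encapsulation, read synthesis (optionally round-
    tripped through FASTQ and the structural read filter), per-barcode
    stats, candidate selection, whitelisting, Hamming repair, UMI
    quantification, barcode filters, species classification + doublet
    estimate (skipped for single-species runs), region fractions.  All
    counts in the report satisfy the conservation identities of their
    stages.  When ``config.out_dir`` is set, artifacts are written there
    (report.json, whitelist, repair map, MatrixMarket triplet, species
    calls, scatter table, config echo).
    """
    sim = config.sim
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("[simulate] encapsulating %d droplets", sim.n_droplets)
    droplets = simulate_encapsulation(sim, _stage_rng(sim.seed, STAGE_ENCAPSULATE))
    fastq_prefix = (
        out_dir / "reads" if (config.write_fastq and out_dir is not None) else None
    )
    reads, fastq_paths = synthesize_reads(
        droplets, sim, _stage_rng(sim.seed, STAGE_READS), fastq_prefix=fastq_prefix
    )
    logger.info("[simulate] %d reads from %d occupied droplets",
                len(reads), int((droplets["nucleus_count"] > 0).sum()))

    if fastq_paths is not None:
        result = filter_fastq(
            fastq_paths[0],
            fastq_paths[1],
            out_dir / "filtered_R1.fastq.gz",
            out_dir / "filtered_R2.fastq.gz",
        )
        read_filter = result.to_dict()
    else:
        # synthesized reads are structurally valid by construction
        # (ACGT barcodes, A/C/G anchor, intact poly-T tail)
        read_filter = {
            "kept": len(reads),
            "rejected": {reason.value: 0 for reason in RejectReason},
            "total": len(reads),
        }

    logger.info("[barcodes] tallying per-barcode stats")
    stats = barcode_stats(reads, min_reads_per_gene=config.min_reads_per_gene)
    candidates = candidate_barcodes(
        stats, min_genes=config.min_genes_candidates, mode=config.ranking_mode
    )
    n_expected = config.resolved_n_expected()
    whitelist = build_whitelist(candidates, n_expected, mode=config.ranking_mode)
    whitelist, repair_summary = repair_barcodes(
        stats["barcode"].astype(str), whitelist, max_distance=config.max_distance
    )
    logger.info(
        "[barcodes] %d candidates, %d whitelisted, %d repaired, %d unassigned",
        len(candidates), len(whitelist), repair_summary.n_repaired,
        repair_summary.n_unassigned,
    )

    human_panel, murine_panel = gene_panels(sim)
    matrix = count_molecules(reads, whitelist, genes=human_panel + murine_panel)
    matrix_filtered = apply_barcode_filters(
        matrix,
        min_reads_per_gene=config.min_reads_per_gene,
        min_genes_per_barcode=config.min_genes_per_barcode,
    )
    logger.info(
        "[quantify] %d -> %d barcodes after filters, %d UMIs",
        len(matrix.barcodes), len(matrix_filtered.barcodes),
        matrix_filtered.total_umis(),
    )

    p_human, p_murine = sim.species_proportions
    two_species = p_human > 0 and p_murine > 0
    calls = estimate = None
    if two_species:
        kept_barcodes = matrix_filtered.barcodes
        matrix_h = count_molecules(
            reads[reads["genome"] == "human"], whitelist, genes=human_panel
        ).subset_barcodes(kept_barcodes)
        matrix_m = count_molecules(
            reads[reads["genome"] == "murine"], whitelist, genes=murine_panel
        ).subset_barcodes(kept_barcodes)
        calls = classify_species(
            matrix_h,
            matrix_m,
            threshold=config.species_threshold,
            unit=config.classify_unit,
        )
        estimate = estimate_doublet_rate(calls, sim.species_proportions)
        logger.info(
            "[barnyard] %d classified, %d mixed, corrected doublet rate %.2f%%",
            estimate.n_total, estimate.n_mixed, estimate.percent,
        )

    regions = region_fractions(reads)
    truth = _truth_block(droplets, calls)

    report = {
        "software": {"name": "droncqc", "version": __version__},
        "seed": sim.seed,
        "config": config.to_dict(),
        "simulate": {
            "n_droplets": int(len(droplets)),
            "n_occupied": int((droplets["nucleus_count"] > 0).sum()),
            "n_nuclei": int(droplets["nucleus_count"].sum()),
            "n_doublets": int(droplets["is_doublet"].sum()),
            "n_cross_species": int(droplets["is_cross_species"].sum()),
        },
        "read_filter": read_filter,
        "whitelist": {
            "n_barcodes_observed": int(len(stats)),
            "n_candidates": int(len(candidates)),
            "n_expected": n_expected,
            "n_entries": len(whitelist),
            "ranking_mode": config.ranking_mode,
        },
        "repair": repair_summary.to_dict(),
        "quantify": {
            "n_barcodes_pre_filter": len(matrix.barcodes),
            "n_barcodes_post_filter": len(matrix_filtered.barcodes),
            "total_umis": matrix.total_umis(),
            "total_reads": int(
                matrix.per_gene_reads.sum()
                if matrix.per_gene_reads is not None
                else 0
            ),
        },
        "species": (
            None
            if calls is None
            else {
                "labels": calls.label_counts(),
                "n_excluded_zero": calls.n_excluded_zero,
                "threshold": calls.threshold,
                "unit": calls.unit,
            }
        ),
        "doublets": None if estimate is None else estimate.to_dict(),
        "regions": regions.to_dict(),
        "truth": truth,
    }

    result = PipelineResult(
        config=config,
        droplets=droplets,
        reads=reads,
        whitelist=whitelist,
        repair_summary=repair_summary,
        matrix=matrix,
        matrix_filtered=matrix_filtered,
        calls=calls,
        estimate=estimate,
        regions=regions,
        report=report,
    )
    if out_dir is not None:
        _write_artifacts(result, out_dir)
    return result


def _truth_block(droplets: pd.DataFrame, calls: SpeciesCallSet | None) -> dict:
    """Ground-truth doublet fractions, overall and among classified barcodes."""
    occupied = droplets[droplets["nucleus_count"] > 0]
    block = {
        "doublet_fraction_among_occupied": (
            float(occupied["is_doublet"].mean()) if len(occupied) else 0.0
        ),
        "cross_species_fraction_among_occupied": (
            float(occupied["is_cross_species"].mean()) if len(occupied) else 0.0
        ),
    }
    if calls is not None:
        truth = occupied.set_index("barcode")
        classified = calls.calls["barcode"]
        matched = classified[classified.isin(truth.index)]
        block["n_classified_matched_to_truth"] = int(len(matched))
        if len(matched):
            sub = truth.loc[matched]
            block["doublet_fraction_among_classified"] = float(
                sub["is_doublet"].mean()
            )
            block["cross_species_fraction_among_classified"] = float(
                sub["is_cross_species"].mean()
            )
    return block


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    result.config.sim.to_yaml(out_dir / "config.yaml")
    result.whitelist.write(out_dir / "whitelist.txt")
    result.whitelist.write_repair_map(out_dir / "repair_map.tsv")
    result.matrix_filtered.save_mtx(out_dir / "matrix_filtered")
    if result.calls is not None:
        result.calls.calls.to_csv(out_dir / "species_calls.tsv", sep="\t", index=False)
        result.scatter_table().to_csv(out_dir / "scatter.tsv", sep="\t", index=False)
    write_report(result.report, out_dir / "report.json")


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a run report deterministically (sorted keys, 2-space indent)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def barnyard_experiment(config: PipelineConfig) -> PipelineResult:
    """Run the two-species mixing experiment end to end.

    Requires both species proportions to be positive; returns the full
    :class:`PipelineResult`, whose ``estimate`` holds the corrected
    doublet rate and whose :meth:`PipelineResult.scatter_table` gives the
    per-barcode (n_human, n_murine, label) scatter data.
    """
    p, q = config.sim.species_proportions
    if p == 0 or q == 0:
        raise ValueError(
            "barnyard_experiment requires a two-species mix; "
            f"got proportions {(p, q)}"
        )
    return run_pipeline(config)
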