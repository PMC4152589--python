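"""End-to-end orchestration from a single YAML config.

Runs the post-alignment stages in order — filter, dedup + complexity,
coverage tracks, then either broad-domain fold-change filtering or the
punctate pseudoreplicate/IDR bookkeeping, peak-to-gene assignment, GO
enrichment, and duplicate diagnostics — writing per-stage TSV summaries
and a machine-readable manifest.  Peak calls (and IDR values for the
punctate profile) are inputs: peak calling and IDR estimation are
external to this package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from peakforge import (
    dup_diagnostics,
    genomic_io,
    go_enrichment,
    peak_tools,
    read_filtering,
    reproducibility,
    signal_tracks,
)

log = logging.getLogger("peakforge")


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration (see README for the YAML layout)."""

    output_dir: Path
    mode: str = "se"  # se | pe
    profile: str = "punctate"  # punctate | broad
    seed: int = 42
    samples: list[dict[str, Any]] = field(default_factory=list)
    peaks: dict[str, str] = field(default_factory=dict)
    genes: str | None = None
    terms: str | None = None
    chrom_sizes: str | None = None
    filter: dict[str, Any] = field(default_factory=dict)
    tracks: dict[str, Any] = field(default_factory=dict)
    assignment: dict[str, Any] = field(default_factory=dict)
    go: dict[str, Any] = field(default_factory=dict)
    idr: dict[str, Any] = field(default_factory=dict)
    domains: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("se", "pe"):
            raise ValueError(f"mode must be se or pe, got {self.mode!r}")
        if self.profile not in ("punctate", "broad"):
            raise ValueError(f"profile must be punctate or broad")
        if not any(s.get("role") == "IP" for s in self.samples):
            raise ValueError("config needs at least one IP sample")
        if self.profile == "broad" and self.idr.get("annotated_peaks"):
            raise ValueError("broad profile forbids the IDR stage")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _load_records(sam_path: str, mode: str):
    reads = [r for r in genomic_io.read_sam(sam_path) if not r.is_unmapped]
    if mode == "pe":
        return genomic_io.pair_reads(reads)
    return reads


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all configured stages; returns the report directory."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"stages": [], "outputs": {}}

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    genome = (
        genomic_io.read_chrom_sizes(config.chrom_sizes)
        if config.chrom_sizes
        else genomic_io.sam_genome_table(config.samples[0]["sam"])
    )
    fcfg = read_filtering.FilterConfig(**config.filter)

    # --- filter + dedup + complexity ------------------------------------
    stage("filter")
    complexity_rows = []
    filtered: dict[str, list] = {}
    for sample in config.samples:
        lib = sample["library"]
        records = _load_records(sample["sam"], config.mode)
        if config.mode == "pe":
            kept, report = read_filtering.filter_paired_end(records, fcfg)
        else:
            kept, report = read_filtering.filter_single_end(records, fcfg)
        filtered[lib] = kept
        row = {"library": lib, "role": sample.get("role", "IP")}
        if report is not None:
            row.update(
                total_unique_mapped=report.total_unique_mapped,
                after_dedup=report.after_dedup,
                complexity=round(report.complexity, 4),
                duplicate_pct=round(report.duplicate_pct, 2),
                meets_guideline=report.guideline_flag,
            )
        complexity_rows.append(row)
    stage("complexity")
    complexity_path = out / "complexity.tsv"
    pd.DataFrame(complexity_rows).to_csv(complexity_path, sep="\t", index=False)
    manifest["outputs"]["complexity"] = str(complexity_path)

    # --- coverage tracks -------------------------------------------------
    stage("tracks")
    tcfg = config.tracks
    for lib, records in filtered.items():
        track = signal_tracks.track_from_records(
            records,
            genome,
            fragment_length=tcfg.get("fragment_length", 200),
            step=tcfg.get("step", 20),
            normalize=tcfg.get("normalize", True),
        )
        for fmt, suffix in (("bedgraph", "bedgraph"), ("wig", "wig")):
            path = out / f"{lib}.{suffix}"
            signal_tracks.write_track(track, path, format=fmt)
            manifest["outputs"][f"track_{lib}_{fmt}"] = str(path)

    # --- peak stage ------------------------------------------------------
    primary_peaks: list = []
    if config.profile == "broad":
        stage("fold_change_filter")
        islands = genomic_io.read_peaks(config.peaks["islands"], "sicer_summary")
        threshold = config.domains.get("min_fold_change", 2.0)
        primary_peaks = peak_tools.fold_change_filter(islands, threshold)
        path = out / "domains_filtered.bed"
        genomic_io.write_peaks(primary_peaks, path, dialect="bed")
        manifest["outputs"]["filtered_domains"] = str(path)
        manifest["outputs"]["n_domains_in"] = len(islands)
        manifest["outputs"]["n_domains_kept"] = len(primary_peaks)
    else:
        stage("idr_bookkeeping")
        cutoff = config.idr.get("cutoff", reproducibility.DEFAULT_IDR_CUTOFF)
        annotated = {
            key: genomic_io.read_peaks(path, "encodePeak")
            for key, path in config.idr.get("annotated_peaks", {}).items()
        }
        required = {"true_replicates", "merged_pseudo", "self_1", "self_2"}
        if annotated and required <= set(annotated):
            counts = {
                key: reproducibility.count_consistent(peaks, cutoff)
                for key, peaks in annotated.items()
            }
            report = reproducibility.assess_reproducibility(
                counts["true_replicates"],
                counts["merged_pseudo"],
                counts["self_1"],
                counts["self_2"],
            )
            curve_rows = []
            for c in reproducibility.IDR_CUTOFF_GRID:
                row = {"cutoff": c}
                for key, peaks in annotated.items():
                    row[key] = reproducibility.count_consistent(peaks, c)
                curve_rows.append(row)
            repro_path = out / "repro.tsv"
            pd.DataFrame(curve_rows).to_csv(repro_path, sep="\t", index=False)
            summary = {
                "n_true": report.n_true,
                "n_merged_pseudo": report.n_merged_pseudo,
                "n_self_1": report.n_self_1,
                "n_self_2": report.n_self_2,
                "rescue_ratio": report.rescue_ratio_rounded,
                "self_ratio": report.self_ratio_rounded,
                "pass": report.passed,
                "conservative_n": report.conservative_n,
                "optimal_n": report.optimal_n,
            }
            manifest["outputs"]["repro_table"] = str(repro_path)
            manifest["outputs"]["reproducibility"] = summary
        if "primary" in config.peaks:
            primary_peaks = genomic_io.read_peaks(config.peaks["primary"], "encodePeak")

    # --- annotation ------------------------------------------------------
    if primary_peaks and config.genes:
        stage("assign_genes")
        genes = peak_tools.read_genes(config.genes)
        records = peak_tools.assign_peaks_to_genes(
            primary_peaks,
            genes,
            max_distance=config.assignment.get("max_distance", 10_000),
        )
        path = out / "peak_vs_gene.tsv"
        pd.DataFrame(
            [
                {
                    "peak_chrom": r.peak_chrom,
                    "peak_start": r.peak_start,
                    "peak_end": r.peak_end,
                    "peak_name": r.peak_name,
                    "gene_id": r.gene_id,
                    "anchor": r.anchor,
                    "distance": r.distance,
                    "is_closest": r.is_closest,
                }
                for r in records
            ]
        ).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["peak_vs_gene"] = str(path)

        if config.terms:
            stage("go_enrichment")
            annotations = go_enrichment.read_term_annotations(config.terms)
            dcfg = go_enrichment.RegulatoryDomainConfig(
                **config.go.get("domain", {})
            )
            domains = go_enrichment.build_domains(
                genes,
                dcfg,
                genome,
                annotated_ids=set(annotations["gene_id"]),
            )
            results = go_enrichment.binomial_enrichment(
                primary_peaks, domains, annotations, genome
            )
            path = out / "go_enrichment.tsv"
            go_enrichment.results_table(results).to_csv(path, sep="\t", index=False)
            manifest["outputs"]["go_enrichment"] = str(path)

    # --- duplicate diagnostics -------------------------------------------
    if primary_peaks and config.mode == "se":
        stage("dup_diagnostics")
        ip_lib = next(s["library"] for s in config.samples if s.get("role") == "IP")
        raw = _load_records(
            next(s["sam"] for s in config.samples if s["library"] == ip_lib),
            config.mode,
        )
        flagged, _ = read_filtering.mark_duplicates(
            read_filtering.filter_mapq_single(raw, fcfg.mapq_cutoff)
        )
        rankable = [
            p
            for p in primary_peaks
            if p.neg_log10_p is not None or p.neg_log10_fdr is not None
        ]
        if rankable:
            rank_by = (
                "neg_log10_p"
                if rankable[0].neg_log10_p is not None
                else "neg_log10_fdr"
            )
            rows = dup_diagnostics.duplication_table(
                flagged, rankable, genome, rank_by=rank_by
            )
            path = out / "dup_regions.tsv"
            pd.DataFrame(
                [
                    {
                        "Type": r.region_class,
                        "Size_bp": r.span,
                        "Non_duplicates": r.non_duplicates,
                        "Duplicates": r.duplicates,
                        "Sum": r.sum,
                        "Duplicates_pct": round(r.dup_pct, 2),
                        "Portion_pct": round(r.portion_pct, 2),
                    }
                    for r in rows
                ]
            ).to_csv(path, sep="\t", index=False)
            manifest["outputs"]["dup_regions"] = str(path)
            if len(rankable) >= 10:
                profile = dup_diagnostics.decile_profile(
                    rankable, flagged, rank_by=rank_by
                )
                path = out / "dup_profile.tsv"
                profile.to_frame().to_csv(path, sep="\t", index=False)
                manifest["outputs"]["dup_profile"] = str(path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
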