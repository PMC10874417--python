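"""End-to-end orchestration: qc -> scan -> posthoc -> annotate.

Each stage writes its TSV artifact; a run manifest records the
configuration echo and per-stage row counts.  Reruns with identical
inputs and configuration reproduce identical outputs.  On a stage
failure, files already written for that stage are renamed with a
``.partial`` suffix and the stage name is raised with the error.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import (
    DEFAULT_WINDOW_BP,
    build_gene_pairs,
    build_snp_gene_map,
    classify_ad_groups,
    ppi_overlap,
    read_gene_intervals,
    read_gene_list,
    read_ppi_edges,
    write_gene_pairs,
)
from .geno_io import (
    encode_covariates,
    read_plink_binary,
    read_trait_table,
    write_results_table,
)
from .posthoc import independence_report, variance_partition, whole_sample_r2_cov, write_ld_report
from .qc import QCThresholds, apply_qc
from .scan import ScanConfig, bonferroni_threshold, pairwise_scan


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    bed_prefix: str
    trait_path: str
    covariate_path: str
    out_dir: str
    gene_intervals_path: str | None = None
    disease_genes_path: str | None = None
    ppi_edges_path: str | None = None
    exclude_samples_path: str | None = None
    trait_id_column: str = "sample_id"
    trait_value_column: str = "trait"
    qc: QCThresholds = field(default_factory=QCThresholds)
    scan: ScanConfig = field(default_factory=ScanConfig)
    alpha: float | None = 0.05  # Bonferroni family-wise level; None = use scan.p_threshold
    ld_r2_threshold: float = 0.8
    annotation_window_bp: int = DEFAULT_WINDOW_BP


def _read_exclusions(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def run_pipeline(config: PipelineConfig, log=sys.stderr) -> dict:
    """Run all stages; returns a summary dict mirroring the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows: list[dict] = []
    summary: dict = {}

    def _log(msg: str) -> None:
        print(f"[epiquant] {msg}", file=log)

    def _stage(name: str, fn, outputs: list[Path]):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            for path in outputs:
                if path.exists():
                    path.rename(path.with_suffix(path.suffix + ".partial"))
            raise StageError(name, exc) from exc
        return result

    # ---- load ----
    def _load():
        dataset = read_plink_binary(config.bed_prefix)
        phenotype = read_trait_table(
            config.trait_path, dataset, config.trait_id_column, config.trait_value_column
        )
        cov_table = pd.read_csv(config.covariate_path, sep="\t", dtype=str)
        return dataset, phenotype, cov_table

    dataset, phenotype, cov_table = _stage("load", _load, [])
    _log(f"loaded {dataset.n_samples} samples x {dataset.n_snps} SNPs")
    manifest_rows.append({"stage": "load", "rows": dataset.n_snps, "file": config.bed_prefix})

    # ---- qc ----
    qc_report_path = out_dir / "qc_report.tsv"

    def _qc():
        exclusions = (
            _read_exclusions(config.exclude_samples_path)
            if config.exclude_samples_path
            else None
        )
        ds, ph, report = apply_qc(dataset, phenotype, config.qc, exclusions)
        report.write(qc_report_path)
        return ds, ph, report

    dataset_qc, phenotype_qc, qc_report = _stage("qc", _qc, [qc_report_path])
    _log(
        f"qc: {dataset_qc.n_samples} samples x {dataset_qc.n_snps} SNPs remain"
    )
    manifest_rows.append({"stage": "qc", "rows": dataset_qc.n_snps, "file": qc_report_path.name})

    covariates = encode_covariates(cov_table, dataset_qc)

    # ---- scan ----
    results_path = out_dir / "results.tsv"

    def _scan():
        scan_cfg = config.scan
        if config.alpha is not None:
            threshold = bonferroni_threshold(dataset_qc.n_snps, config.alpha)
            scan_cfg = ScanConfig(
                p_threshold=threshold,
                block_size=scan_cfg.block_size,
                missing_policy=scan_cfg.missing_policy,
                same_chrom_min_distance_bp=scan_cfg.same_chrom_min_distance_bp,
                cross_chromosome=scan_cfg.cross_chromosome,
            )
        return pairwise_scan(dataset_qc, phenotype_qc, covariates, scan_cfg), scan_cfg

    (scan_result, scan_cfg) = _stage("scan", _scan, [results_path])
    _log(
        f"scan: {scan_result.n_pairs_tested} pairs tested at p <= "
        f"{scan_cfg.p_threshold:.3g}; {len(scan_result.significant)} significant, "
        f"{len(scan_result.invalid)} invalid"
    )

    # ---- posthoc ----
    ld_path = out_dir / "ld_report.tsv"

    def _posthoc():
        partitions = {}
        for res in scan_result.significant:
            partitions[(res.snp1_index, res.snp2_index)] = variance_partition(
                phenotype_qc,
                covariates,
                dataset_qc.genotypes[:, res.snp1_index],
                dataset_qc.genotypes[:, res.snp2_index],
                scan_cfg.missing_policy,
            )
        snp_set = sorted(
            {i for r in scan_result.significant for i in (r.snp1_index, r.snp2_index)}
        )
        ld = independence_report(snp_set, dataset_qc, config.ld_r2_threshold) if len(snp_set) >= 2 else []
        write_ld_report(ld, ld_path, dataset_qc)
        r2_cov_whole = whole_sample_r2_cov(phenotype_qc, covariates)
        return partitions, ld, r2_cov_whole

    partitions, ld, r2_cov_whole = _stage("posthoc", _posthoc, [ld_path])
    _log(
        f"posthoc: whole-sample covariate R^2 = {r2_cov_whole:.4f}; "
        f"{len(ld)} within-set pairs above LD r^2 {config.ld_r2_threshold}"
    )
    manifest_rows.append({"stage": "posthoc", "rows": len(ld), "file": ld_path.name})

    # ---- annotate ----
    gene_pairs_path = out_dir / "gene_pairs.tsv"
    gene_map: dict[int, list[str]] = {}
    gene_pairs = []
    n_overlap = 0

    def _annotate():
        nonlocal gene_map, gene_pairs, n_overlap
        if config.gene_intervals_path is None:
            return
        intervals = read_gene_intervals(config.gene_intervals_path)
        snp_set = {i for r in scan_result.significant for i in (r.snp1_index, r.snp2_index)}
        gene_map = build_snp_gene_map(
            dataset_qc, intervals, snp_set, config.annotation_window_bp
        )
        gene_pairs = build_gene_pairs(
            [(r.snp1_index, r.snp2_index) for r in scan_result.significant], gene_map
        )
        if config.disease_genes_path:
            classify_ad_groups(gene_pairs, read_gene_list(config.disease_genes_path))
        if config.ppi_edges_path:
            _, n = ppi_overlap(gene_pairs, read_ppi_edges(config.ppi_edges_path))
            n_overlap = n
        write_gene_pairs(gene_pairs, gene_pairs_path)

    _stage("annotate", _annotate, [gene_pairs_path])
    if config.gene_intervals_path is not None:
        _log(f"annotate: {len(gene_pairs)} gene pairs, {n_overlap} PPI overlaps")
        manifest_rows.append(
            {"stage": "annotate", "rows": len(gene_pairs), "file": gene_pairs_path.name}
        )

    # results table last so partition columns are included
    frame = write_results_table(
        scan_result.significant + scan_result.invalid,
        results_path,
        dataset_qc,
        partitions,
        gene_map or None,
    )
    manifest_rows.append({"stage": "scan", "rows": len(frame), "file": results_path.name})

    manifest_path = out_dir / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write(f"# epiquant {__version__}\n")
        fh.write(f"# bed_prefix={config.bed_prefix}\n")
        fh.write(f"# p_threshold={scan_cfg.p_threshold:.12g}\n")
        fh.write(f"# missing_policy={scan_cfg.missing_policy}\n")
        fh.write(f"# ld_r2_threshold={config.ld_r2_threshold}\n")
        fh.write(f"# annotation_window_bp={config.annotation_window_bp}\n")
        pd.DataFrame(manifest_rows).to_csv(fh, sep="\t", index=False)

    summary.update(
        n_samples=dataset_qc.n_samples,
        n_snps=dataset_qc.n_snps,
        n_pairs_tested=scan_result.n_pairs_tested,
        p_threshold=scan_cfg.p_threshold,
        n_significant=len(scan_result.significant),
        n_invalid=len(scan_result.invalid),
        r2_cov_whole_sample=r2_cov_whole,
        n_ld_pairs_above_threshold=len(ld),
        n_gene_pairs=len(gene_pairs),
        n_ppi_overlaps=n_overlap,
        results_path=str(results_path),
        manifest_path=str(manifest_path),
    )
    return summary
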