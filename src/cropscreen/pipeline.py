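"""End-to-end orchestration: qc -> assign -> test -> aggregate (-> calibrate).

Every stage writes a plain-text artifact into the output directory, and
a manifest records versions, seeds, input checksums and per-stage
counts.  The calibration stage reuses the exact same DE entry point as
the real analysis, differing only in its target table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import aggregate_targets, build_e2g_table
from .assignment import assign_guides, cell_assignment_classes, classify_cells
from .calibration import (
    build_nt_pseudo_targets,
    pseudo_target_specs,
    qq_diagnostics,
    run_null_screen,
)
from .de import (
    build_dataset,
    run_de,
    select_nt_background,
    single_assignment,
    target_specs_from_design,
)
from .io import (
    PipelineConfig,
    design_from_tables,
    library_from_table,
    read_gene_annotation,
    read_guide_library,
    read_matrix_triplet,
    read_targets_bed,
    sha256_of,
    write_json,
)
from .qc import compute_qc_metrics, filter_cells, flag_doublet_like
from .simulate import MITO_CHROM

log = logging.getLogger("cropscreen")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline described by ``config``.

    Returns the manifest dictionary; artifacts land in
    ``config.out_dir``.
    """
    config.validate()
    indir = Path(config.screen_dir)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = []
    stage_counts = {}

    def _stage(name):
        log.info("stage: %s", name)

    try:
        _stage("load")
        gene_counts, gene_ids, cell_ids = read_matrix_triplet(indir / "gene")
        guide_counts, guide_ids, cell_ids2 = read_matrix_triplet(indir / "grna")
        if cell_ids != cell_ids2:
            raise ValueError("gene and gRNA matrices list different barcodes")
        targets = read_targets_bed(indir / "targets.bed")
        annotation = read_gene_annotation(indir / "annotation.tsv")
        lib_table = read_guide_library(indir / "library.tsv")
        design = design_from_tables(targets, lib_table)
        library = library_from_table(lib_table)
        if list(library.guide_ids) != list(guide_ids):
            raise ValueError("guide matrix features do not match library guide ids")
        batch_path = indir / "batches.tsv"
        if batch_path.exists():
            batches = pd.read_csv(batch_path, sep="\t")
            batch = batches.set_index("cell_id").loc[cell_ids, "batch"].to_numpy()
        else:
            batch = np.repeat("exp1", len(cell_ids))
    except Exception as e:
        raise RuntimeError(f"[load] {e}") from e

    try:
        _stage("qc")
        mito_ids = annotation.loc[annotation.chrom == MITO_CHROM, "gene_id"].tolist()
        metrics = compute_qc_metrics(gene_counts, gene_ids, mito_ids, batch, cell_ids)
        keep, thresholds = filter_cells(metrics, config.n_mads)
        stage_counts["qc_cells_in"] = len(cell_ids)
        stage_counts["qc_cells_kept"] = int(keep.sum())
    except Exception as e:
        raise RuntimeError(f"[qc] {e}") from e

    try:
        _stage("assign")
        table = assign_guides(
            guide_counts, library, alpha=config.alpha, umi_floor=config.umi_floor,
            cell_ids=cell_ids,
        )
        classes = cell_assignment_classes(table, len(cell_ids))
        class_summary = classify_cells(table, len(cell_ids))
        doublet_flags = flag_doublet_like(classes, metrics)
        stage_counts["assigned_cells"] = int((classes != "unassigned").sum())
        stage_counts["doublet_flagged"] = int(doublet_flags.sum())
    except Exception as e:
        raise RuntimeError(f"[assign] {e}") from e

    def _write_early_artifacts():
        qc_out = metrics.copy()
        qc_out["keep"] = keep
        qc_out["doublet_flag"] = doublet_flags
        qc_out.to_csv(outdir / "qc_metrics.tsv", sep="\t", index=False)
        thresholds.to_csv(outdir / "qc_thresholds.tsv", sep="\t", index=False)
        table.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        cls_out = pd.DataFrame({"cell_id": cell_ids, "assignment_class": classes})
        cls_out.to_csv(outdir / "cell_classes.tsv", sep="\t", index=False)
        return ["qc_metrics.tsv", "qc_thresholds.tsv", "assignments.tsv",
                "cell_classes.tsv"]

    def _manifest(arts):
        inputs = {}
        for rel in ("gene/matrix.mtx", "grna/matrix.mtx", "targets.bed",
                    "annotation.tsv", "library.tsv"):
            p = indir / rel
            if not p.exists():
                p = indir / (rel + ".gz")
            if p.exists():
                inputs[rel] = sha256_of(p)
        m = {
            "version": __version__,
            "seed": config.seed,
            "backend": config.backend,
            "inputs_sha256": inputs,
            "stage_counts": stage_counts,
            "artifacts": arts,
            "class_proportions": {
                r["class"]: r["proportion"] for _, r in class_summary.iterrows()
            },
        }
        write_json(m, outdir / "manifest.json")
        return m

    if config.stop_after in ("qc", "assign"):
        _stage("write")
        return _manifest(_write_early_artifacts())

    try:
        _stage("test")
        keep_final = keep.copy()
        if config.remove_doublet_flagged:
            keep_final &= ~doublet_flags
        kept_idx = np.flatnonzero(keep_final)
        sub_gene = gene_counts[:, kept_idx]
        totals = np.asarray(sub_gene.sum(axis=0)).ravel()
        nonzero = totals > 0
        kept_idx = kept_idx[nonzero]
        sub_gene = gene_counts[:, kept_idx]
        data = build_dataset(sub_gene, gene_ids, batch[kept_idx], config.min_frac)
        single_full = single_assignment(table, len(cell_ids))
        single_guide = single_full[kept_idx]
        background = select_nt_background(
            single_guide, design.nt_guide_ids, config.nt_background_n, config.seed
        )
        specs = target_specs_from_design(
            design, annotation, data.tested_gene_ids, config.window
        )
        de = run_de(data, specs, single_guide, background, backend=config.backend)
        stage_counts["cells_tested"] = len(kept_idx)
        stage_counts["genes_tested"] = int(data.tested_mask.sum())
        stage_counts["de_tests"] = int(len(de))
    except Exception as e:
        raise RuntimeError(f"[test] {e}") from e

    try:
        _stage("aggregate")
        agg = aggregate_targets(de, config.fdr)
        e2g, summary = build_e2g_table(
            agg, design, annotation, data.tested_gene_ids, config.fdr
        )
        stage_counts["target_gene_pairs"] = int(len(e2g))
        stage_counts["significant_pairs"] = summary["n_significant"]
    except Exception as e:
        raise RuntimeError(f"[aggregate] {e}") from e

    calib_report = None
    if config.calibrate:
        try:
            _stage("calibrate")
            pseudo = build_nt_pseudo_targets(
                design.nt_guide_ids, config.calibration_group_size, config.seed
            )
            universe = sorted({g for s in specs for g in s.gene_ids})
            cap = config.calibration_max_genes or None
            pspecs = pseudo_target_specs(pseudo, universe, cap, config.seed)
            null_de = run_null_screen(
                data, pspecs, single_guide, background, backend=config.backend
            )
            calib_report = qq_diagnostics(null_de.p_raw.dropna().to_numpy())
            null_de.to_csv(outdir / "calibration_tests.tsv", sep="\t", index=False)
            artifacts.append("calibration_tests.tsv")
            write_json(
                {
                    "n_tests": calib_report.n_tests,
                    "ks_statistic": calib_report.ks_statistic,
                    "ks_pvalue": calib_report.ks_pvalue,
                    "inflation_factor": calib_report.inflation_factor,
                    "type_i_rates": calib_report.type_i_rates,
                },
                outdir / "calibration_report.json",
            )
            artifacts.append("calibration_report.json")
        except Exception as e:
            raise RuntimeError(f"[calibrate] {e}") from e

    _stage("write")
    core = _write_early_artifacts()
    de.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    e2g.to_csv(outdir / "e2g_results.tsv", sep="\t", index=False)
    write_json(summary, outdir / "e2g_summary.json")
    return _manifest(core + ["de_results.tsv", "e2g_results.tsv", "e2g_summary.json"]
                     + artifacts)
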