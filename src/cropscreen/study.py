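"""Reference study-scale configurations and end-to-end analysis helpers.

These functions pin the screen layout used for the package's headline
evaluations: the full 80-target / 355-guide library on a compact toy
chromosome, transduced at MOI 0.3 with enough cells to recover roughly
300 assigned cells per guide — and a half-size no-effect screen used
for null calibration.  The analysis helper runs the exact production
stages (QC, assignment, DE, aggregation) in memory on a screen object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import aggregate_targets, build_e2g_table
from .assignment import assign_guides, cell_assignment_classes
from .de import (
    build_dataset,
    run_de,
    select_nt_background,
    single_assignment,
    target_specs_from_design,
)
from .qc import compute_qc_metrics, filter_cells, flag_doublet_like
from .simulate import (
    MITO_CHROM,
    SimulationParams,
    SyntheticScreen,
    ToyGenome,
    reference_design,
    simulate_screen,
)


def study_genome() -> ToyGenome:
    """One 170 Mb chromosome with genes every 200 kb (~10 genes per
    +/- 1 Mb testing window)."""
    return ToyGenome({"chr1": 170_000_000}, gene_spacing=200_000)


def study_design(genome: ToyGenome | None = None):
    return reference_design(genome or study_genome(), target_spacing=2_000_000)


def power_screen(seed: int = 0, n_cells: int = 480_000) -> SyntheticScreen:
    """The default power-evaluation screen: ~300 assigned cells/guide."""
    genome = study_genome()
    return simulate_screen(
        SimulationParams(n_cells=n_cells, seed=seed),
        design=study_design(genome),
        genome=genome,
    )


def calibration_screen(seed: int = 0, n_cells: int = 200_000) -> SyntheticScreen:
    """A no-effect screen (all knockdowns zero) for null calibration."""
    genome = study_genome()
    return simulate_screen(
        SimulationParams(n_cells=n_cells, seed=seed),
        design=study_design(genome),
        genome=genome,
        null=True,
    )


@dataclass
class ScreenAnalysis:
    """All intermediate products of an in-memory end-to-end run."""

    screen: SyntheticScreen
    qc_keep: np.ndarray
    kept_idx: np.ndarray  # positions into the original cell axis
    assign_table: pd.DataFrame
    cell_classes: pd.Series
    data: object  # DEDataset over kept cells
    single_guide: np.ndarray  # per kept cell
    background: np.ndarray  # positions into kept cells
    specs: list
    de: pd.DataFrame
    aggregated: pd.DataFrame
    e2g: pd.DataFrame
    summary: dict


def analyze_screen(
    screen: SyntheticScreen,
    nt_background_n: int = 5000,
    seed: int = 0,
    backend: str = "hurdle",
    window: int = 1_000_000,
    min_frac: float = 0.05,
    fdr: float = 0.05,
    release_counts: bool = False,
) -> ScreenAnalysis:
    """QC -> assign -> DE -> aggregate, mirroring the disk pipeline.

    ``release_counts=True`` drops the screen's full gene matrix once the
    QC-passing subset has been taken (the screen object is mutated),
    which caps peak memory on the largest runs.
    """
    ann = screen.annotation
    mito = ann.loc[ann.chrom == MITO_CHROM, "gene_id"].tolist()
    metrics = compute_qc_metrics(
        screen.gene_counts, screen.gene_ids, mito, screen.batch, screen.cell_ids
    )
    keep, _ = filter_cells(metrics)

    table = assign_guides(screen.guide_counts, screen.library, cell_ids=screen.cell_ids)
    classes = cell_assignment_classes(table, len(screen.cell_ids))
    doublet = flag_doublet_like(classes, metrics)

    totals_all = np.asarray(screen.gene_counts.sum(axis=0)).ravel()
    keep_final = keep & ~doublet & (totals_all > 0)
    kept_idx = np.flatnonzero(keep_final)
    sub = screen.gene_counts[:, kept_idx]

    if release_counts:
        screen.gene_counts = None
    data = build_dataset(sub, screen.gene_ids, screen.batch[kept_idx], min_frac)
    del sub
    single_guide = single_assignment(table, len(screen.cell_ids))[kept_idx]
    background = select_nt_background(
        single_guide, screen.design.nt_guide_ids, nt_background_n, seed
    )
    specs = target_specs_from_design(screen.design, ann, data.tested_gene_ids, window)
    de = run_de(data, specs, single_guide, background, backend=backend)
    agg = aggregate_targets(de, fdr)
    e2g, summary = build_e2g_table(agg, screen.design, ann, data.tested_gene_ids, fdr)
    return ScreenAnalysis(
        screen=screen, qc_keep=keep, kept_idx=kept_idx, assign_table=table,
        cell_classes=classes, data=data, single_guide=single_guide,
        background=background, specs=specs, de=de, aggregated=agg,
        e2g=e2g, summary=summary,
    )


def baseline_means_from_background(analysis: ScreenAnalysis) -> pd.Series:
    """Per-gene baseline mean UMIs/cell measured on the NT background."""
    bg_cols = analysis.data.counts[:, analysis.background]
    mean = np.asarray(bg_cols.mean(axis=1)).ravel()
    return pd.Series(mean, index=analysis.data.gene_ids)


def expected_gene_recovery(
    analysis: ScreenAnalysis,
    min_baseline_mean: float = 2.0,
    fdr: float = 0.05,
) -> dict:
    """Recovery of planted expected genes, overall and by expression bin.

    A pair counts as recovered when its FDR < ``fdr``, at least two
    guides support it with concordant direction, and the summary fold
    change is negative (knockdown direction).
    """
    base = baseline_means_from_background(analysis)
    e2g = analysis.e2g
    exp = e2g[e2g.is_expected_gene].copy()
    exp["baseline_mean"] = [base.get(g, 0.0) for g in exp.gene_id]
    exp["recovered"] = (
        (exp.fdr < fdr) & (exp.n_supporting_guides >= 2) & (exp.summary_log2fc < 0)
    )
    bins = [0.0, 0.5, 2.0, np.inf]
    labels = ["lt_0.5", "0.5_to_2", "ge_2"]
    exp["expr_bin"] = pd.cut(exp.baseline_mean, bins, labels=labels, right=False)
    by_bin = {
        str(b): {
            "n": int(len(sub)),
            "recovered": int(sub.recovered.sum()),
            "rate": float(sub.recovered.mean()) if len(sub) else float("nan"),
        }
        for b, sub in exp.groupby("expr_bin", observed=False)
    }
    high = exp[exp.baseline_mean >= min_baseline_mean]
    return {
        "n_expected_pairs": int(len(exp)),
        "n_high_expression": int(len(high)),
        "recovery_rate_high_expression": float(high.recovered.mean()) if len(high) else float("nan"),
        "recovery_by_bin": by_bin,
        "table": exp,
    }


def null_calibration(
    analysis: ScreenAnalysis,
    min_tests: int = 10_000,
    group_size: int = 4,
    seed: int = 0,
) -> dict:
    """Null p-value calibration on a no-effect screen.

    Pools the gRNA-level p-values of the (effect-free) real targets with
    NT pseudo-target tests run through the identical DE entry point; the
    pseudo-target gene universe is subsampled just enough to reach
    ``min_tests`` total tests.  Also reports the target-level FDR<5%
    false-link rate of the real-target aggregation.
    """
    import math

    from .calibration import (
        build_nt_pseudo_targets,
        pseudo_target_specs,
        qq_diagnostics,
        run_null_screen,
    )

    scr = analysis.screen
    p_real = analysis.de.p_raw.dropna().to_numpy()
    pseudo = build_nt_pseudo_targets(scr.design.nt_guide_ids, group_size, seed)
    universe = sorted({g for s in analysis.specs for g in s.gene_ids})
    need = max(0, min_tests - len(p_real))
    per_target = max(1, math.ceil(need / (len(pseudo) * group_size)))
    pspecs = pseudo_target_specs(pseudo, universe, per_target, seed)
    null_de = run_null_screen(
        analysis.data, pspecs, analysis.single_guide, analysis.background
    )
    pvals = np.concatenate([p_real, null_de.p_raw.dropna().to_numpy()])
    n_pairs = len(analysis.e2g)
    n_false = int((analysis.e2g.fdr < 0.05).sum())
    return {
        "pvals": pvals,
        "null_de": null_de,
        "report": qq_diagnostics(pvals),
        "n_target_gene_pairs": n_pairs,
        "false_link_rate": n_false / n_pairs if n_pairs else float("nan"),
    }


def assignment_scores(analysis: ScreenAnalysis) -> dict:
    """Precision/recall of assignment calls against simulation truth."""
    truth_sets = [
        set(g.split(";")) - {""} for g in analysis.screen.truth.cells.guides
    ]
    assigned = analysis.assign_table[analysis.assign_table.assigned]
    tp = fp = 0
    for c, g in zip(assigned.cell_index.to_numpy(), assigned.guide_id.to_numpy()):
        if g in truth_sets[c]:
            tp += 1
        else:
            fp += 1
    fn = sum(len(s) for s in truth_sets) - tp
    cls = analysis.cell_classes
    n_assigned = int((cls != "unassigned").sum())
    return {
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "fraction_cells_assigned": n_assigned / len(cls),
        "fraction_single_among_assigned": (
            float((cls == "single").sum() / n_assigned) if n_assigned else float("nan")
        ),
    }
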