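"""Per-cell quality control: MAD-based outlier gates and a doublet heuristic.

Cells are filtered per batch on three metrics — total UMIs, number of
detected genes, and mitochondrial fraction — removing cells that deviate
by more than ``n_mads`` median absolute deviations from the batch median.
Totals and gene counts are gated on the low side only (on the log1p
scale); the mitochondrial fraction is gated on both sides: high-mito
cells are dying/low quality, and an unusually *low* mito fraction flags
stripped nuclei.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: normal-consistency constant so that MAD estimates the s.d. under normality
MAD_SCALE = 1.4826


def compute_qc_metrics(
    counts: sp.spmatrix,
    gene_ids,
    mito_gene_ids,
    batch=None,
    cell_ids=None,
) -> pd.DataFrame:
    """Per-cell QC metrics from a gene x cell count matrix.

    All-zero cells get ``mito_fraction`` 0 by convention.
    """
    if not sp.issparse(counts):
        counts = sp.csc_matrix(counts)
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    gene_ids = np.asarray(gene_ids)
    unknown = set(mito_gene_ids) - set(gene_ids)
    if unknown:
        raise ValueError(f"mito genes absent from annotation: {sorted(unknown)}")
    mito_mask = np.isin(gene_ids, list(mito_gene_ids))

    total = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = np.asarray(counts[mito_mask].sum(axis=0)).ravel() if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)

    n_cells = counts.shape[1]
    out = pd.DataFrame(
        {
            "cell_id": cell_ids if cell_ids is not None else [f"CELL_{i:06d}" for i in range(n_cells)],
            "total_umis": total.astype(np.int64),
            "n_genes_detected": n_genes.astype(np.int64),
            "mito_fraction": mito_frac,
            "batch": batch if batch is not None else np.repeat("exp1", n_cells),
        }
    )
    return out


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return MAD_SCALE * float(np.median(np.abs(x - med)))


def filter_cells(metrics: pd.DataFrame, n_mads: float = 3.0):
    """Keep-mask plus per-batch thresholds.

    Within each batch a cell is removed if any of:

    * log1p(total_umis) < median - n_mads * MAD
    * log1p(n_genes_detected) < median - n_mads * MAD
    * mito_fraction > median + n_mads * MAD (low quality)
    * mito_fraction < median - n_mads * MAD (stripped nuclei)

    Deviations of exactly ``n_mads`` MADs are kept ("more than" is
    strict), and a metric whose MAD is 0 in a batch filters nothing
    there (degenerate, documented behaviour).
    """
    keep = np.ones(len(metrics), dtype=bool)
    rows = []
    for b, sub in metrics.groupby("batch", sort=True):
        if len(sub) < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 cells")
        idx = sub.index.to_numpy()
        lt = np.log1p(sub.total_umis.to_numpy(dtype=float))
        lg = np.log1p(sub.n_genes_detected.to_numpy(dtype=float))
        mf = sub.mito_fraction.to_numpy(dtype=float)

        bounds = {}
        for name, x, low, high in (
            ("total_umis", lt, True, False),
            ("n_genes_detected", lg, True, False),
            ("mito_fraction", mf, True, True),
        ):
            med = float(np.median(x))
            mad = _mad(x)
            lo = med - n_mads * mad if (low and mad > 0) else -np.inf
            hi = med + n_mads * mad if (high and mad > 0) else np.inf
            bounds[name] = (lo, hi)
            keep[idx] &= (x >= lo) & (x <= hi)
        rows.append(
            {
                "batch": b,
                "log1p_total_lo": bounds["total_umis"][0],
                "log1p_genes_lo": bounds["n_genes_detected"][0],
                "mito_lo": bounds["mito_fraction"][0],
                "mito_hi": bounds["mito_fraction"][1],
                "n_cells": len(sub),
                "n_removed": int((~keep[idx]).sum()),
            }
        )
    return keep, pd.DataFrame(rows)


def flag_doublet_like(
    cell_class: pd.Series,
    metrics: pd.DataFrame,
    umi_percentile: float = 95.0,
) -> np.ndarray:
    """Heuristic doublet flag: multi-gRNA AND batch-top total UMIs.

    Doublets carry two cells' worth of transcripts and guides, so they
    tend to show both multiple assigned gRNAs and high library size.
    Flags cells whose class is ``multi`` and whose total UMIs exceed the
    batch ``umi_percentile`` (strictly).  Flag only; removal is left to
    the pipeline.
    """
    is_multi = (cell_class.to_numpy() == "multi")
    flags = np.zeros(len(metrics), dtype=bool)
    for b, sub in metrics.groupby("batch", sort=True):
        thr = np.percentile(sub.total_umis.to_numpy(dtype=float), umi_percentile)
        idx = sub.index.to_numpy()
        flags[idx] = is_multi[idx] & (sub.total_umis.to_numpy() > thr)
    return flags
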