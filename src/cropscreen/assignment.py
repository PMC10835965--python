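"""Probabilistic gRNA-to-cell assignment via a binomial ambient model.

For each cell with N_c total guide-library UMIs, the count x_gc of guide
g is tested against Binomial(N_c, p_g), where p_g is the guide's
expected proportion from the plasmid library.  This accounts both for
per-cell differences in guide-transcript recovery (through N_c) and for
guide-abundance-driven ambient background (through p_g).  A guide is
called present in a cell iff its Bonferroni-adjusted upper-tail p-value
is below ``alpha`` AND it is supported by strictly more than
``umi_floor`` UMIs.

The Bonferroni family is all guides in the library, applied per cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .simulate import GuideLibrary

CELL_CLASSES = ("unassigned", "single", "multi")


def binomial_tail_pvalue(x, n, p):
    """Inclusive upper-tail binomial p-value P[X >= x], X ~ Bin(n, p).

    Vectorized over ``x`` and ``n``.  Exact (survival-function based) and
    numerically stable for n up to at least 1e6.
    """
    x = np.asarray(x)
    n = np.asarray(n)
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("require 0 <= x <= n")
    p = float(p) if np.ndim(p) == 0 else np.asarray(p, dtype=float)
    if np.any(np.asarray(p) <= 0) or np.any(np.asarray(p) >= 1):
        raise ValueError("require 0 < p < 1")
    # P[X >= x] = sf(x - 1)
    return stats.binom.sf(x - 1, n, p)


def assign_guides(
    guide_counts: sp.spmatrix,
    library: GuideLibrary,
    alpha: float = 0.001,
    umi_floor: int = 3,
    cell_ids=None,
) -> pd.DataFrame:
    """Per-(cell, guide) assignment table for all observed candidates.

    Tests every guide with x_gc > 0 in every cell with N_c > 0; the
    returned long-form table has columns cell_index, cell_id, guide_id,
    x, n, p_raw, p_adj, assigned.  Cells with N_c = 0 contribute no rows
    and are classed unassigned.
    """
    library.validate()
    counts = sp.csc_matrix(guide_counts)
    n_guides, n_cells = counts.shape
    lib_ids = np.asarray(library.guide_ids)
    if n_guides != len(lib_ids):
        raise ValueError(
            f"guide matrix has {n_guides} guides but library lists {len(lib_ids)}"
        )
    p_g = library.proportions

    coo = counts.tocoo()
    gidx, cidx, x = coo.row, coo.col, coo.data
    if np.any(x < 0) or not np.issubdtype(x.dtype, np.integer):
        raise ValueError("guide counts must be non-negative integers")
    n_c = np.asarray(counts.sum(axis=0)).ravel()

    p_raw = stats.binom.sf(x - 1, n_c[cidx], p_g[gidx])
    p_adj = np.minimum(1.0, p_raw * n_guides)
    assigned = (p_adj < alpha) & (x > umi_floor)

    cell_ids = np.asarray(cell_ids) if cell_ids is not None else np.array(
        [f"CELL_{i:06d}" for i in range(n_cells)]
    )
    table = pd.DataFrame(
        {
            "cell_index": cidx,
            "cell_id": cell_ids[cidx],
            "guide_id": lib_ids[gidx],
            "x": x,
            "n": n_c[cidx],
            "p_raw": p_raw,
            "p_adj": p_adj,
            "assigned": assigned,
        }
    ).sort_values(["cell_index", "guide_id"], kind="stable", ignore_index=True)
    table.attrs["n_cells"] = n_cells
    return table


def check_guides_in_library(guide_ids, library: GuideLibrary) -> None:
    """Raise naming the first guide that the library does not list."""
    known = set(library.guide_ids)
    for g in guide_ids:
        if g not in known:
            raise KeyError(f"guide {g!r} present in counts but absent from library")


def cell_assignment_classes(table: pd.DataFrame, n_cells: int | None = None) -> pd.Series:
    """Per-cell class: unassigned / single / multi assigned guides."""
    if n_cells is None:
        n_cells = table.attrs.get("n_cells")
        if n_cells is None:
            raise ValueError("n_cells required when the table does not record it")
    counts = np.zeros(n_cells, dtype=int)
    assigned = table[table.assigned]
    if len(assigned):
        idx, cnt = np.unique(assigned.cell_index.to_numpy(), return_counts=True)
        counts[idx] = cnt
    cls = np.where(counts == 0, "unassigned", np.where(counts == 1, "single", "multi"))
    return pd.Series(cls, name="assignment_class")


def classify_cells(table: pd.DataFrame, n_cells: int | None = None) -> pd.DataFrame:
    """Counts and proportions of unassigned / single / multi cells."""
    cls = cell_assignment_classes(table, n_cells)
    n = len(cls)
    rows = []
    for c in CELL_CLASSES:
        k = int((cls == c).sum())
        rows.append({"class": c, "n_cells": k, "proportion": k / n if n else 0.0})
    return pd.DataFrame(rows)


def assigned_guides_per_cell(table: pd.DataFrame, n_cells: int | None = None) -> list:
    """List of assigned guide-id lists, one entry per cell."""
    if n_cells is None:
        n_cells = table.attrs.get("n_cells")
    out = [[] for _ in range(n_cells)]
    sub = table[table.assigned]
    for c, g in zip(sub.cell_index.to_numpy(), sub.guide_id.to_numpy()):
        out[c].append(g)
    return out
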