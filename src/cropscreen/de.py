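"""Per-gRNA differential expression against a non-targeting background.

For each target, cells carrying any of its guides plus a fixed set of
randomly chosen single-NT background cells are modelled jointly, and the
effect of each guide is tested with a likelihood-ratio test under a
two-part hurdle model:

* a logistic *detection* component (gene detected yes/no), and
* a Gaussian *continuous* component on log2-normalized expression among
  detected cells,

both regressed on per-guide indicators, experiment (batch) and the
cellular detection rate (CDR).  The two components' likelihoods
factorize, so the per-guide LR statistic is the sum of the component LR
statistics, referred to a chi-square with one df per estimable
component.  A stratified Wilcoxon (van Elteren) backend is provided as a
nonparametric alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

LOG2 = np.log(2.0)
DEGENERATE_COEF = 15.0
RIDGE = 1e-6


@dataclass
class NormalizedExpression:
    """Library-size-normalized, log2-transformed expression.

    values = log2(1 + count / s_c * scale) with s_c the median-scaled
    library size factor.  Stored sparse: zeros stay zeros.
    """

    matrix: sp.csr_matrix  # genes x cells, float
    size_factors: np.ndarray
    scale: float = 1.0


@dataclass
class TargetSpec:
    """A unit of DE testing: a target id, its guides, and the genes to test."""

    target_id: str
    guide_ids: list
    gene_ids: list


def detection_filter(counts: sp.spmatrix, min_frac: float = 0.05) -> np.ndarray:
    """Boolean mask over genes detected in at least ``min_frac`` of cells."""
    if not (0 < min_frac < 1):
        raise ValueError("min_frac must be in (0, 1)")
    if not sp.issparse(counts):
        counts = sp.csc_matrix(counts)
    det = np.asarray((counts > 0).sum(axis=1)).ravel()
    return det >= min_frac * counts.shape[1]


def normalize_log(counts: sp.spmatrix, scale: float = 1.0) -> NormalizedExpression:
    """Median-scaled library-size normalization, then log2(1 + x).

    A deliberately simple stand-in for pool-based deconvolution factors;
    the factor definition is isolated here so it can be swapped.
    """
    if not sp.issparse(counts):
        counts = sp.csc_matrix(counts)
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    if np.any(totals <= 0):
        raise ValueError("cells with zero totals must be removed before normalization")
    s = totals / np.median(totals)
    # divide each column by its size factor, then log2(1+x) on the data;
    # float32 is plenty for log-scale expression and halves the footprint
    mat = sp.csc_matrix(counts, dtype=np.float32, copy=True)
    percol = np.repeat(s.astype(np.float32), np.diff(mat.indptr))
    mat.data = np.log2(np.float32(1.0) + mat.data / percol * np.float32(scale))
    return NormalizedExpression(matrix=mat, size_factors=s, scale=scale)


def compute_cdr(counts: sp.spmatrix, tested_mask: np.ndarray) -> np.ndarray:
    """Cellular detection rate over tested genes, standardized.

    Fraction of tested genes detected per cell, centered and scaled to
    unit variance (population s.d.).  If the rate has zero variance the
    covariate is degenerate and all-zeros is returned.
    """
    if tested_mask.sum() == 0:
        raise ValueError("no tested genes")
    if not sp.issparse(counts):
        counts = sp.csc_matrix(counts)
    frac = np.asarray((counts[tested_mask] > 0).sum(axis=0)).ravel() / tested_mask.sum()
    sd = frac.std()
    if sd == 0:
        import warnings

        warnings.warn("CDR has zero variance; covariate dropped")
        return np.zeros(len(frac))
    return (frac - frac.mean()) / sd


def single_assignment(assign_table: pd.DataFrame, n_cells: int) -> np.ndarray:
    """Per-cell: the uniquely assigned guide id, or '' if 0 or >1 assigned."""
    out = np.full(n_cells, "", dtype=object)
    counts = np.zeros(n_cells, dtype=int)
    sub = assign_table[assign_table.assigned]
    for c, g in zip(sub.cell_index.to_numpy(), sub.guide_id.to_numpy()):
        counts[c] += 1
        out[c] = g if counts[c] == 1 else ""
    return out


def select_nt_background(
    single_guide: np.ndarray,
    nt_guide_ids,
    n: int = 5000,
    seed: int = 0,
) -> np.ndarray:
    """Fixed background set: cells whose only assigned guide is NT.

    Samples min(n, available) uniformly without replacement; the same
    set is reused for every target of a run.
    """
    nt = set(nt_guide_ids)
    eligible = np.flatnonzero([g in nt for g in single_guide])
    if len(eligible) == 0:
        raise ValueError("no cells with a single non-targeting gRNA")
    if len(eligible) <= n:
        if len(eligible) < n:
            import warnings

            warnings.warn(
                f"only {len(eligible)} eligible NT cells for background of {n}"
            )
        return np.sort(eligible)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(eligible, size=n, replace=False))


def genes_in_window(
    target_chrom: str,
    target_start: int,
    target_end: int,
    annotation: pd.DataFrame,
    window: int = 1_000_000,
    tested_gene_ids=None,
) -> list:
    """Genes whose TSS lies in [start - window, end + window], closed.

    Restricted to the target's chromosome and, if given, intersected
    with the tested gene set (order preserved by genomic position).
    """
    if target_chrom not in set(annotation.chrom):
        raise ValueError(f"chromosome {target_chrom!r} absent from annotation")
    sub = annotation[annotation.chrom == target_chrom]
    lo, hi = target_start - window, target_end + window
    sel = sub[(sub.tss >= lo) & (sub.tss <= hi)].sort_values("tss")
    ids = list(sel.gene_id)
    if tested_gene_ids is not None:
        tested = set(tested_gene_ids)
        ids = [g for g in ids if g in tested]
    return ids


# ---------------------------------------------------------------------------
# model fitting


def _logistic_fit(X, y, ridge_cols, lam=RIDGE, beta0=None, tol=1e-10, max_iter=60):
    """Penalized logistic regression by Newton's method with step halving.

    Ridge penalty lam/2 * beta_j^2 on columns in ``ridge_cols`` keeps the
    fit finite under separation.  Returns (beta, penalized loglik).
    """
    n, k = X.shape
    R = np.zeros(k)
    R[list(ridge_cols)] = lam
    beta = np.zeros(k) if beta0 is None else beta0.copy()

    def pll(b):
        eta = np.clip(X @ b, -30, 30)
        return float(y @ eta - np.logaddexp(0, eta).sum() - 0.5 * (R * b * b).sum())

    ll = pll(beta)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu) - R * beta
        if np.max(np.abs(grad)) < tol:
            break
        W = mu * (1 - mu) + 1e-12
        H = (X * W[:, None]).T @ X + np.diag(R + 1e-12)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = pll(cand)
            if ll_new >= ll - 1e-14:
                break
            t *= 0.5
        beta = beta + t * step
        if abs(ll_new - ll) < 1e-13 * (1 + abs(ll)) and np.max(np.abs(grad)) < 1e-8:
            ll = ll_new
            break
        ll = ll_new
    return beta, pll(beta)


def _gaussian_loglik(X, y):
    """Profile (MLE-sigma) Gaussian loglik of OLS fit; returns (ll, rss)."""
    n = len(y)
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    rss = max(rss, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
    return ll, rss


def _drop_constant_columns(X, protect):
    """Indices of usable columns: intercept plus non-constant covariates.

    ``protect`` columns (guide indicators) are kept even if constant so
    their estimability is judged separately.
    """
    keep = [0]
    for j in range(1, X.shape[1]):
        if j in protect or X[:, j].std() > 0:
            keep.append(j)
    return keep


def hurdle_lrt_single_gene(
    y_counts: np.ndarray,
    z: np.ndarray,
    group_ids: np.ndarray,
    guide_levels: list,
    batch_codes: np.ndarray,
    cdr: np.ndarray,
    ridge: float = RIDGE,
):
    """Per-guide hurdle LR tests for one gene.

    ``group_ids``: -1 for background cells, g >= 0 for cells of guide
    ``guide_levels[g]``.  Returns a list of dicts, one per guide level.
    """
    n = len(y_counts)
    det = (y_counts > 0).astype(float)
    n_guides = len(guide_levels)

    # design: intercept | guide dummies | batch dummies | cdr
    cols = [np.ones(n)]
    guide_cols = []
    for g in range(n_guides):
        cols.append((group_ids == g).astype(float))
        guide_cols.append(g + 1)
    levels = np.unique(batch_codes)
    for b in levels[1:]:
        cols.append((batch_codes == b).astype(float))
    cols.append(cdr)
    X = np.column_stack(cols)
    usable = _drop_constant_columns(X, set(guide_cols))
    Xu = X[:, usable]
    guide_pos = {g: usable.index(g + 1) for g in range(n_guides) if (g + 1) in usable}
    ridge_idx = [guide_pos[g] for g in guide_pos]

    det_varies = 0.0 < det.mean() < 1.0
    results = []

    beta_full = ll_disc_full = None
    if det_varies:
        beta_full, ll_disc_full = _logistic_fit(Xu, det, ridge_idx, ridge)
    det_mask = det > 0
    n_det = int(det_mask.sum())
    ll_cont_full = rss_full = None
    if n_det >= Xu.shape[1]:
        ll_cont_full, rss_full = _gaussian_loglik(Xu[det_mask], z[det_mask])

    for g, level in enumerate(guide_levels):
        n_g = int((group_ids == g).sum())
        if n_g == 0:
            results.append(
                dict(guide_id=level, n_cells=0, p_raw=np.nan, log2fc=np.nan, flag="no_cells")
            )
            continue
        keep_cols = [j for j, orig in enumerate(usable) if orig != g + 1]
        Xr = Xu[:, keep_cols]
        flags = []
        stat = 0.0
        df = 0
        # discrete component
        if det_varies:
            # cold start: warm starts can stall in the flat region that
            # separation + tiny ridge creates
            gset = set(guide_cols)
            ridge_r = [
                i for i, jj in enumerate(keep_cols) if usable[jj] in gset
            ]
            _, ll_red = _logistic_fit(Xr, det, ridge_r, ridge)
            stat += max(0.0, 2.0 * (ll_disc_full - ll_red))
            df += 1
            if np.max(np.abs(beta_full)) > DEGENERATE_COEF:
                flags.append("degenerate_disc")
        else:
            flags.append("cont_only")
        # continuous component: needs enough detected cells on both sides
        det_in_g = int((det_mask & (group_ids == g)).sum())
        det_rest = n_det - det_in_g
        if rss_full is not None and det_in_g >= 3 and det_rest >= 3:
            _, rss_red = _gaussian_loglik(Xr[det_mask], z[det_mask])
            stat += max(0.0, n_det * np.log(rss_red / rss_full))
            df += 1
        else:
            if det_varies:
                flags.append("disc_only")
        if df == 0:
            results.append(
                dict(guide_id=level, n_cells=n_g, p_raw=np.nan, log2fc=np.nan, flag="degenerate")
            )
            continue
        p = float(stats.chi2.sf(stat, df))
        lfc = float(z[group_ids == g].mean() - z[group_ids == -1].mean())
        results.append(
            dict(
                guide_id=level,
                n_cells=n_g,
                p_raw=p,
                log2fc=lfc,
                flag=";".join(flags) if flags else "",
            )
        )
    return results


def _van_elteren(z, group_mask, bg_mask, batch_codes):
    """Stratified rank-sum Z statistic combined over batches.

    Weights 1/(m_s + n_s + 1) per stratum (van Elteren); normal
    approximation with tie correction.  Returns two-sided p.
    """
    num = 0.0
    var = 0.0
    used = 0
    for b in np.unique(batch_codes):
        sel = (batch_codes == b) & (group_mask | bg_mask)
        m = int((group_mask & (batch_codes == b)).sum())
        nn = int((bg_mask & (batch_codes == b)).sum())
        if m == 0 or nn == 0:
            continue
        vals = z[sel]
        ranks = stats.rankdata(vals)
        w_stat = ranks[group_mask[sel]].sum()
        N = m + nn
        e = m * (N + 1) / 2.0
        _, t_counts = np.unique(vals, return_counts=True)
        tie = (t_counts**3 - t_counts).sum() / ((N) * (N - 1)) if N > 1 else 0.0
        v = m * nn / 12.0 * ((N + 1) - tie)
        w = 1.0 / (N + 1)
        num += w * (w_stat - e)
        var += w * w * v
        used += 1
    if used == 0 or var <= 0:
        return 1.0
    zstat = num / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(zstat)))


def wilcoxon_single_gene(z, group_ids, guide_levels, batch_codes, bg_id=-1):
    """Per-guide stratified Wilcoxon rows, same schema as the hurdle test."""
    bg_mask = group_ids == bg_id
    results = []
    for g, level in enumerate(guide_levels):
        gmask = group_ids == g
        n_g = int(gmask.sum())
        if n_g < 2:
            results.append(
                dict(guide_id=level, n_cells=n_g, p_raw=np.nan, log2fc=np.nan, flag="too_few_cells")
            )
            continue
        p = _van_elteren(z, gmask, bg_mask, batch_codes)
        lfc = float(z[gmask].mean() - z[bg_mask].mean())
        results.append(dict(guide_id=level, n_cells=n_g, p_raw=p, log2fc=lfc, flag=""))
    return results


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class DEDataset:
    """Aligned per-cell data for a DE run (one cell universe throughout)."""

    counts: sp.spmatrix  # genes x cells (QC-passed), CSC
    normalized: NormalizedExpression
    gene_ids: np.ndarray
    tested_mask: np.ndarray
    batch_codes: np.ndarray
    cdr: np.ndarray

    @property
    def tested_gene_ids(self):
        return self.gene_ids[self.tested_mask]


def build_dataset(counts, gene_ids, batch_labels, min_frac: float = 0.05) -> DEDataset:
    """Detection filter, normalization and CDR in one pass."""
    counts = sp.csc_matrix(counts)
    tested = detection_filter(counts, min_frac)
    norm = normalize_log(counts)
    cdr = compute_cdr(counts, tested)
    labels, codes = np.unique(np.asarray(batch_labels), return_inverse=True)
    return DEDataset(
        counts=counts,
        normalized=norm,
        gene_ids=np.asarray(gene_ids),
        tested_mask=tested,
        batch_codes=codes,
        cdr=cdr,
    )


def target_specs_from_design(
    design, annotation: pd.DataFrame, tested_gene_ids, window: int = 1_000_000
) -> list:
    """One TargetSpec per genomic target: its guides and window genes."""
    specs = []
    for _, t in design.targets.iterrows():
        genes = genes_in_window(
            t.chrom, int(t.start), int(t.end), annotation, window, tested_gene_ids
        )
        specs.append(TargetSpec(t.target_id, design.guides_for_target(t.target_id), genes))
    return specs


def run_de(
    data: DEDataset,
    specs: list,
    single_guide: np.ndarray,
    background: np.ndarray,
    backend: str = "hurdle",
) -> pd.DataFrame:
    """Test every (guide, window gene) pair of every spec; BH across all.

    ``single_guide`` gives each cell's uniquely assigned guide ('' for
    none/multi); only single-assigned cells enter guide groups, and
    background cells overlapping a spec's guides are dropped from the
    background for that spec.
    """
    if backend not in ("hurdle", "wilcoxon"):
        raise ValueError(f"unknown backend {backend!r}")
    gene_pos = {g: i for i, g in enumerate(data.gene_ids)}
    norm_csc = data.normalized.matrix.tocsc()
    counts_csc = data.counts.tocsc()
    bg = np.asarray(background)

    # positions of single-assigned cells, grouped by guide
    sg = pd.Series(single_guide)
    guide_to_cells = {
        g: idx.to_numpy() for g, idx in sg[sg != ""].groupby(sg[sg != ""]).groups.items()
    }

    rows = []
    for spec in specs:
        guide_levels = list(spec.guide_ids)
        member_parts = [guide_to_cells.get(g, np.array([], dtype=int)) for g in guide_levels]
        member = np.concatenate(member_parts) if member_parts else np.array([], dtype=int)
        bg_spec = bg[~np.isin(bg, member)]
        cells = np.concatenate([member, bg_spec]).astype(int)
        group_ids = np.empty(len(cells), dtype=int)
        off = 0
        for g, part in enumerate(member_parts):
            group_ids[off : off + len(part)] = g
            off += len(part)
        group_ids[off:] = -1
        batch_codes = data.batch_codes[cells]
        cdr = data.cdr[cells]

        counts_sub = counts_csc[:, cells].tocsr() if len(spec.gene_ids) else None
        norm_sub = norm_csc[:, cells].tocsr() if len(spec.gene_ids) else None
        for gene in spec.gene_ids:
            gi = gene_pos[gene]
            y = np.asarray(counts_sub[gi].todense()).ravel()
            z = np.asarray(norm_sub[gi].todense()).ravel()
            if backend == "hurdle":
                res = hurdle_lrt_single_gene(
                    y, z, group_ids, guide_levels, batch_codes, cdr
                )
            else:
                res = wilcoxon_single_gene(z, group_ids, guide_levels, batch_codes)
            for r in res:
                rows.append(
                    dict(
                        target_id=spec.target_id,
                        gene_id=gene,
                        n_bg=int((group_ids == -1).sum()),
                        backend=backend,
                        **r,
                    )
                )
    out = pd.DataFrame(
        rows,
        columns=[
            "target_id", "guide_id", "gene_id", "n_cells", "n_bg",
            "p_raw", "log2fc", "backend", "flag",
        ],
    )
    from .aggregate import bh_adjust

    if len(out):
        valid = out.p_raw.notna().to_numpy()
        adj = np.full(len(out), np.nan)
        if valid.any():
            adj[valid] = bh_adjust(out.p_raw.to_numpy()[valid])
        out["p_adj"] = adj
    else:
        out["p_adj"] = []
    return out
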