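"""Target-level evidence aggregation into element-to-gene (E2G) links.

Per-guide raw p-values for a target-gene pair are combined with Fisher's
method, the combined p-values are BH-corrected across all pairs tested
in the run, and each significant pair is placed in a confidence tier by
how many of its guides independently support the change (raw p < 0.05
with concordant direction): 3-4 supporting guides = high, 2 = medium,
1 = low.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

TIERS = ("high", "medium", "low", "ns")


def fisher_combine(pvals) -> float:
    """Fisher's method: X2 = -2 sum(ln p_i) ~ chi-square(2k).

    NaN entries (e.g., guides with zero recovered cells) are dropped and
    the degrees of freedom reduced accordingly; an empty list gives NaN.
    """
    p = np.asarray([v for v in np.atleast_1d(pvals) if not np.isnan(v)], dtype=float)
    if p.size == 0:
        return float("nan")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, 2 * p.size))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def classify_tier(p_raw, log2fc, n_cells, fdr, alpha: float = 0.05):
    """Confidence tier and support count for one target-gene pair.

    Support = number of guides with raw p < 0.05 whose log2FC sign
    matches the majority sign among those guides (ties broken by the
    cell-count-weighted mean log2FC).  Pairs with FDR >= ``alpha`` are
    'ns' regardless of support.
    """
    p = np.asarray(p_raw, dtype=float)
    l = np.asarray(log2fc, dtype=float)
    w = np.asarray(n_cells, dtype=float)
    hit = (p < 0.05) & ~np.isnan(p) & ~np.isnan(l) & (l != 0)
    support = 0
    if hit.any():
        signs = np.sign(l[hit])
        pos, neg = int((signs > 0).sum()), int((signs < 0).sum())
        if pos > neg:
            maj = 1.0
        elif neg > pos:
            maj = -1.0
        else:
            maj = np.sign((l[hit] * w[hit]).sum()) or 1.0
        support = int((signs == maj).sum())
    if np.isnan(fdr) or fdr >= alpha:
        return "ns", support
    if support >= 3:
        return "high", support
    if support == 2:
        return "medium", support
    if support == 1:
        return "low", support
    return "ns", support


def aggregate_targets(de_results: pd.DataFrame, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Combine per-guide DE rows into one row per (target, gene) pair."""
    rows = []
    for (tid, gene), sub in de_results.groupby(["target_id", "gene_id"], sort=True):
        p = sub.p_raw.to_numpy(dtype=float)
        combined = fisher_combine(p)
        w = sub.n_cells.to_numpy(dtype=float)
        l = sub.log2fc.to_numpy(dtype=float)
        ok = ~np.isnan(l)
        summary_lfc = float((l[ok] * w[ok]).sum() / w[ok].sum()) if ok.any() and w[ok].sum() > 0 else float("nan")
        rows.append(
            dict(
                target_id=tid,
                gene_id=gene,
                p_combined=combined,
                n_guides_tested=int((~np.isnan(p)).sum()),
                guide_pvals=";".join(f"{v:.3e}" if not np.isnan(v) else "NA" for v in p),
                guide_log2fcs=";".join(f"{v:.4f}" if not np.isnan(v) else "NA" for v in l),
                summary_log2fc=summary_lfc,
                _p=p,
                _l=l,
                _w=w,
            )
        )
    out = pd.DataFrame(rows)
    if not len(out):
        return pd.DataFrame(
            columns=[
                "target_id", "gene_id", "p_combined", "fdr", "n_supporting_guides",
                "tier", "summary_log2fc", "n_guides_tested", "guide_pvals", "guide_log2fcs",
            ]
        )
    valid = out.p_combined.notna().to_numpy()
    fdr = np.full(len(out), np.nan)
    if valid.any():
        fdr[valid] = bh_adjust(out.p_combined.to_numpy()[valid])
    out["fdr"] = fdr
    tiers, supports = [], []
    for i, r in out.iterrows():
        tier, supp = classify_tier(r._p, r._l, r._w, r.fdr, fdr_alpha)
        tiers.append(tier)
        supports.append(supp)
    out["tier"] = tiers
    out["n_supporting_guides"] = supports
    return out.drop(columns=["_p", "_l", "_w"])


def build_e2g_table(
    aggregated: pd.DataFrame,
    design,
    annotation: pd.DataFrame,
    tested_gene_ids,
    fdr_alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Annotate aggregated pairs with distances and summarize.

    distance_bp = |gene TSS - target interval midpoint|;
    is_nearest_expressed_gene is computed among detection-filtered genes
    on the target's chromosome.  Low-tier rows are retained but excluded
    from the headline summary counts (which report medium+high only).
    """
    tinfo = design.targets.set_index("target_id")
    ann = annotation.set_index("gene_id")
    tested = [g for g in tested_gene_ids if g in ann.index]
    tested_by_chrom = {
        c: sub.sort_values("tss")
        for c, sub in ann.loc[tested].reset_index().groupby("chrom")
    }

    dist = []
    nearest = []
    expected = []
    for _, r in aggregated.iterrows():
        t = tinfo.loc[r.target_id]
        mid = (int(t.start) + int(t.end)) // 2
        tss = int(ann.loc[r.gene_id, "tss"])
        dist.append(abs(tss - mid))
        sub = tested_by_chrom.get(t.chrom)
        if sub is None or not len(sub):
            nearest.append(False)
        else:
            d = np.abs(sub.tss.to_numpy() - mid)
            nearest.append(sub.gene_id.to_numpy()[int(np.argmin(d))] == r.gene_id)
        expected.append(r.gene_id == t.expected_gene_id)
    out = aggregated.copy()
    out["distance_bp"] = dist
    out["is_nearest_expressed_gene"] = nearest
    out["is_expected_gene"] = expected
    tclass = tinfo.target_class
    out["target_class"] = [tclass.loc[t] for t in out.target_id]

    sig = out[(out.fdr < fdr_alpha) & out.tier.isin(["high", "medium"])]
    sig_all = out[out.fdr < fdr_alpha]
    tier_counts = out.tier.value_counts().to_dict()
    degs_per_target = sig.groupby("target_id").size()
    recovery = {}
    for cls, sub in out.groupby("target_class"):
        exp = sub[sub.is_expected_gene]
        hit = exp[(exp.fdr < fdr_alpha) & (exp.summary_log2fc < 0) & exp.tier.isin(["high", "medium"])]
        recovery[cls] = {
            "n_expected_tested": int(len(exp)),
            "n_recovered": int(len(hit)),
        }
    summary = {
        "n_pairs_tested": int(len(out)),
        "n_significant": int(len(sig_all)),
        "tier_counts": {t: int(tier_counts.get(t, 0)) for t in TIERS},
        "degs_per_target_hist": degs_per_target.value_counts().sort_index().to_dict(),
        "frac_nearest_expressed": (
            float(sig.is_nearest_expressed_gene.mean()) if len(sig) else float("nan")
        ),
        "median_distance_nearest_bp": (
            float(sig[sig.is_nearest_expressed_gene].distance_bp.median())
            if len(sig[sig.is_nearest_expressed_gene])
            else float("nan")
        ),
        "median_distance_not_nearest_bp": (
            float(sig[~sig.is_nearest_expressed_gene].distance_bp.median())
            if len(sig[~sig.is_nearest_expressed_gene])
            else float("nan")
        ),
        "expected_gene_recovery_by_class": recovery,
    }
    return out, summary
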