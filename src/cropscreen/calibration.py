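"""Null calibration of the DE pipeline using non-targeting pseudo-targets.

Non-targeting guides are grouped into pseudo-targets of four guides to
mimic the library structure, and run through the *same* DE entry point
as real targets (``de.run_de``).  Since NT guides have no genomic
location, each pseudo-target is tested against genes drawn from the
union of all real targets' window genes.  The resulting p-values should
be uniform; the report quantifies deviation with a KS statistic, an
inflation factor on the median -log10 p, and empirical type-I rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import TargetSpec, run_de


@dataclass
class CalibrationReport:
    n_tests: int
    ks_statistic: float
    ks_pvalue: float
    inflation_factor: float
    type_i_rates: dict
    degenerate: bool = False


def build_nt_pseudo_targets(nt_guide_ids, group_size: int = 4, seed: int = 0) -> list:
    """Random disjoint groups of NT guides; leftovers are unused.

    With 35 NT guides and groups of four this yields 8 pseudo-targets
    (3 guides unused).
    """
    nt = list(nt_guide_ids)
    if len(nt) < group_size:
        raise ValueError(
            f"need at least {group_size} NT guides, have {len(nt)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(nt))
    n_groups = len(nt) // group_size
    groups = []
    for k in range(n_groups):
        ids = [nt[i] for i in perm[k * group_size : (k + 1) * group_size]]
        groups.append((f"NT_PSEUDO_{k:02d}", ids))
    return groups


def pseudo_target_specs(
    pseudo_targets: list,
    gene_universe,
    max_genes_per_target: int | None = None,
    seed: int = 0,
) -> list:
    """TargetSpecs for pseudo-targets over the window-gene universe.

    ``gene_universe`` is the union of all real targets' window genes.
    ``max_genes_per_target`` optionally subsamples the universe per
    pseudo-target (seeded) to bound compute.
    """
    universe = list(gene_universe)
    rng = np.random.default_rng(seed)
    specs = []
    for tid, guides in pseudo_targets:
        genes = universe
        if max_genes_per_target is not None and len(universe) > max_genes_per_target:
            pick = rng.choice(len(universe), size=max_genes_per_target, replace=False)
            genes = [universe[i] for i in np.sort(pick)]
        specs.append(TargetSpec(tid, list(guides), genes))
    return specs


def run_null_screen(
    data,
    pseudo_specs: list,
    single_guide,
    background,
    backend: str = "hurdle",
) -> pd.DataFrame:
    """Run the identical DE pipeline on pseudo-targets; returns DE rows."""
    return run_de(data, pseudo_specs, single_guide, background, backend=backend)


def qq_diagnostics(pvals, min_n: int = 100) -> CalibrationReport:
    """Compare a p-value vector to U(0,1).

    Inflation factor = median(-log10 p) / -log10(0.5); 1 means
    calibrated, > 1 inflated.  Type-I rates at alpha = 0.05 and 0.01.
    """
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < min_n:
        raise ValueError(f"need at least {min_n} p-values, have {p.size}")
    degenerate = np.unique(p).size == 1
    if degenerate:
        import warnings

        warnings.warn("constant p-value vector; calibration report is degenerate")
    ks = stats.kstest(p, "uniform")
    with np.errstate(divide="ignore"):
        med = float(np.median(-np.log10(np.clip(p, 1e-300, 1.0))))
    inflation = med / (-np.log10(0.5))
    return CalibrationReport(
        n_tests=int(p.size),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        inflation_factor=float(inflation),
        type_i_rates={
            "0.05": float((p < 0.05).mean()),
            "0.01": float((p < 0.01).mean()),
        },
        degenerate=degenerate,
    )


def qq_plot(pvals, path) -> None:
    """Write a QQ plot of observed vs expected -log10 p to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.sort(np.asarray(pvals, dtype=float))
    p = p[~np.isnan(p)]
    n = len(p)
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    obs = -np.log10(np.clip(p, 1e-300, 1))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(exp, obs, ".", ms=2)
    lim = max(exp.max(), obs.max())
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
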