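"""Aggregate per-gRNA evidence into element-to-gene (E2G) links.

Fisher's method combines the four guide p-values per (target, gene)
pair, BH controls the FDR across all pairs, and each significant pair
gets a confidence tier from its number of concordant supporting guides.
"""

import pandas as pd

from cropscreen import SimulationParams, ToyGenome, build_design, simulate_screen
from cropscreen.study import analyze_screen, expected_gene_recovery

genome = ToyGenome({"chr1": 40_000_000}, gene_spacing=200_000)
design = build_design({"TSS": 8, "ENH": 6}, 4, 14, genome, target_spacing=2_500_000)
screen = simulate_screen(
    SimulationParams(n_cells=60_000, seed=4), design=design, genome=genome
)
analysis = analyze_screen(screen, seed=4)

e2g = analysis.e2g
sig = e2g[e2g.tier.isin(["high", "medium"])]
print(f"{len(e2g)} target-gene pairs tested, tiers: "
      f"{analysis.summary['tier_counts']}")
cols = ["target_id", "gene_id", "fdr", "tier", "n_supporting_guides",
        "summary_log2fc", "distance_bp", "is_nearest_expressed_gene"]
with pd.option_context("display.float_format", "{:.3g}".format):
    print(sig[cols].head(10).to_string(index=False))

rec = expected_gene_recovery(analysis)
print(f"\nexpected genes recovered (fdr<5%, >=2 guides, negative FC), "
      f"baseline mean >= 2 UMIs/cell: "
      f"{rec['recovery_rate_high_expression']:.0%} of {rec['n_high_expression']}")
# Every medium/high-tier link in this simulation should be a planted
# target-gene pair; misses concentrate in weakly expressed genes and
# weak-effect enhancers, reproducing the power behaviour of real screens.
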