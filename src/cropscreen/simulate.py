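"""Synthetic CROP-seq CRISPRi screens with known ground truth.

Emulates the structure of a pooled low-MOI CRISPRi screen in primary
T cells: a guide library targeting TSSs and non-coding elements plus
non-targeting (NT) controls, lentiviral transduction at low multiplicity
of infection, guide-capture counts contaminated by plasmid-proportional
ambient molecules, and negative-binomial gene expression with per-target
knockdown effects applied to each target's expected gene.

Every stage is deterministic under a fixed seed, and the ground truth
(true integrations per cell, true effect per target-gene pair, per-guide
efficiency) is returned alongside the count matrices so that assignment
and differential-expression calls can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

TARGET_CLASSES = ("TSS", "ENH", "CCRE_INTRONIC", "CCRE_INTERGENIC", "LCR")
NT_CLASS = "NT"

#: Library composition of the reference screen design: 80 targets in five
#: classes, four guides per target, plus 35 non-targeting controls
#: (355 guides total).
REFERENCE_CLASS_COUNTS = {
    "TSS": 35,
    "ENH": 28,
    "CCRE_INTRONIC": 11,
    "CCRE_INTERGENIC": 3,
    "LCR": 3,
}

MITO_CHROM = "chrM"
N_MITO_GENES = 10


@dataclass(frozen=True)
class ToyGenome:
    """A minimal genome model: chromosomes with uniformly spaced gene TSSs.

    Genes alternate strand and are spaced ``gene_spacing`` bp apart, which
    guarantees every placed target has expressed genes both inside and
    outside its +/- 1 Mb testing window.  A small mitochondrial contig with
    ``MT-`` genes is always appended so that QC mito fractions are defined.
    """

    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 250_000_000})
    gene_spacing: int = 50_000

    def annotation(self) -> pd.DataFrame:
        """Gene annotation table: gene_id, chrom, tss (0-based), strand."""
        rows = []
        i = 0
        for chrom, length in self.chrom_lengths.items():
            pos = self.gene_spacing // 2
            while pos < length:
                rows.append((f"G{i:05d}", chrom, pos, "+" if i % 2 == 0 else "-"))
                i += 1
                pos += self.gene_spacing
        for j in range(N_MITO_GENES):
            rows.append((f"MT-{j}", MITO_CHROM, 100 * j, "+"))
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


@dataclass(frozen=True)
class ScreenDesign:
    """Targets and guides of a screen.

    ``targets`` holds one row per genomic target (target_id, target_class,
    chrom, start, end, expected_gene_id); NT controls are not genomic
    targets and appear only in ``guides`` with class ``NT`` and no target
    interval.
    """

    targets: pd.DataFrame
    guides: pd.DataFrame  # guide_id, target_id, target_class
    guides_per_target: int
    n_nt: int

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_guides(self) -> int:
        return len(self.guides)

    @property
    def nt_guide_ids(self) -> list:
        g = self.guides
        return list(g.loc[g.target_class == NT_CLASS, "guide_id"])

    def guides_for_target(self, target_id: str) -> list:
        g = self.guides
        return list(g.loc[g.target_id == target_id, "guide_id"])

    def validate(self) -> None:
        g = self.guides
        if g.guide_id.duplicated().any():
            raise ValueError("duplicate guide ids")
        t = self.targets
        if len(t) and not (t.start < t.end).all():
            raise ValueError("target intervals must satisfy start < end")
        per = g.loc[g.target_class != NT_CLASS].groupby("target_id").size()
        if len(per) and not (per == self.guides_per_target).all():
            raise ValueError("non-NT targets must have exactly guides_per_target guides")


@dataclass(frozen=True)
class GuideLibrary:
    """Plasmid-library representation of each guide.

    ``proportions`` are the expected proportions p_g used as binomial
    success probabilities during assignment; they always sum to 1.
    """

    table: pd.DataFrame  # guide_id, plasmid_count, proportion

    @property
    def guide_ids(self) -> list:
        return list(self.table.guide_id)

    @property
    def proportions(self) -> np.ndarray:
        return self.table.proportion.to_numpy()

    def validate(self) -> None:
        p = self.proportions
        if not np.all(p > 0):
            raise ValueError("all guide proportions must be positive")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("guide proportions must sum to 1")


@dataclass(frozen=True)
class SimulationParams:
    """Tunable knobs of the generator; defaults emulate the study design.

    Units: means are UMIs per cell; knockdowns are fractional reductions
    of the expected gene's mean in [0, 1]; ``moi`` is the Poisson mean
    number of lentiviral integrations per cell.
    """

    n_cells: int = 20_000
    moi: float = 0.3
    ambient_rate: float = 0.05
    guide_umi_mean: float = 25.0
    guide_capture_sigma: float = 0.3
    nb_dispersion: float = 10.0
    expected_gene_mean_range: tuple = (0.2, 8.0)
    bystander_log_mean: float = math.log(0.25)
    bystander_log_sigma: float = 1.0
    knockdown_by_class: dict = field(
        default_factory=lambda: {
            "TSS": 0.31,
            "ENH": 0.20,
            "CCRE_INTRONIC": 0.20,
            "CCRE_INTERGENIC": 0.20,
            "LCR": 0.29,
        }
    )
    knockdown_sigma: float = 0.05
    knockdown_range: tuple = (0.08, 0.60)
    guide_efficiency_beta: tuple = (5.0, 1.0)
    n_batches: int = 2
    batch_effect_scale: float = 0.1
    size_factor_sigma: float = 0.25
    mito_mean_by_batch: tuple = (0.06, 0.08)
    mito_concentration: float = 60.0
    stripped_fraction: float = 0.01
    stripped_mito_mean: float = 0.003
    stripped_size_factor: float = 0.4
    doublet_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.moi < 0:
            raise ValueError("moi must be >= 0")
        if not (0 <= self.ambient_rate < 1):
            raise ValueError("ambient_rate must be in [0, 1)")
        for cls, k in self.knockdown_by_class.items():
            if not (0 <= k <= 1):
                raise ValueError(f"knockdown for {cls} outside [0, 1]")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")


@dataclass
class Infections:
    """Partial ground truth after transduction: who got which guides.

    ``table`` is long-form (cell_index, guide_id), one row per
    integration; ``batch`` assigns each cell to an experiment label.
    """

    n_cells: int
    table: pd.DataFrame  # cell_index, guide_id
    batch: np.ndarray  # str labels, len n_cells

    def guides_per_cell(self) -> pd.Series:
        counts = np.zeros(self.n_cells, dtype=int)
        if len(self.table):
            idx, cnt = np.unique(self.table.cell_index.to_numpy(), return_counts=True)
            counts[idx] = cnt
        return pd.Series(counts)


@dataclass
class GroundTruth:
    """Full ground truth emitted next to the count matrices."""

    cells: pd.DataFrame  # cell_id, batch, guides (';'-joined), n_integrations, is_doublet
    target_effects: pd.DataFrame  # target_id, gene_id, effect
    guide_efficiency: pd.DataFrame  # guide_id, efficiency


@dataclass
class SyntheticScreen:
    """A complete simulated screen: matrices, metadata and ground truth."""

    design: ScreenDesign
    library: GuideLibrary
    annotation: pd.DataFrame
    gene_counts: sp.spmatrix  # genes x cells (CSC)
    guide_counts: sp.spmatrix  # guides x cells (CSR)
    gene_ids: list
    guide_ids: list
    cell_ids: list
    batch: np.ndarray
    truth: GroundTruth
    params: SimulationParams


# ---------------------------------------------------------------------------
# design construction


def build_design(
    class_counts: dict,
    guides_per_target: int = 4,
    n_nt: int = 35,
    genome: ToyGenome | None = None,
    target_spacing: int = 2_000_000,
    target_width: int = 500,
) -> ScreenDesign:
    """Place targets on the toy genome and enumerate their guides.

    Targets are laid out deterministically, ``target_spacing`` bp apart,
    each anchored near a gene TSS so that its *expected gene* falls inside
    the +/- 1 Mb testing window.  TSS-class targets sit exactly on the
    gene's TSS; enhancer-like classes are offset 25 kb upstream.

    Raises ``ValueError`` if the genome cannot hold the requested targets.
    """
    genome = genome or ToyGenome()
    bad = set(class_counts) - set(TARGET_CLASSES)
    if bad:
        raise ValueError(f"unknown target classes: {sorted(bad)}")
    if any(v < 0 for v in class_counts.values()) or guides_per_target < 0 or n_nt < 0:
        raise ValueError("counts must be non-negative")

    ann = genome.annotation()
    nuclear = ann[ann.chrom != MITO_CHROM]

    n_targets = sum(class_counts.values())
    # interleave classes deterministically along the genome
    class_seq = []
    for cls in TARGET_CLASSES:
        class_seq.extend([cls] * class_counts.get(cls, 0))

    target_rows = []
    guide_rows = []
    positions_used = 0
    for chrom, length in genome.chrom_lengths.items():
        chrom_genes = nuclear[nuclear.chrom == chrom].reset_index(drop=True)
        pos = target_spacing
        while pos + target_spacing < length and positions_used < n_targets:
            cls = class_seq[positions_used]
            # anchor to the nearest gene TSS
            gi = int(np.argmin(np.abs(chrom_genes.tss.to_numpy() - pos)))
            gene = chrom_genes.iloc[gi]
            if cls == "TSS":
                start = int(gene.tss)
            else:
                start = max(0, int(gene.tss) - 25_000)
            end = start + target_width
            if abs((start + end) // 2 - gene.tss) > 1_000_000:
                raise ValueError("genome too small: no gene within 1 Mb of target")
            tid = f"{cls}_{positions_used:03d}"
            target_rows.append((tid, cls, chrom, start, end, gene.gene_id))
            for k in range(guides_per_target):
                guide_rows.append((f"{tid}.g{k + 1}", tid, cls))
            positions_used += 1
            pos += target_spacing
        if positions_used >= n_targets:
            break
    if positions_used < n_targets:
        raise ValueError(
            f"genome too small to place {n_targets} targets at {target_spacing} bp spacing"
        )
    for k in range(n_nt):
        guide_rows.append((f"NT.g{k + 1}", "NT", NT_CLASS))

    targets = pd.DataFrame(
        target_rows,
        columns=["target_id", "target_class", "chrom", "start", "end", "expected_gene_id"],
    )
    guides = pd.DataFrame(guide_rows, columns=["guide_id", "target_id", "target_class"])
    design = ScreenDesign(targets, guides, guides_per_target, n_nt)
    design.validate()
    return design


def reference_design(genome: ToyGenome | None = None, target_spacing: int = 2_000_000) -> ScreenDesign:
    """The 80-target / 355-guide reference library layout."""
    return build_design(
        REFERENCE_CLASS_COUNTS, guides_per_target=4, n_nt=35, genome=genome,
        target_spacing=target_spacing,
    )


# ---------------------------------------------------------------------------
# simulation stages


def simulate_plasmid_library(
    design: ScreenDesign, lognormal_sigma: float = 0.5, seed: int = 0
) -> GuideLibrary:
    """Draw plasmid abundances per guide from a lognormal distribution.

    ``lognormal_sigma`` = 0 gives a perfectly uniform library.  Abundances
    are emitted as integer counts (sequencing-read style) at a depth that
    makes rounding error negligible, and normalized to proportions p_g.
    """
    if lognormal_sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    n = design.n_guides
    raw = np.exp(rng.normal(0.0, lognormal_sigma, size=n))
    counts = np.maximum(1, np.round(raw / raw.sum() * n * 100_000).astype(np.int64))
    table = pd.DataFrame(
        {
            "guide_id": design.guides.guide_id.to_numpy(),
            "plasmid_count": counts,
            "proportion": counts / counts.sum(),
        }
    )
    lib = GuideLibrary(table)
    lib.validate()
    return lib


def simulate_infections(
    design: ScreenDesign,
    library: GuideLibrary,
    n_cells: int,
    moi: float = 0.3,
    seed: int = 0,
    n_batches: int = 2,
) -> Infections:
    """Transduce cells at Poisson(``moi``) integrations per cell.

    Guide identities are drawn proportionally to plasmid abundance,
    without replacement within a cell.  Cells are split into ``n_batches``
    contiguous blocks emulating independent experiments.
    """
    if moi < 0:
        raise ValueError("moi must be >= 0")
    rng = np.random.default_rng(seed)
    k = rng.poisson(moi, size=n_cells)
    guide_ids = np.asarray(library.guide_ids)
    p = library.proportions
    cell_col = []
    guide_col = []
    # k == 1 cells vectorized; k >= 2 cells need per-cell sampling without
    # replacement and are rare at low MOI
    ones = np.flatnonzero(k == 1)
    if len(ones):
        draws = rng.choice(len(guide_ids), size=len(ones), p=p)
        cell_col.append(ones)
        guide_col.append(draws)
    for c in np.flatnonzero(k >= 2):
        kk = min(int(k[c]), len(guide_ids))
        draws = rng.choice(len(guide_ids), size=kk, replace=False, p=p)
        cell_col.append(np.full(kk, c))
        guide_col.append(draws)
    if cell_col:
        cell_idx = np.concatenate(cell_col)
        gidx = np.concatenate(guide_col)
        order = np.argsort(cell_idx, kind="stable")
        table = pd.DataFrame(
            {"cell_index": cell_idx[order], "guide_id": guide_ids[gidx[order]]}
        )
    else:
        table = pd.DataFrame({"cell_index": np.array([], dtype=int), "guide_id": []})
    edges = np.linspace(0, n_cells, n_batches + 1).astype(int)
    batch = np.empty(n_cells, dtype=object)
    for b in range(n_batches):
        batch[edges[b] : edges[b + 1]] = f"exp{b + 1}"
    return Infections(n_cells=n_cells, table=table, batch=batch.astype(str))


def simulate_guide_counts(
    infections: Infections,
    library: GuideLibrary,
    params: SimulationParams,
    seed: int = 0,
    capture: np.ndarray | None = None,
) -> sp.csr_matrix:
    """Guide x cell UMI matrix: true signal plus plasmid-proportional ambient.

    A truly present guide yields Poisson(guide_umi_mean * capture_c) UMIs,
    where capture_c ~ lognormal(0, guide_capture_sigma) models cell-to-cell
    guide-transcript recovery efficiency.  Every cell also receives
    Poisson(ambient_rate * guide_umi_mean * capture_c) ambient UMIs
    allocated multinomially by plasmid proportion p_g, emulating ambient
    RNA / PCR background.
    """
    rng = np.random.default_rng(seed)
    n_cells = infections.n_cells
    guide_ids = np.asarray(library.guide_ids)
    gindex = {g: i for i, g in enumerate(guide_ids)}
    if capture is None:
        capture = np.exp(rng.normal(0.0, params.guide_capture_sigma, size=n_cells))

    rows = []
    cols = []
    data = []
    if len(infections.table):
        cidx = infections.table.cell_index.to_numpy()
        gidx = np.array([gindex[g] for g in infections.table.guide_id], dtype=int)
        lam = params.guide_umi_mean * capture[cidx]
        x = rng.poisson(lam)
        keep = x > 0
        rows.append(gidx[keep])
        cols.append(cidx[keep])
        data.append(x[keep])

    amb_total = rng.poisson(params.ambient_rate * params.guide_umi_mean * capture)
    nz = np.flatnonzero(amb_total)
    if len(nz):
        p = library.proportions
        for c in nz:
            alloc = rng.multinomial(amb_total[c], p)
            g = np.flatnonzero(alloc)
            rows.append(g)
            cols.append(np.full(len(g), c))
            data.append(alloc[g])

    if rows:
        mat = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(guide_ids), n_cells),
            dtype=np.int64,
        ).tocsr()
        mat.sum_duplicates()
    else:
        mat = sp.csr_matrix((len(guide_ids), n_cells), dtype=np.int64)
    return mat


def _draw_target_effects(design: ScreenDesign, params: SimulationParams, rng) -> pd.DataFrame:
    t = design.targets
    means = t.target_class.map(params.knockdown_by_class).to_numpy(dtype=float)
    eff = rng.normal(means, params.knockdown_sigma)
    eff = np.clip(eff, *params.knockdown_range)
    return pd.DataFrame(
        {"target_id": t.target_id, "gene_id": t.expected_gene_id, "effect": eff}
    )


def simulate_expression(
    design: ScreenDesign,
    infections: Infections,
    params: SimulationParams,
    seed: int = 0,
    annotation: pd.DataFrame | None = None,
    genome: ToyGenome | None = None,
    null: bool = False,
    _chunk: int = 20_000,
):
    """Gene x cell NB counts with knockdown effects on expected genes.

    Baseline counts are NB(mean mu_g * s_c * b_{g,batch}, dispersion
    theta); for each true integration of a guide g' targeting t, the
    expected gene of t has its mean multiplied by (1 - effect_t * f_g'),
    with f the per-guide efficiency.  ``null=True`` zeroes all effects.

    Returns ``(counts, annotation, target_effects, guide_efficiency,
    mito_fraction_truth)``.
    """
    rng = np.random.default_rng(seed)
    if annotation is None:
        annotation = (genome or ToyGenome()).annotation()
    n_cells = infections.n_cells
    gene_ids = annotation.gene_id.to_numpy()
    n_genes = len(gene_ids)
    is_mito = (annotation.chrom == MITO_CHROM).to_numpy()

    # baseline means: expected genes span a controlled range (log-uniform),
    # bystanders follow a lognormal expression distribution
    lo, hi = params.expected_gene_mean_range
    mu = np.exp(rng.normal(params.bystander_log_mean, params.bystander_log_sigma, n_genes))
    mu = np.clip(mu, 0.01, 20.0)
    expected = design.targets.expected_gene_id.to_numpy() if design.n_targets else []
    gpos = {g: i for i, g in enumerate(gene_ids)}
    exp_idx = np.array([gpos[g] for g in expected], dtype=int)
    if len(exp_idx):
        mu[exp_idx] = np.exp(rng.uniform(math.log(lo), math.log(hi), size=len(exp_idx)))
    mu[is_mito] = 0.0  # mito counts are added from the per-cell mito fraction

    # batch effects: per-gene lognormal fold changes per batch
    batches = sorted(set(infections.batch))
    bfac = {
        b: np.exp(rng.normal(0.0, params.batch_effect_scale, size=n_genes))
        for b in batches
    }
    batch_codes = np.searchsorted(np.array(batches), infections.batch)

    # per-cell size factors; stripped nuclei get shrunken size factors
    s = np.exp(rng.normal(0.0, params.size_factor_sigma, size=n_cells))
    stripped = rng.random(n_cells) < params.stripped_fraction
    s[stripped] *= params.stripped_size_factor

    # per-cell mito fraction from batch-specific Beta distributions
    conc = params.mito_concentration
    mito_f = np.empty(n_cells)
    for bi, b in enumerate(batches):
        m = params.mito_mean_by_batch[bi % len(params.mito_mean_by_batch)]
        sel = infections.batch == b
        mito_f[sel] = rng.beta(m * conc, (1 - m) * conc, size=int(sel.sum()))
    ms = params.stripped_mito_mean
    if stripped.any():
        mito_f[stripped] = rng.beta(ms * conc, (1 - ms) * conc, size=int(stripped.sum()))

    # knockdown ground truth
    effects = _draw_target_effects(design, params, rng)
    a, b_ = params.guide_efficiency_beta
    g_eff = pd.DataFrame(
        {
            "guide_id": design.guides.guide_id.to_numpy(),
            "efficiency": rng.beta(a, b_, size=design.n_guides),
        }
    )
    if null:
        effects = effects.assign(effect=0.0)

    # per-cell multiplicative knockdown on the expected gene of each
    # integrated guide
    kd_cell = []  # (cell, gene_idx, factor)
    if len(infections.table) and len(exp_idx) and not null:
        eff_by_target = dict(zip(effects.target_id, effects.effect))
        gene_by_target = dict(zip(design.targets.target_id, design.targets.expected_gene_id))
        f_by_guide = dict(zip(g_eff.guide_id, g_eff.efficiency))
        t_by_guide = dict(zip(design.guides.guide_id, design.guides.target_id))
        for c, gid in zip(
            infections.table.cell_index.to_numpy(), infections.table.guide_id.to_numpy()
        ):
            t = t_by_guide[gid]
            if t == "NT":
                continue
            factor = 1.0 - eff_by_target[t] * f_by_guide[gid]
            kd_cell.append((c, gpos[gene_by_target[t]], factor))
    kd = pd.DataFrame(kd_cell, columns=["cell", "gene", "factor"]) if kd_cell else None

    theta = params.nb_dispersion
    nuc_idx = np.flatnonzero(~is_mito)
    mu_nuc = mu[nuc_idx]
    total_nuc_mean = mu_nuc.sum()

    mito_rows = np.flatnonzero(is_mito)
    bfac_nuc = np.stack([bfac[b][nuc_idx] for b in batches], axis=1)
    blocks = []
    for start in range(0, n_cells, _chunk):
        stop = min(start + _chunk, n_cells)
        cells = np.arange(start, stop)
        mean = mu_nuc[:, None] * s[cells][None, :] * bfac_nuc[:, batch_codes[cells]]
        if kd is not None:
            sel = kd[(kd.cell >= start) & (kd.cell < stop)]
            for c, g, f in zip(sel.cell, sel.gene, sel.factor):
                gi = np.searchsorted(nuc_idx, g)
                mean[gi, c - start] *= f
        block = np.zeros((n_genes, stop - start), dtype=np.int32)
        block[nuc_idx] = rng.negative_binomial(theta, theta / (theta + mean))
        # mito counts: expected mito total tuned to hit the target fraction
        mito_mean_total = total_nuc_mean * s[cells] * mito_f[cells] / (1 - mito_f[cells])
        per_gene = mito_mean_total / N_MITO_GENES
        block[mito_rows] = rng.poisson(np.tile(per_gene, (N_MITO_GENES, 1)))
        blocks.append(sp.csc_matrix(block))

    if blocks:
        counts = sp.hstack(blocks, format="csc", dtype=np.int32)
    else:
        counts = sp.csc_matrix((n_genes, 0), dtype=np.int32)
    return counts, annotation, effects, g_eff, mito_f


def simulate_screen(
    params: SimulationParams | None = None,
    design: ScreenDesign | None = None,
    genome: ToyGenome | None = None,
    library_sigma: float = 0.5,
    null: bool = False,
) -> SyntheticScreen:
    """Run all stages and fold in doublets; fully seeded by ``params.seed``.

    Doublets are emulated by simulating ``doublet_rate * n_cells`` extra
    phantom cells and summing each one's gene and guide columns into a
    randomly chosen host cell, so emitted matrices keep exactly
    ``n_cells`` columns.
    """
    params = params or SimulationParams()
    params.validate()
    genome = genome or ToyGenome()
    design = design or reference_design(genome)
    root = np.random.default_rng(params.seed)
    seeds = root.integers(0, 2**31 - 1, size=5)

    library = simulate_plasmid_library(design, library_sigma, seed=int(seeds[0]))
    n_doub = int(round(params.doublet_rate * params.n_cells))
    n_total = params.n_cells + n_doub
    inf = simulate_infections(
        design, library, n_total, params.moi, seed=int(seeds[1]), n_batches=params.n_batches
    )
    # phantom cells inherit the batch of their host so doublets stay
    # within-batch
    host = np.random.default_rng(int(seeds[2])).choice(params.n_cells, size=n_doub, replace=False)
    inf.batch[params.n_cells :] = inf.batch[host]

    guide_counts = simulate_guide_counts(inf, library, params, seed=int(seeds[3]))
    gene_counts, annotation, effects, g_eff, mito_f = simulate_expression(
        design, inf, params, seed=int(seeds[4]), genome=genome, null=null
    )

    # fold phantom columns into hosts
    owner = np.arange(n_total)
    owner[params.n_cells :] = host
    if n_doub:
        fold = sp.coo_matrix(
            (np.ones(n_total, dtype=np.int32), (np.arange(n_total), owner)),
            shape=(n_total, params.n_cells),
        ).tocsc()
        guide_counts = (guide_counts @ fold).tocsr()
        gene_counts = sp.csc_matrix(gene_counts @ fold)

    is_doublet = np.zeros(params.n_cells, dtype=bool)
    is_doublet[host] = True

    per_cell_guides = [[] for _ in range(params.n_cells)]
    for c, gid in zip(inf.table.cell_index.to_numpy(), inf.table.guide_id.to_numpy()):
        per_cell_guides[owner[c]].append(gid)

    cell_ids = [f"CELL_{i:06d}" for i in range(params.n_cells)]
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "batch": inf.batch[: params.n_cells],
            "guides": [";".join(g) for g in per_cell_guides],
            "n_integrations": [len(g) for g in per_cell_guides],
            "is_doublet": is_doublet,
        }
    )
    truth = GroundTruth(cells=cells, target_effects=effects, guide_efficiency=g_eff)
    return SyntheticScreen(
        design=design,
        library=library,
        annotation=annotation,
        gene_counts=gene_counts,
        guide_counts=guide_counts,
        gene_ids=list(annotation.gene_id),
        guide_ids=library.guide_ids,
        cell_ids=cell_ids,
        batch=inf.batch[: params.n_cells].copy(),
        truth=truth,
        params=params,
    )


def null_screen(params: SimulationParams | None = None, **kw) -> SyntheticScreen:
    """A screen with every knockdown effect forced to zero."""
    return simulate_screen(params, null=True, **kw)
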