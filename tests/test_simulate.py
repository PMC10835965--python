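"""Generator correctness: design arithmetic, noise models, determinism."""

import math

import numpy as np
import pytest

from cropscreen import (
    REFERENCE_CLASS_COUNTS,
    SimulationParams,
    ToyGenome,
    build_design,
    reference_design,
    simulate_expression,
    simulate_guide_counts,
    simulate_infections,
    simulate_plasmid_library,
    simulate_screen,
)
from cropscreen.simulate import Infections
import pandas as pd


class TestBuildDesign:
    @pytest.mark.parametrize(
        "counts, gpt, n_nt, exp_targets, exp_guides",
        [
            (REFERENCE_CLASS_COUNTS, 4, 35, 80, 355),
            ({}, 4, 0, 0, 0),
            ({"TSS": 2}, 4, 1, 2, 9),
        ],
    )
    def test_guide_and_target_counts(self, counts, gpt, n_nt, exp_targets, exp_guides):
        d = build_design(counts, gpt, n_nt)
        assert d.n_targets == exp_targets
        # count by enumerating emitted guide rows
        assert len(d.guides.guide_id) == exp_guides
        assert d.guides.guide_id.is_unique

    def test_expected_gene_within_window(self):
        d = reference_design()
        ann = ToyGenome().annotation().set_index("gene_id")
        for _, t in d.targets.iterrows():
            tss = ann.loc[t.expected_gene_id, "tss"]
            mid = (t.start + t.end) // 2
            assert abs(tss - mid) <= 1_000_000

    def test_nt_guides_have_nt_class(self):
        d = build_design({"TSS": 1}, 4, 3)
        nt = d.guides[d.guides.target_class == "NT"]
        assert len(nt) == 3
        assert set(nt.target_id) == {"NT"}

    def test_genome_too_small(self):
        tiny = ToyGenome({"chr1": 1_000_000}, gene_spacing=50_000)
        with pytest.raises(ValueError, match="small"):
            build_design({"TSS": 30}, 4, 0, tiny)


class TestPlasmidLibrary:
    def test_sigma_zero_is_uniform(self):
        d = build_design({"TSS": 2}, 4, 1)
        lib = simulate_plasmid_library(d, 0.0, seed=0)
        np.testing.assert_allclose(lib.proportions, 1 / 9, rtol=1e-9)

    def test_cv_matches_lognormal(self):
        d = reference_design()
        lib = simulate_plasmid_library(d, 0.5, seed=1)
        p = lib.proportions
        cv = p.std() / p.mean()
        expected = math.sqrt(math.exp(0.25) - 1)
        assert abs(cv - expected) / expected < 0.15

    def test_deterministic(self):
        d = build_design({"TSS": 3}, 4, 2)
        a = simulate_plasmid_library(d, 0.5, seed=7)
        b = simulate_plasmid_library(d, 0.5, seed=7)
        np.testing.assert_array_equal(a.proportions, b.proportions)

    def test_proportions_sum_to_one(self):
        d = reference_design()
        lib = simulate_plasmid_library(d, 1.0, seed=2)
        assert abs(lib.proportions.sum() - 1) < 1e-12
        assert (lib.proportions > 0).all()


class TestInfections:
    def test_moi_zero(self):
        d = build_design({"TSS": 2}, 4, 1)
        lib = simulate_plasmid_library(d, 0.0, seed=0)
        inf = simulate_infections(d, lib, 500, moi=0.0, seed=0)
        assert len(inf.table) == 0

    def test_single_guide_fraction_closed_form(self):
        """At MOI lambda the single-integration share of infected cells is
        lambda e^-lambda / (1 - e^-lambda)."""
        d = reference_design()
        lib = simulate_plasmid_library(d, 0.5, seed=1)
        n = 100_000
        lam = 0.3
        inf = simulate_infections(d, lib, n, moi=lam, seed=11)
        per_cell = inf.guides_per_cell().to_numpy()
        infected = per_cell > 0
        frac = (per_cell == 1).sum() / infected.sum()
        expect = lam * math.exp(-lam) / (1 - math.exp(-lam))
        sd = math.sqrt(expect * (1 - expect) / infected.sum())
        assert abs(frac - expect) < 3 * sd

    def test_high_moi_mean(self):
        d = reference_design()
        lib = simulate_plasmid_library(d, 0.0, seed=1)
        inf = simulate_infections(d, lib, 20_000, moi=5.0, seed=5)
        mean = inf.guides_per_cell().mean()
        assert abs(mean - 5.0) < 3 * math.sqrt(5.0 / 20_000)

    def test_no_duplicate_guides_within_cell(self):
        d = build_design({"TSS": 2}, 4, 1)
        lib = simulate_plasmid_library(d, 0.0, seed=0)
        inf = simulate_infections(d, lib, 2_000, moi=3.0, seed=2)
        dup = inf.table.groupby(["cell_index", "guide_id"]).size()
        assert (dup == 1).all()


class TestGuideCounts:
    def _two_guide_setup(self):
        d = build_design({"TSS": 1}, 1, 1)  # 2 guides total
        lib = d.guides.assign(plasmid_count=[9000, 1000], proportion=[0.9, 0.1])
        from cropscreen.simulate import GuideLibrary

        return d, GuideLibrary(lib[["guide_id", "plasmid_count", "proportion"]])

    def test_uninfected_no_ambient_all_zero(self):
        d, lib = self._two_guide_setup()
        inf = Infections(100, pd.DataFrame({"cell_index": [], "guide_id": []}),
                         np.repeat("exp1", 100))
        params = SimulationParams(ambient_rate=0.0)
        mat = simulate_guide_counts(inf, lib, params, seed=0)
        assert mat.nnz == 0

    def test_ambient_allocated_by_plasmid_proportion(self):
        d, lib = self._two_guide_setup()
        n = 10_000
        inf = Infections(n, pd.DataFrame({"cell_index": [], "guide_id": []}),
                         np.repeat("exp1", n))
        params = SimulationParams(ambient_rate=0.05, guide_umi_mean=25.0)
        mat = simulate_guide_counts(inf, lib, params, seed=4)
        totals = np.asarray(mat.sum(axis=1)).ravel()
        share = totals[0] / totals.sum()
        assert abs(share - 0.9) < 0.02

    def test_deterministic(self, small_screen):
        params = small_screen.params
        scr2 = simulate_screen(params, design=small_screen.design,
                               genome=ToyGenome({"chr1": 30_000_000}, 200_000))
        assert (small_screen.guide_counts != scr2.guide_counts).nnz == 0
        assert (small_screen.gene_counts != scr2.gene_counts).nnz == 0


class TestExpression:
    def _one_target(self):
        genome = ToyGenome({"chr1": 10_000_000}, gene_spacing=200_000)
        design = build_design({"TSS": 1}, 1, 0, genome, target_spacing=2_500_000)
        return genome, design

    def test_knockdown_halves_mean(self):
        """e = 0.5 with full guide efficiency halves the NB mean."""
        genome, design = self._one_target()
        n = 2_000
        # 300 perturbed cells, the rest uninfected
        table = pd.DataFrame(
            {"cell_index": np.arange(300), "guide_id": [design.guides.guide_id[0]] * 300}
        )
        inf = Infections(n, table, np.repeat("exp1", n))
        params = SimulationParams(
            knockdown_by_class={"TSS": 0.5}, knockdown_sigma=0.0,
            knockdown_range=(0.5, 0.5), guide_efficiency_beta=(1e7, 1e-3),
            expected_gene_mean_range=(5.0, 5.0), size_factor_sigma=0.0,
            batch_effect_scale=0.0, n_batches=1, stripped_fraction=0.0,
        )
        counts, ann, effects, geff, _ = simulate_expression(
            design, inf, params, seed=9, genome=genome
        )
        gi = list(ann.gene_id).index(design.targets.expected_gene_id.iloc[0])
        pert = counts[gi, :300].mean()
        ctrl = counts[gi, 300:].mean()
        assert effects.effect.iloc[0] == 0.5
        assert abs(pert / ctrl - 0.5) < 0.05

    def test_no_batch_effect_when_scale_zero(self):
        genome, design = self._one_target()
        inf = Infections(4_000, pd.DataFrame({"cell_index": [], "guide_id": []}),
                         np.r_[np.repeat("exp1", 2000), np.repeat("exp2", 2000)])
        params = SimulationParams(batch_effect_scale=0.0, size_factor_sigma=0.0,
                                  stripped_fraction=0.0)
        counts, ann, *_ = simulate_expression(design, inf, params, seed=1, genome=genome)
        nuclear = np.asarray([c != "chrM" for c in ann.chrom])
        m1 = counts[nuclear][:, :2000].sum() / 2000
        m2 = counts[nuclear][:, 2000:].sum() / 2000
        assert abs(m1 - m2) / m1 < 0.02

    def test_null_screen_has_no_effects(self, small_genome, small_design):
        from cropscreen import null_screen

        scr = null_screen(SimulationParams(n_cells=500, seed=5),
                          design=small_design, genome=small_genome)
        assert (scr.truth.target_effects.effect == 0).all()


class TestScreenInvariants:
    def test_matrix_dimensions_match_design(self, small_screen):
        p = small_screen.params
        assert small_screen.gene_counts.shape[1] == p.n_cells
        assert small_screen.guide_counts.shape == (small_screen.design.n_guides, p.n_cells)
        assert small_screen.gene_counts.shape[0] == len(small_screen.annotation)

    def test_doublets_marked_in_truth(self, small_screen):
        t = small_screen.truth.cells
        rate = t.is_doublet.mean()
        assert 0.03 < rate < 0.07

    def test_ground_truth_consistent(self, small_screen):
        t = small_screen.truth
        assert len(t.cells) == small_screen.params.n_cells
        assert len(t.target_effects) == small_screen.design.n_targets
        assert len(t.guide_efficiency) == small_screen.design.n_guides
        assert t.target_effects.effect.between(0, 1).all()
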