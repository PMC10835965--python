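"""Hurdle-model DE: fitting correctness, calibration, and helpers."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import optimize, stats
from scipy.linalg import lstsq as sla_lstsq

from cropscreen import (
    TargetSpec,
    build_dataset,
    compute_cdr,
    detection_filter,
    genes_in_window,
    normalize_log,
    run_de,
    select_nt_background,
    single_assignment,
)
from cropscreen.de import (
    RIDGE,
    hurdle_lrt_single_gene,
    wilcoxon_single_gene,
)


class TestDetectionFilter:
    def test_boundary_is_strict_at_five_percent(self):
        n = 10_000
        row = np.zeros((1, n))
        row[0, :490] = 1  # 4.9%
        assert not detection_filter(sp.csr_matrix(row), 0.05)[0]
        row[0, :500] = 1  # exactly 5%
        assert detection_filter(sp.csr_matrix(row), 0.05)[0]

    def test_ubiquitous_gene_included(self):
        mat = sp.csr_matrix(np.ones((1, 50)))
        assert detection_filter(mat)[0]

    def test_matches_hand_enumeration(self):
        rng = np.random.default_rng(0)
        fracs = rng.uniform(0, 1, 20)
        n = 200
        mat = np.zeros((20, n))
        for i, f in enumerate(fracs):
            mat[i, : int(round(f * n))] = 1
        got = detection_filter(sp.csr_matrix(mat), 0.25)
        want = np.array([int(round(f * n)) >= 0.25 * n for f in fracs])
        np.testing.assert_array_equal(got, want)


class TestNormalize:
    def test_equal_totals_unit_factors(self):
        mat = sp.csr_matrix(np.array([[2, 4], [4, 2]]))
        norm = normalize_log(mat)
        np.testing.assert_allclose(norm.size_factors, [1.0, 1.0])
        np.testing.assert_allclose(
            norm.matrix.toarray(), np.log2(1 + mat.toarray()), rtol=1e-6
        )

    def test_depth_scaling_cancels(self):
        base = np.array([[4.0, 4.0], [6.0, 6.0]])
        doubled = base.copy()
        doubled[:, 1] *= 2
        norm = normalize_log(sp.csr_matrix(doubled))
        got = norm.matrix.toarray()
        # cell 1 has double depth, so its size factor doubles and the
        # normalized values match cell 0 exactly
        np.testing.assert_allclose(got[:, 0], got[:, 1], rtol=1e-6)

    def test_zero_total_cell_errors(self):
        mat = sp.csr_matrix(np.array([[1, 0], [1, 0]]))
        with pytest.raises(ValueError, match="zero totals"):
            normalize_log(mat)


class TestCDR:
    def test_arithmetic(self):
        # 3 tested genes; detection fractions 1, 1/3, 1/3 -> standardized
        mat = sp.csr_matrix(np.array([[1, 1, 0], [1, 0, 1], [1, 0, 0]]))
        tested = np.array([True, True, True])
        got = compute_cdr(mat, tested)
        frac = np.array([1.0, 1 / 3, 1 / 3])
        want = (frac - frac.mean()) / frac.std()
        np.testing.assert_allclose(got, want)

    def test_constant_rate_dropped_with_warning(self):
        mat = sp.csr_matrix(np.ones((4, 10)))
        with pytest.warns(UserWarning, match="zero variance"):
            got = compute_cdr(mat, np.ones(4, dtype=bool))
        np.testing.assert_array_equal(got, np.zeros(10))


class TestBackground:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["cell_index", "guide_id", "assigned"]).assign(
            x=5, n=10, p_raw=0.0, p_adj=0.0
        )

    def test_multi_assignment_with_targeting_guide_excluded(self):
        table = self._table(
            [(0, "NT.g1", True), (1, "NT.g1", True), (1, "TSS_0.g1", True), (2, "TSS_0.g1", True)]
        )
        single = single_assignment(table, 4)
        bg = select_nt_background(single, ["NT.g1"], n=10, seed=0)
        assert bg.tolist() == [0]  # cell 1 is multi, cell 2 targeting, cell 3 empty

    def test_exhaustion_returns_all_with_warning(self):
        table = self._table([(i, "NT.g1", True) for i in range(10)])
        single = single_assignment(table, 10)
        with pytest.warns(UserWarning, match="eligible"):
            bg = select_nt_background(single, ["NT.g1"], n=5000, seed=1)
        assert len(bg) == 10

    def test_seeded_and_reproducible(self):
        table = self._table([(i, "NT.g1", True) for i in range(200)])
        single = single_assignment(table, 200)
        a = select_nt_background(single, ["NT.g1"], n=50, seed=3)
        b = select_nt_background(single, ["NT.g1"], n=50, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_no_eligible_cells_errors(self):
        single = np.array(["", ""], dtype=object)
        with pytest.raises(ValueError, match="non-targeting"):
            select_nt_background(single, ["NT.g1"])


class TestGenesInWindow:
    ANN = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "d"],
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "tss": [0, 1_000_000, 2_500_000, 1_050_000],
            "strand": ["+", "-", "+", "+"],
        }
    )

    def test_closed_boundary_inclusive(self):
        # window [start - 1 Mb, end + 1 Mb]; gene a sits exactly on the edge
        got = genes_in_window("chr1", 1_000_000, 1_000_100, self.ANN)
        assert got == ["a", "b"]

    def test_other_chromosome_excluded(self):
        got = genes_in_window("chr1", 1_000_000, 1_000_100, self.ANN)
        assert "d" not in got

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="chrX"):
            genes_in_window("chrX", 0, 100, self.ANN)

    def test_tested_intersection_and_enumeration(self):
        got = genes_in_window("chr1", 0, 3_000_000, self.ANN, tested_gene_ids=["c", "a"])
        assert got == ["a", "c"]


def _twelve_cell_fixture():
    """Hand-coded 12-cell, 2-guide design for the ML oracle check."""
    counts = np.array([2, 3, 1, 1, 2, 4, 0, 1, 0, 2, 1, 3], dtype=float)
    z = np.log2(1 + counts)
    group_ids = np.array([0, 0, 0, 1, 1, 1, -1, -1, -1, -1, -1, -1])
    batch = np.zeros(12, dtype=int)
    cdr = np.linspace(-1.2, 1.2, 12)
    return counts, z, group_ids, batch, cdr


def _oracle_lr(counts, z, group_ids, cdr, drop_guide):
    """Independent maximum-likelihood oracle via a generic optimizer."""
    det = (counts > 0).astype(float)
    X_full = np.column_stack(
        [np.ones(12), (group_ids == 0).astype(float), (group_ids == 1).astype(float), cdr]
    )
    keep = [j for j in range(4) if j != drop_guide + 1]
    X_red = X_full[:, keep]

    def nll(beta, X, ridge_cols):
        eta = X @ beta
        pen = 0.5 * RIDGE * sum(beta[j] ** 2 for j in ridge_cols)
        return -(det @ eta - np.logaddexp(0, eta).sum()) + pen

    def fit(X, ridge_cols):
        res = optimize.minimize(
            nll, np.zeros(X.shape[1]), args=(X, ridge_cols), method="BFGS",
            options={"gtol": 1e-12, "maxiter": 500},
        )
        return -res.fun

    llf = fit(X_full, [1, 2])
    llr = fit(X_red, [j for j, orig in enumerate(keep) if orig in (1, 2)])
    lr_disc = 2 * (llf - llr)

    det_mask = det > 0
    n_det = det_mask.sum()

    def rss(X):
        beta = sla_lstsq(X[det_mask], z[det_mask])[0]
        r = z[det_mask] - X[det_mask] @ beta
        return float(r @ r)

    lr_cont = n_det * np.log(rss(X_red) / rss(X_full))
    return lr_disc + lr_cont


class TestHurdleModel:
    def test_lr_statistic_matches_ml_oracle(self):
        counts, z, group_ids, batch, cdr = _twelve_cell_fixture()
        rows = hurdle_lrt_single_gene(counts, z, group_ids, ["gA", "gB"], batch, cdr)
        for g, row in enumerate(rows):
            stat_impl = stats.chi2.isf(row["p_raw"], 2)
            stat_oracle = _oracle_lr(counts, z, group_ids, cdr, g)
            assert stat_impl == pytest.approx(stat_oracle, abs=1e-6)

    def test_location_invariance_of_continuous_component(self):
        counts, z, group_ids, batch, cdr = _twelve_cell_fixture()
        a = hurdle_lrt_single_gene(counts, z, group_ids, ["gA", "gB"], batch, cdr)
        b = hurdle_lrt_single_gene(counts, z + 2.5, group_ids, ["gA", "gB"], batch, cdr)
        for ra, rb in zip(a, b):
            assert ra["p_raw"] == pytest.approx(rb["p_raw"], abs=1e-9)

    def test_zero_cell_guide_flagged_na(self):
        counts, z, group_ids, batch, cdr = _twelve_cell_fixture()
        rows = hurdle_lrt_single_gene(
            counts, z, group_ids, ["gA", "gB", "ghost"], batch, cdr
        )
        ghost = rows[2]
        assert np.isnan(ghost["p_raw"]) and ghost["flag"] == "no_cells"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_detects_planted_fifty_percent_knockdown(self, seed):
        """300 perturbed cells at 50% knockdown of a 5-UMI gene versus a
        2,000-cell background: overwhelming evidence, strong negative FC."""
        rng = np.random.default_rng(seed)
        n_p, n_b = 300, 2000
        theta = 10.0
        mu = np.r_[np.full(n_p, 2.5), np.full(n_b, 5.0)]
        counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
        z = np.log2(1 + counts)
        group_ids = np.r_[np.zeros(n_p, dtype=int), np.full(n_b, -1)]
        batch = np.r_[np.zeros(1150, dtype=int), np.ones(1150, dtype=int)]
        cdr = rng.normal(size=n_p + n_b)
        row = hurdle_lrt_single_gene(counts, z, group_ids, ["g"], batch, cdr)[0]
        assert row["p_raw"] < 1e-6
        assert row["log2fc"] < -0.5

    def test_null_pvalues_roughly_uniform(self, small_screen):
        """NT pseudo-guides run through the full DE path give near-uniform
        p-values."""
        scr = small_screen
        from cropscreen import assign_guides

        table = assign_guides(scr.guide_counts, scr.library)
        single = single_assignment(table, scr.params.n_cells)
        data = build_dataset(scr.gene_counts, scr.gene_ids, scr.batch)
        nt = scr.design.nt_guide_ids
        bg = select_nt_background(single, nt, 5000, seed=0)
        spec = TargetSpec("NT_PSEUDO", nt[:4], list(data.tested_gene_ids[:60]))
        de = run_de(data, [spec], single, bg)
        p = de.p_raw.dropna().to_numpy()
        assert len(p) >= 200
        frac = (p < 0.05).mean()
        assert frac < 0.12
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.12


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        z = np.ones(20)
        group_ids = np.r_[np.zeros(10, dtype=int), np.full(10, -1)]
        row = wilcoxon_single_gene(z, group_ids, ["g"], np.zeros(20, dtype=int))[0]
        assert row["p_raw"] == 1.0

    def test_shifted_distributions_significant(self):
        rng = np.random.default_rng(1)
        z = np.r_[rng.normal(0, 1, 200), rng.normal(1, 1, 200)]
        group_ids = np.r_[np.zeros(200, dtype=int), np.full(200, -1)]
        batch = np.tile([0, 1], 200)
        row = wilcoxon_single_gene(z, group_ids, ["g"], batch)[0]
        assert row["p_raw"] < 1e-4

    def test_single_batch_equals_textbook_ranksum(self):
        # x = (1,2,3) vs y = (4,5,6): W = 6, E = 10.5, Var = 5.25
        z = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        group_ids = np.array([0, 0, 0, -1, -1, -1])
        row = wilcoxon_single_gene(z, group_ids, ["g"], np.zeros(6, dtype=int))[0]
        zstat = (6 - 10.5) / np.sqrt(5.25)
        want = 2 * stats.norm.sf(abs(zstat))
        assert row["p_raw"] == pytest.approx(want, rel=1e-12)

    def test_small_group_is_na(self):
        z = np.arange(5, dtype=float)
        group_ids = np.array([0, -1, -1, -1, -1])
        row = wilcoxon_single_gene(z, group_ids, ["g"], np.zeros(5, dtype=int))[0]
        assert np.isnan(row["p_raw"])


class TestPowerMonotonicity:
    def test_power_rises_with_expression_and_effect(self):
        """Detection power grows with baseline mean and with knockdown size."""
        rng = np.random.default_rng(7)
        theta = 10.0
        n_p, n_b = 200, 1000

        def reject_rate(mu, effect, reps=20):
            hits = 0
            for _ in range(reps):
                m = np.r_[np.full(n_p, mu * (1 - effect)), np.full(n_b, mu)]
                counts = rng.negative_binomial(theta, theta / (theta + m)).astype(float)
                z = np.log2(1 + counts)
                gid = np.r_[np.zeros(n_p, dtype=int), np.full(n_b, -1)]
                row = hurdle_lrt_single_gene(
                    counts, z, gid, ["g"], np.zeros(n_p + n_b, dtype=int),
                    rng.normal(size=n_p + n_b),
                )[0]
                hits += row["p_raw"] < 0.05
            return hits / reps

        low_expr = reject_rate(0.2, 0.3)
        high_expr = reject_rate(5.0, 0.3)
        weak = reject_rate(2.0, 0.05)
        strong = reject_rate(2.0, 0.4)
        assert high_expr >= low_expr
        assert strong >= weak
        assert high_expr > 0.9 and strong > 0.9
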