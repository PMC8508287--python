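from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from polyti.simulate import SimConfig, simulate_counts, simulate_gene_truth
from polyti.translatome import test_ti as ti_permutation_test
from polyti.translatome import (
    DesignError,
    TIConfig,
    adjust_fdr,
    classify_translational,
    compute_ti,
    estimate_size_factors,
    filter_expressed,
    normalized_counts,
    run_translatome,
)

from conftest import make_dataset, make_sheet


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Textbook Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


def interaction_oracle(norm_cyto, cyto_is_t, norm_poly, poly_is_t):
    """Brute-force exhaustive permutation p for one gene's log2 TI statistic."""

    def log_ratio(vals, mask):
        return np.log2(vals[mask].mean()) - np.log2(vals[~mask].mean())

    def stat(mask_c, mask_p):
        return log_ratio(norm_poly, mask_p) - log_ratio(norm_cyto, mask_c)

    obs = abs(stat(cyto_is_t, poly_is_t))
    count = total = 0
    for idx_c in combinations(range(len(cyto_is_t)), int(cyto_is_t.sum())):
        mask_c = np.zeros(len(cyto_is_t), dtype=bool)
        mask_c[list(idx_c)] = True
        for idx_p in combinations(range(len(poly_is_t)), int(poly_is_t.sum())):
            mask_p = np.zeros(len(poly_is_t), dtype=bool)
            mask_p[list(idx_p)] = True
            total += 1
            if abs(stat(mask_c, mask_p)) >= obs - 1e-12:
                count += 1
    return count / total


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [20], [30]], (1, 4)),
                              columns=list("abcd"))
        np.testing.assert_allclose(estimate_size_factors(counts), 1.0)

    def test_doubled_column_hand_computation(self):
        # col2 = 2 * col1 over 3 genes: median ratios 1/sqrt2 and sqrt2,
        # already at geometric mean 1
        counts = pd.DataFrame({"s1": [10, 20, 40], "s2": [20, 40, 80]})
        factors = estimate_size_factors(counts)
        np.testing.assert_allclose(factors, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_single_sample_unit_factor(self):
        counts = pd.DataFrame({"only": [5, 0, 7]})
        np.testing.assert_allclose(estimate_size_factors(counts), [1.0])

    def test_all_zero_reference_rejected(self):
        counts = pd.DataFrame({"s1": [0, 3], "s2": [4, 0]})
        with pytest.raises(DesignError):
            estimate_size_factors(counts)

    def test_rescaling_one_column_leaves_ti_invariant(self, small_dataset):
        ti_before = compute_ti(small_dataset)["log2_ti"]
        scaled = small_dataset.counts.copy()
        scaled.iloc[:, 3] *= 7
        rescaled = make_dataset(scaled.to_numpy(), replicates=2,
                                genes=list(scaled.index))
        ti_after = compute_ti(rescaled)["log2_ti"]
        assert np.abs(ti_after - ti_before).max() < 1e-6


# ---------------------------------------------------------------------------
# filtering and the statistic
# ---------------------------------------------------------------------------

class TestFilterAndTI:
    def test_gene_absent_from_one_group_excluded(self):
        counts = np.full((2, 8), 50)
        counts[0, 6:8] = 0  # poly_T replicates
        dataset = make_dataset(counts)
        kept = filter_expressed(dataset, TIConfig())
        assert list(kept) == ["g1"]

    def test_threshold_boundary_inclusive(self):
        sheet = make_sheet(1)
        # one sample per group; normalized means equal raw counts only if
        # factors are 1, so use the normalized= hook with explicit values
        norm = pd.DataFrame([[12, 11, 15, 10]], index=["g"],
                            columns=sheet.index, dtype=float)
        counts = norm.astype(np.int64)
        from polyti.io import CountDataset

        dataset = CountDataset(counts=counts, sheet=sheet)
        kept = filter_expressed(dataset, TIConfig(expression_min_mean=10.0),
                                normalized=norm)
        assert list(kept) == ["g"]

    def test_equal_group_means_give_zero_log2ti(self):
        dataset = make_dataset(np.full((3, 8), 100))
        ti = compute_ti(dataset)
        np.testing.assert_allclose(ti["log2_ti"], 0.0, atol=1e-12)

    def test_hand_computed_ratio(self):
        sheet = make_sheet(1)
        norm = pd.DataFrame([[10, 10, 5, 20]], index=["g"],
                            columns=sheet.index, dtype=float)
        dataset = make_dataset(norm.to_numpy(), replicates=1, genes=["g"])
        ti = compute_ti(dataset, normalized=norm)
        # x1 = poly_T/cyto_T = 20/10, x2 = poly_NT/cyto_NT = 5/10 -> TI = 4
        assert ti.loc["g", "x1"] == pytest.approx(2.0)
        assert ti.loc["g", "x2"] == pytest.approx(0.5)
        assert ti.loc["g", "log2_ti"] == pytest.approx(2.0)

    def test_zero_mean_flagged_not_infinite(self):
        counts = np.full((2, 8), 50)
        counts[0, 6:8] = 0  # poly_T mean 0; second gene anchors normalization
        dataset = make_dataset(counts)
        ti = compute_ti(dataset)
        assert np.isnan(ti["log2_ti"].iloc[0])
        assert np.isfinite(ti["log2_ti"].iloc[1])


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

class TestPermutation:
    @pytest.mark.parametrize("replicates", [2, 3])
    def test_matches_brute_force_oracle(self, replicates, rng):
        counts = rng.poisson(150, size=(12, 8 * replicates // 2))
        dataset = make_dataset(counts, replicates=replicates)
        cfg = TIConfig(seed=0)
        genes = list(dataset.genes)
        p = ti_permutation_test(dataset, genes, cfg)
        norm = normalized_counts(dataset)
        cyto = dataset.columns_for("cytoplasmic")
        poly = dataset.columns_for("polysomal")
        cyto_is_t = (dataset.sheet.loc[cyto, "condition"] == "T").to_numpy()
        poly_is_t = (dataset.sheet.loc[poly, "condition"] == "T").to_numpy()
        for gene in genes:
            expected = interaction_oracle(
                norm.loc[gene, cyto].to_numpy(), cyto_is_t,
                norm.loc[gene, poly].to_numpy(), poly_is_t,
            )
            assert p[gene] == pytest.approx(expected, abs=0)

    def test_zero_statistic_gives_p_one(self):
        dataset = make_dataset(np.full((2, 12), 80), replicates=3)
        p = ti_permutation_test(dataset, list(dataset.genes), TIConfig(seed=0))
        assert (p == 1.0).all()

    def test_saturated_effect_reaches_minimum_p(self):
        """A gene with opposing condition shifts in both fractions makes the
        observed statistic strictly dominate every non-trivial relabelling;
        with 3+3 per fraction (400 relabellings, +- symmetry tying the
        identity with its full complement) the smallest attainable
        two-sided p is 2/400."""
        anchor = np.full((5, 12), 1000)
        extreme = np.array(
            [[1000] * 3 + [8000] * 3 + [8000] * 3 + [1000] * 3]  # cytoNT cytoT polyNT polyT
        )
        dataset = make_dataset(np.vstack([anchor, extreme]), replicates=3)
        p = ti_permutation_test(dataset, list(dataset.genes), TIConfig(seed=0))
        assert p.iloc[-1] == pytest.approx(2 / 400)
        assert (p.iloc[:-1] == 1.0).all()

    def test_single_replicate_group_rejected(self):
        sheet = make_sheet(2).drop("poly_T_2")
        counts = pd.DataFrame(np.full((2, 7), 30), index=["a", "b"],
                              columns=sheet.index)
        from polyti.io import CountDataset

        dataset = CountDataset(counts=counts, sheet=sheet)
        with pytest.raises(DesignError, match="polysomal, T"):
            ti_permutation_test(dataset, ["a", "b"], TIConfig(seed=0))

    def test_monte_carlo_branch_reproducible(self, rng):
        counts = rng.poisson(100, size=(5, 16))
        dataset = make_dataset(counts, replicates=4)
        cfg = TIConfig(n_permutations=200, seed=5)  # C(8,4)^2 = 4900 > 200
        p1 = ti_permutation_test(dataset, list(dataset.genes), cfg)
        p2 = ti_permutation_test(dataset, list(dataset.genes), cfg)
        pd.testing.assert_series_equal(p1, p2)
        assert ((p1 > 0) & (p1 <= 1)).all()


# ---------------------------------------------------------------------------
# FDR and classification
# ---------------------------------------------------------------------------

class TestFDR:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate_vectors(self):
        np.testing.assert_allclose(adjust_fdr([0.3]), [0.3])
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)
        assert len(adjust_fdr([])) == 0

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(adjust_fdr(p), bh_oracle(p), rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


class TestClassification:
    cfg = TIConfig(fold_cutoff=1.5, alpha=0.05)

    @pytest.mark.parametrize(
        "log2_ti,fdr,expected",
        [
            (-0.99, 0.01, "down"),   # fold 2^0.99 ~ 1.99 >= 1.5
            (0.0, 0.001, "stable"),
            (0.5, 0.001, "stable"),  # fold 1.41 < 1.5
            (0.9, 0.001, "up"),
            (0.9, 0.2, "stable"),    # not significant
            (np.log2(1.5), 0.049, "up"),  # boundary inclusive on fold
        ],
    )
    def test_fold_and_alpha_rule(self, log2_ti, fdr, expected):
        records = pd.DataFrame({"log2_ti": [log2_ti], "fdr": [fdr]})
        assert classify_translational(records, self.cfg).iloc[0] == expected

    def test_classes_partition_filtered_genes(self):
        cfg = SimConfig(n_genes=400, seed=30)
        dataset = simulate_counts(simulate_gene_truth(cfg), cfg)
        table = run_translatome(dataset, TIConfig(seed=0))
        assert table["te_class"].isin(["up", "down", "stable"]).all()
        assert len(table) == len(filter_expressed(dataset, TIConfig()))
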