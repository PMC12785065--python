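"""Protein-table cleaning, MinProb imputation, edge correlations, nulls."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from lazynet.core_model import ValidationError
from lazynet.proteomics_validation import (
    EdgeCorrelation,
    ImputeConfig,
    ProteinMatrix,
    clean_protein_table,
    degree_matched_protein_null,
    edge_protein_correlation,
    filter_quantified,
    log2_median_center,
    minprob_impute,
    wilcoxon_rank_sum,
)


def table(rows, channels=("i1", "i2")):
    df = pd.DataFrame(rows)
    for c in channels:
        df[c] = df[c].astype(float)
    return df


class TestCleanProteinTable:
    def test_reverse_rows_dropped(self):
        df = table(
            [
                {"gene_symbol": "ABC", "reverse": "+", "i1": 1, "i2": 2},
                {"gene_symbol": "DEF", "reverse": "", "i1": 3, "i2": 4},
            ]
        )
        out = clean_protein_table(df, intensity_cols=["i1", "i2"])
        assert out.symbols == ["DEF"]

    def test_duplicate_symbols_averaged_case_insensitively(self):
        df = table(
            [
                {"gene_symbol": "gpx4", "i1": 2, "i2": 8},
                {"gene_symbol": "GPX4", "i1": 4, "i2": 8},
            ]
        )
        out = clean_protein_table(df, intensity_cols=["i1", "i2"])
        assert out.symbols == ["GPX4"]
        assert out.values[0, 0] == pytest.approx(3.0)

    def test_zero_intensity_becomes_missing(self):
        df = table([{"gene_symbol": "ABC", "i1": 0, "i2": 5}])
        out = clean_protein_table(df, intensity_cols=["i1", "i2"])
        assert np.isnan(out.values[0, 0])
        assert out.values[0, 1] == 5.0

    def test_rows_without_symbol_dropped(self):
        df = table(
            [
                {"gene_symbol": "", "i1": 1, "i2": 1},
                {"gene_symbol": "KEEP", "i1": 1, "i2": 1},
            ]
        )
        out = clean_protein_table(df, intensity_cols=["i1", "i2"])
        assert out.symbols == ["KEEP"]

    def test_intensity_regex_column_selection(self):
        df = pd.DataFrame(
            [{"gene_symbol": "A", "Intensity L": 1.0, "Intensity H": 2.0,
              "Score": 9.0}]
        )
        out = clean_protein_table(df, intensity_regex=r"^Intensity")
        assert out.channels == ["Intensity L", "Intensity H"]


class TestMinProbImpute:
    def test_complete_column_untouched(self, rng):
        vals = rng.normal(20, 2, (50, 3))
        mat = ProteinMatrix(vals, [f"P{i}" for i in range(50)], list("abc"))
        out = minprob_impute(mat, ImputeConfig(seed=0))
        assert np.array_equal(out.values, vals)

    def test_left_shift_distribution(self, rng):
        """Imputed values follow N(mu - 1.8 sigma, (0.3 sigma)^2)."""
        n_obs, n_miss = 2000, 10_000
        col = np.concatenate(
            [rng.normal(20, 2, n_obs), np.full(n_miss, np.nan)]
        )
        mat = ProteinMatrix(
            col[:, None], [f"P{i}" for i in range(len(col))], ["c"]
        )
        out = minprob_impute(mat, ImputeConfig(seed=1))
        imputed = out.values[n_obs:, 0]
        obs = col[:n_obs]
        mu, sd = obs.mean(), obs.std(ddof=1)
        assert imputed.mean() == pytest.approx(mu - 1.8 * sd, abs=0.02)
        assert imputed.std() == pytest.approx(0.3 * sd, abs=0.02)

    def test_observed_entries_bitwise_identical(self, rng):
        vals = rng.normal(20, 2, (30, 4))
        vals[rng.random((30, 4)) < 0.3] = np.nan
        mask = np.isfinite(vals)
        mat = ProteinMatrix(vals, [f"P{i}" for i in range(30)], list("abcd"))
        out = minprob_impute(mat, ImputeConfig(seed=2))
        assert np.array_equal(out.values[mask], vals[mask])
        assert np.isfinite(out.values).all()

    def test_deterministic_per_seed(self, rng):
        vals = rng.normal(20, 2, (30, 2))
        vals[::3] = np.nan
        mat = ProteinMatrix(vals, [f"P{i}" for i in range(30)], ["a", "b"])
        a = minprob_impute(mat, ImputeConfig(seed=5))
        b = minprob_impute(mat, ImputeConfig(seed=5))
        assert np.array_equal(a.values, b.values)

    def test_underobserved_column_raises(self):
        vals = np.array([[1.0], [np.nan], [np.nan]])
        mat = ProteinMatrix(vals, ["A", "B", "C"], ["c"])
        with pytest.raises(ValidationError):
            minprob_impute(mat, ImputeConfig())


class TestLog2MedianCenter:
    def test_two_point_column(self):
        mat = ProteinMatrix(np.array([[2.0], [8.0]]), ["A", "B"], ["c"])
        out = log2_median_center(mat)
        assert np.allclose(out.values[:, 0], [-1.0, 1.0])

    def test_constant_column_becomes_zero(self):
        mat = ProteinMatrix(np.full((5, 1), 7.0), [f"P{i}" for i in range(5)], ["c"])
        out = log2_median_center(mat)
        assert np.allclose(out.values, 0.0)

    def test_column_medians_vanish(self, rng):
        vals = rng.lognormal(3, 1, (41, 6))
        mat = ProteinMatrix(vals, [f"P{i}" for i in range(41)], list("abcdef"))
        out = log2_median_center(mat)
        assert np.all(np.abs(np.median(out.values, axis=0)) < 1e-12)

    def test_nonpositive_raises(self):
        mat = ProteinMatrix(np.array([[0.5], [-1.0]]), ["A", "B"], ["c"])
        with pytest.raises(ValidationError):
            log2_median_center(mat)

    def test_spearman_invariant_under_log2(self, rng):
        """Rank correlations are unchanged by the strictly monotone log."""
        a = rng.lognormal(0, 1, 20)
        b = a * rng.lognormal(0, 0.2, 20)
        assert spearmanr(a, b).statistic == pytest.approx(
            spearmanr(np.log2(a), np.log2(b)).statistic
        )


class TestFilterQuantified:
    def test_coverage_and_variance_rules(self):
        vals = np.array(
            [
                [1.0, 2.0, 3.0, 4.0],     # keep
                [1.0, 2.0, np.nan, np.nan],  # only 2 channels
                [5.0, 5.0, 5.0, 5.0],     # zero variance
            ]
        )
        mat = ProteinMatrix(vals, ["A", "B", "C"], list("abcd"))
        out = filter_quantified(mat, min_channels=3)
        assert out.symbols == ["A"]


class TestEdgeCorrelation:
    def matrix(self):
        vals = np.array(
            [
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0],   # A
                [2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0],  # B monotone with A
                [np.nan] * 7 + [1.0, 2.0],                        # C: 2 shared
                [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0],   # D
            ]
        )
        return ProteinMatrix(vals, ["A", "B", "C", "D"], [f"c{i}" for i in range(9)])

    def test_monotone_pair_has_rho_one(self):
        corrs, _ = edge_protein_correlation(self.matrix(), [("A", "B")])
        assert corrs[0].rho == pytest.approx(1.0)
        assert corrs[0].n_obs == 9

    def test_insufficient_coverage_excluded(self):
        corrs, excluded = edge_protein_correlation(self.matrix(), [("A", "C")])
        assert corrs == []
        assert excluded["coverage"] == 1

    def test_matches_rank_formula_on_hand_table(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        y = np.array([2.0, 0.5, 9.0, 1.0, 3.0])
        vals = np.vstack([x, y])
        mat = ProteinMatrix(vals, ["X", "Y"], [f"c{i}" for i in range(5)])
        corrs, _ = edge_protein_correlation(mat, [("X", "Y")])
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        expected = np.corrcoef(rx, ry)[0, 1]
        assert corrs[0].rho == pytest.approx(expected)


class TestWilcoxonRankSum:
    def test_exact_small_sample(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_enumeration_small_n(self, seed):
        r = np.random.default_rng(seed)
        x = r.permutation(np.arange(1.0, 11.0))[:4]
        rest = [v for v in np.arange(1.0, 11.0) if v not in x][:5]
        y = np.array(rest)
        p = wilcoxon_rank_sum(x, y)
        # enumerate every assignment of the pooled ranks to group 1
        pooled = np.concatenate([x, y])
        from scipy.stats import rankdata
        ranks = rankdata(pooled)
        n1 = len(x)
        obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        us = []
        for idx in combinations(range(len(pooled)), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            us.append(u)
        us = np.array(us)
        m = len(x) * len(y)
        exact = np.mean(np.minimum(us, m - us) <= min(obs_u, m - obs_u))
        assert p == pytest.approx(exact, abs=1e-9)


class TestDegreeMatchedNull:
    def planted_matrix(self, rng, n_genes=60, n_channels=10, rho=0.9):
        base = rng.normal(0, 1, (n_genes, n_channels))
        # planted pairs (2i, 2i+1) strongly correlated
        for i in range(0, 20, 2):
            base[i + 1] = rho * base[i] + np.sqrt(1 - rho**2) * rng.normal(
                0, 1, n_channels
            )
        symbols = [f"P{i:02d}" for i in range(n_genes)]
        return ProteinMatrix(2.0 ** (base + 20), symbols, [f"c{i}" for i in range(n_channels)]), symbols

    def test_planted_signal_significant(self, rng):
        mat, symbols = self.planted_matrix(rng)
        mat = log2_median_center(mat)
        edges = [(symbols[i], symbols[i + 1]) for i in range(0, 20, 2)]
        degree = {s: 1 for s in symbols}
        out = degree_matched_protein_null(
            mat, edges, degree, n_null=2000, seed=0
        )
        assert out["p_wilcoxon"] < 0.01
        assert out["median_real"] > out["median_null"]

    def test_self_null_is_calibrated(self, rng):
        """Sampling the null from uncorrelated pairs against uncorrelated
        'real' edges gives an unremarkable p and matching medians."""
        mat, symbols = self.planted_matrix(rng, rho=0.0)
        mat = log2_median_center(mat)
        edges = [(symbols[i], symbols[i + 40]) for i in range(10)]
        degree = {s: 1 for s in symbols}
        out = degree_matched_protein_null(
            mat, edges, degree, n_null=2000, seed=3
        )
        assert out["p_wilcoxon"] > 0.05
        assert abs(out["median_real"] - out["median_null"]) < 0.2

    def test_validates_edge_correlation_bounds(self):
        with pytest.raises(ValidationError):
            EdgeCorrelation(("A", "B"), 1.5, 5)
        with pytest.raises(ValidationError):
            EdgeCorrelation(("A", "B"), 0.5, 2)
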