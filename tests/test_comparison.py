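import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

import burdenslp as b
from burdenslp.comparison import (
    flip_protective,
    relative_slp,
    run_comparison,
    score_correlation_matrix,
)
from burdenslp.types import GenePhenotypePair


class TestFlipProtective:
    def test_case_direction_is_identity(self, small_gene_dataset):
        _, _, _, cohort, _ = small_gene_dataset
        pair = GenePhenotypePair("G", "pheno", "case")
        assert flip_protective(cohort, pair) is cohort

    def test_involution(self, small_gene_dataset):
        _, _, _, cohort, _ = small_gene_dataset
        pair = GenePhenotypePair("G", "pheno", "control")
        twice = flip_protective(flip_protective(cohort, pair), pair)
        np.testing.assert_array_equal(twice["phenotype"], cohort["phenotype"])

    def test_flip_negates_slp(self, small_gene_dataset):
        _, _, _, cohort, profiles = small_gene_dataset
        control = GenePhenotypePair("G", "pheno", "control")
        base = b.predictor_slp(profiles, cohort, "pred_high")
        flipped = b.predictor_slp(profiles, flip_protective(cohort, control), "pred_high")
        assert flipped.slp == -base.slp

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            GenePhenotypePair("G", "pheno", "sideways")


class TestRunComparison:
    def test_matrix_shape_means_and_duplicate_rows(self, small_gene_dataset):
        _, _, _, cohort, profiles = small_gene_dataset
        prof = profiles.copy()
        prof["pred_copy"] = prof["pred_high"]  # identical scores -> identical row
        pair = GenePhenotypePair("GENE1", "sim", "case")
        res = run_comparison([(pair, prof, cohort)],
                             ["pred_high", "pred_copy", "pred_null"], sort_rows=False)
        assert res.slp.shape == (3, 1)
        assert res.slp.loc["pred_high", "GENE1"] == res.slp.loc["pred_copy", "GENE1"]
        np.testing.assert_allclose(res.mean_slp, res.slp.mean(axis=1), atol=1e-9)

    def test_rows_sorted_by_mean_slp(self, small_gene_dataset):
        _, _, _, cohort, profiles = small_gene_dataset
        pair = GenePhenotypePair("GENE1", "sim", "case")
        res = run_comparison([(pair, profiles, cohort)], ["pred_null", "pred_high"])
        means = res.mean_slp.to_numpy()
        assert (np.diff(means) <= 0).all()
        assert res.table.columns[-1] == "mean_slp"

    def test_protective_gene_flipped_in_matrix(self, small_gene_dataset):
        _, _, _, cohort, profiles = small_gene_dataset
        case = GenePhenotypePair("GENE1", "sim", "case")
        control = GenePhenotypePair("GENE1", "sim", "control")
        r_case = run_comparison([(case, profiles, cohort)], ["pred_high"])
        r_ctl = run_comparison([(control, profiles, cohort)], ["pred_high"])
        assert r_ctl.slp.iloc[0, 0] == -r_case.slp.iloc[0, 0]

    def test_missing_predictor_rejected(self, small_gene_dataset):
        _, _, _, cohort, profiles = small_gene_dataset
        pair = GenePhenotypePair("GENE1", "sim", "case")
        with pytest.raises(KeyError, match="nope"):
            run_comparison([(pair, profiles, cohort)], ["nope"])


class TestScoreCorrelation:
    def _table(self, seed=0, n=50, k=5, missing=0.2):
        rng = np.random.default_rng(seed)
        names = [f"s{i}" for i in range(k)]
        df = pd.DataFrame(rng.uniform(0, 1, size=(n, k)), columns=names)
        mask = rng.random((n, k)) < missing
        df = df.mask(mask)
        df["consequence"] = "missense_variant"
        return df, names

    def test_diagonal_and_duplicate_column(self):
        df, names = self._table()
        df["s_dup"] = df["s0"]
        corr = score_correlation_matrix(df, names + ["s_dup"])
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.loc["s0", "s_dup"] == pytest.approx(1.0)
        np.testing.assert_allclose(corr.values, corr.values.T, equal_nan=True)

    @pytest.mark.parametrize("method,func", [("pearson", pearsonr), ("spearman", spearmanr)])
    def test_matches_pairwise_brute_force(self, method, func):
        df, names = self._table(seed=3)
        corr = score_correlation_matrix(df, names, method=method)
        for a in names:
            for c in names:
                if a == c:
                    assert corr.loc[a, c] == 1.0
                    continue
                both = df[[a, c]].dropna()
                expected = func(both[a], both[c])[0] if len(both) >= 3 else np.nan
                got = corr.loc[a, c]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_sparse_pair_left_absent(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0, 4.0, np.nan, np.nan],
                "b": [np.nan, np.nan, np.nan, np.nan, 1.0, 2.0],
                "consequence": "missense_variant",
            }
        )
        corr = score_correlation_matrix(df, ["a", "b"])
        assert np.isnan(corr.loc["a", "b"])

    def test_restricted_to_missense_by_default(self):
        df, names = self._table(seed=4, missing=0.0)
        df.loc[:20, "consequence"] = "stop_gained"
        corr = score_correlation_matrix(df, names)
        assert corr.attrs["n_variants"] == (df["consequence"] == "missense_variant").sum()

    def test_unknown_method_rejected(self):
        df, names = self._table()
        with pytest.raises(ValueError, match="method"):
            score_correlation_matrix(df, names, method="kendall")


class TestRelativeSlp:
    def test_direct_ratios_and_flags(self):
        slp = pd.DataFrame({"g": [4.0, 2.0, -1.0]}, index=["a", "b", "c"])
        rel = relative_slp(slp)
        np.testing.assert_allclose(rel.ratio["g"], [1.0, 0.5, -0.25])
        assert rel.negative.loc["c", "g"] and not rel.negative.loc["a", "g"]
        assert rel.flagged_genes == []

    def test_column_max_exactly_one_and_scale_invariance(self):
        rng = np.random.default_rng(8)
        slp = pd.DataFrame(rng.normal(1, 2, size=(6, 4)),
                           index=[f"p{i}" for i in range(6)],
                           columns=[f"g{j}" for j in range(4)])
        rel = relative_slp(slp)
        for g in slp.columns:
            if g in rel.flagged_genes:
                continue
            assert (rel.ratio[g] == 1.0).sum() >= 1
            assert rel.ratio[g].max() == 1.0
        rel2 = relative_slp(slp * 5.0)
        pd.testing.assert_frame_equal(rel.ratio, rel2.ratio)

    def test_all_negative_column_flagged_absent(self):
        slp = pd.DataFrame({"g1": [-1.0, -2.0], "g2": [3.0, 1.0]}, index=["a", "b"])
        rel = relative_slp(slp)
        assert rel.flagged_genes == ["g1"]
        assert rel.ratio["g1"].isna().all()
        np.testing.assert_allclose(rel.ratio["g2"], [1.0, 1 / 3])
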