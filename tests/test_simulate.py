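import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import burdenslp as b
from burdenslp.simulate import (
    SimulationConfig,
    simulate_gene_dataset,
    simulate_genotypes,
    simulate_phenotype,
    simulate_predictor_panel,
    simulate_variants,
    true_burden,
)


@pytest.mark.parametrize(
    "kwargs,field",
    [
        ({"n_individuals": 0}, "n_individuals"),
        ({"n_variants": -2}, "n_variants"),
        ({"maf_max": 0.0}, "maf_max"),
        ({"maf_max": 0.7}, "maf_max"),
        ({"category_probs": (0.5, 0.5, 0.5)}, "category_probs"),
        ({"panel_spec": (("a", 0.5), ("a", 0.1))}, "panel_spec"),
        ({"panel_spec": (("a", 1.5),)}, "lambda"),
        ({"target_prevalence": 0.0}, "target_prevalence"),
        ({"covariate_effects": {"height": 1.0}}, "covariate_effects"),
    ],
)
def test_invalid_config_names_field(kwargs, field):
    with pytest.raises(ValueError, match=field):
        SimulationConfig(**kwargs)


class TestSimulateVariants:
    def test_maf_truncation_and_categories(self):
        cfg = SimulationConfig(n_variants=500, maf_max=0.01, seed=1)
        v = simulate_variants(cfg)
        assert len(v) == 500
        assert (v.maf > 0).all() and (v.maf <= 0.01).all()
        assert ((v.is_lof + v.is_protein_altering) <= 1).all()
        assert v.true_pathogenicity.between(0, 1).all()

    def test_degenerate_category_probs(self):
        cfg = SimulationConfig(n_variants=200, category_probs=(1.0, 0.0, 0.0), seed=2)
        v = simulate_variants(cfg)
        assert (v.is_lof == 1).all()

    def test_loguniform_maf_mean_matches_closed_form(self):
        # mean of log-uniform on [a, b] is (b - a) / ln(b / a)
        cfg = SimulationConfig(n_variants=10_000, n_individuals=10_000, seed=3)
        v = simulate_variants(cfg)
        a, bnd = cfg.maf_min, cfg.maf_max
        analytic = (bnd - a) / np.log(bnd / a)
        mc_se = v.maf.std(ddof=1) / np.sqrt(len(v))
        assert abs(v.maf.mean() - analytic) < 3 * mc_se

    def test_deterministic(self):
        cfg = SimulationConfig(n_variants=100, seed=9)
        pd.testing.assert_frame_equal(simulate_variants(cfg), simulate_variants(cfg))


class TestPredictorPanel:
    def _variants(self, n=10_000, seed=4):
        return simulate_variants(SimulationConfig(n_variants=n, seed=seed))

    def test_lambda_one_is_monotone_in_truth(self):
        v = simulate_predictor_panel(self._variants(2000), (("perfect", 1.0),), seed=4)
        scored = v[v.is_protein_altering == 1]
        rho, _ = spearmanr(scored["perfect"], scored["true_pathogenicity"])
        assert rho == pytest.approx(1.0)

    def test_lambda_zero_uncorrelated(self):
        v = simulate_predictor_panel(self._variants(), (("noise", 0.0),), seed=4)
        scored = v[v.is_protein_altering == 1]
        rho, _ = spearmanr(scored["noise"], scored["true_pathogenicity"])
        assert abs(rho) < 0.05

    def test_identical_spec_shared_stream_identical_columns(self):
        v = simulate_predictor_panel(
            self._variants(500), (("a", 0.5), ("b", 0.5)), seed=7
        )
        np.testing.assert_array_equal(v["a"], v["b"])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            simulate_predictor_panel(self._variants(50), (("a", 0.5), ("a", 0.5)), 1)

    def test_scores_restricted_to_protein_altering_by_default(self):
        v = simulate_predictor_panel(self._variants(500), (("a", 0.5),), seed=1)
        assert v.loc[v.is_protein_altering == 0, "a"].isna().all()
        assert v.loc[v.is_protein_altering == 1, "a"].notna().all()
        v_all = simulate_predictor_panel(
            self._variants(500), (("a", 0.5),), seed=1, score_all_variants=True
        )
        assert v_all["a"].notna().all()

    def test_scores_in_unit_interval(self):
        v = simulate_predictor_panel(self._variants(500), (("a", 0.3),), seed=1)
        s = v["a"].dropna()
        assert (s > 0).all() and (s <= 1).all()


class TestSimulateGenotypes:
    def test_zero_maf_column_all_zero(self):
        v = pd.DataFrame({"variant_id": ["x"], "maf": [0.0]})
        g = simulate_genotypes(v, 500, seed=1)
        assert (g.dosages == 0).all()

    def test_allele_frequency_within_binomial_error(self):
        v = pd.DataFrame({"variant_id": ["x"], "maf": [0.005]})
        g = simulate_genotypes(v, 20_000, seed=2)
        p = 0.005
        se = np.sqrt(p * (1 - p) / (2 * 20_000))
        assert abs(g.allele_frequencies()[0] - p) < 4 * se

    def test_deterministic(self):
        v = simulate_variants(SimulationConfig(n_variants=30, seed=5))
        g1 = simulate_genotypes(v, 100, seed=5)
        g2 = simulate_genotypes(v, 100, seed=5)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)


class TestSimulatePhenotype:
    @pytest.mark.parametrize("n", [2000, 20_000])
    def test_prevalence_calibration(self, n):
        cfg = SimulationConfig(
            n_individuals=n, n_variants=50, effect_size=0.0,
            covariate_effects={}, target_prevalence=0.3, seed=6, panel_spec=(),
        )
        v = simulate_variants(cfg)
        g = simulate_genotypes(v, n, cfg.seed)
        cohort = simulate_phenotype(g, v, cfg)
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(cohort.phenotype.mean() - 0.3) < 4 * se

    def test_cases_enriched_for_true_burden_under_large_effect(self):
        cfg = SimulationConfig(
            n_individuals=4000, n_variants=100, effect_size=1.5, seed=7, panel_spec=()
        )
        v = simulate_variants(cfg)
        g = simulate_genotypes(v, cfg.n_individuals, cfg.seed)
        cohort = simulate_phenotype(g, v, cfg)
        tb = true_burden(g, v)
        assert tb[cohort.phenotype == 1].mean() > tb[cohort.phenotype == 0].mean()

    def test_unreachable_prevalence_reports_bounds(self):
        cfg = SimulationConfig(
            n_individuals=200, n_variants=20, target_prevalence=1e-20,
            seed=8, panel_spec=(),
        )
        v = simulate_variants(cfg)
        g = simulate_genotypes(v, 200, cfg.seed)
        with pytest.raises(ValueError, match="unreachable"):
            simulate_phenotype(g, v, cfg)

    def test_deterministic_and_covariates_shaped(self):
        cfg = SimulationConfig(n_individuals=300, n_variants=30, seed=9, panel_spec=())
        v = simulate_variants(cfg)
        g = simulate_genotypes(v, 300, cfg.seed)
        c1 = simulate_phenotype(g, v, cfg)
        c2 = simulate_phenotype(g, v, cfg)
        pd.testing.assert_frame_equal(c1, c2)
        assert set(c1.sex.unique()) <= {0, 1}
        assert [c for c in c1.columns if c.startswith("PC")] == [
            f"PC{i}" for i in range(1, 21)
        ]


def test_full_generator_bit_reproducible():
    cfg = SimulationConfig(n_individuals=400, n_variants=40, seed=13)
    v1, g1, c1 = simulate_gene_dataset(cfg)
    v2, g2, c2 = simulate_gene_dataset(cfg)
    pd.testing.assert_frame_equal(v1, v2)
    np.testing.assert_array_equal(g1.dosages, g2.dosages)
    pd.testing.assert_frame_equal(c1, c2)
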