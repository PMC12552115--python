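import pandas as pd
import pytest

import burdenslp as b


@pytest.fixture(scope="session")
def small_gene_dataset():
    """One simulated gene with a moderate burden effect, small enough for fast fits."""
    cfg = b.SimulationConfig(
        n_individuals=2000,
        n_variants=80,
        panel_spec=(("pred_high", 0.9), ("pred_null", 0.0)),
        effect_size=0.4,
        seed=42,
    )
    variants, genotypes, cohort = b.simulate_gene_dataset(cfg)
    profiles = b.gene_profiles(genotypes, variants, ["pred_high", "pred_null"])
    return cfg, variants, genotypes, cohort, profiles


@pytest.fixture()
def tiny_variants():
    """Hand-written four-variant annotation table."""
    return pd.DataFrame(
        {
            "variant_id": [
                "chr1:100:A:T",
                "chr1:200:C:G",
                "chr1:300:G:A",
                "chr1:400:T:C",
            ],
            "gene": ["G"] * 4,
            "consequence": [
                "stop_gained",
                "missense_variant",
                "synonymous_variant",
                "missense_variant",
            ],
            "maf": [0.001, 0.005, 0.01, 0.0025],
            "is_lof": [1, 0, 0, 0],
            "is_protein_altering": [0, 1, 0, 1],
            "scoreA": [float("nan"), 0.5, float("nan"), 1.0],
        }
    )
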