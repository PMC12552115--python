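"""Synthetic case-control cohorts for exercising the burden pipeline.

Real weighted-burden studies run on restricted biobank exomes; this module
generates stand-in data with the statistical structure the analysis
assumes, so every downstream stage can be tested without any download:

* rare variants with a log-uniform site-frequency spectrum truncated at a
  MAF ceiling, each carrying a latent true pathogenicity in [0, 1];
* a panel of predictor scores whose rank correlation with the latent truth
  is controlled by an informativeness parameter ``lambda`` per predictor;
* genotypes drawn independently per site as Binomial(2, MAF) (linkage
  equilibrium);
* sex, 20 structure-free principal-component covariates, and a binary
  phenotype from a logistic model on the frequency-weighted true burden,
  with the intercept solved so the expected prevalence hits a target.

Everything is a pure function of (inputs, seed).  A single master seed is
expanded into five documented child streams (variants, panel, genotypes,
covariates, phenotype) so components can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .burden import WeightConfig, frequency_weight
from .types import GenotypeMatrix, PC_COLUMNS

__all__ = [
    "SimulationConfig",
    "simulate_variants",
    "simulate_predictor_panel",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_gene_dataset",
    "true_burden",
]

# child-stream indices under the master seed
_STREAM_VARIANTS = 0
_STREAM_PANEL = 1
_STREAM_GENOTYPES = 2
_STREAM_COVARIATES = 3
_STREAM_PHENOTYPE = 4

_LOF_CONSEQUENCES = np.array(
    ["stop_gained", "frameshift_variant", "splice_acceptor_variant", "splice_donor_variant"]
)
_PA_CONSEQUENCES = np.array(
    ["missense_variant", "protein_altering_variant", "start_lost", "stop_lost"]
)
# missense dominates protein-altering calls in real exome annotation
_PA_PROBS = np.array([0.85, 0.05, 0.05, 0.05])


def _stream(seed: int, which: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(which,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated gene-cohort study.

    Defaults describe a moderately powered single-gene study: 10,000
    individuals, 150 rare variants with MAF <= 0.01, a four-predictor panel
    spanning the informativeness range, a common phenotype with 20%
    prevalence and a modest positive burden effect.
    """

    n_individuals: int = 10_000
    n_variants: int = 150
    maf_max: float = 0.01
    #: probabilities of (LOF, protein-altering, excluded) categories
    category_probs: tuple[float, float, float] = (0.10, 0.60, 0.30)
    #: (predictor_name, informativeness lambda in [0, 1]) pairs
    panel_spec: tuple[tuple[str, float], ...] = (
        ("pred_high", 0.9),
        ("pred_mid", 0.5),
        ("pred_weak", 0.3),
        ("pred_null", 0.0),
    )
    #: log-odds of case status per unit of frequency-weighted true burden
    effect_size: float = 0.25
    target_prevalence: float = 0.2
    #: log-odds for sex and each principal component
    covariate_effects: dict = field(default_factory=lambda: {"sex": 0.2})
    #: attach predictor scores to all variants, not just protein-altering
    score_all_variants: bool = False
    gene_name: str = "GENE1"
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if not 0 < self.maf_max <= 0.5:
            raise ValueError("maf_max must be in (0, 0.5]")
        probs = np.asarray(self.category_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-12:
            raise ValueError("category_probs must be 3 non-negative values summing to 1")
        names = [n for n, _ in self.panel_spec]
        if len(set(names)) != len(names):
            raise ValueError("panel_spec contains duplicate predictor names")
        for name, lam in self.panel_spec:
            if not 0 <= lam <= 1:
                raise ValueError(f"panel_spec: lambda for {name!r} must be in [0, 1]")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must be in (0, 1)")
        unknown = set(self.covariate_effects) - ({"sex"} | set(PC_COLUMNS))
        if unknown:
            raise ValueError(f"covariate_effects has unknown terms: {sorted(unknown)}")

    @property
    def maf_min(self) -> float:
        """Lower MAF bound: a singleton allele in the simulated cohort."""
        return 1.0 / (2.0 * self.n_individuals)

    @property
    def predictor_names(self) -> list[str]:
        return [n for n, _ in self.panel_spec]


def simulate_variants(config: SimulationConfig) -> pd.DataFrame:
    """Annotated variant table: id, gene, consequence, maf, category flags, truth.

    MAF is log-uniform on [1/(2 n), maf_max], mimicking the excess of very
    rare alleles in a site-frequency spectrum without population-genetic
    machinery.  Latent truth is Beta(9, 1) for LOF variants (almost all
    damaging), Uniform(0, 1) for protein-altering (missense spans benign to
    pathogenic) and Beta(1, 9) for excluded variants.
    """
    rng = _stream(config.seed, _STREAM_VARIANTS)
    m = config.n_variants
    maf = np.exp(rng.uniform(np.log(config.maf_min), np.log(config.maf_max), size=m))
    category = rng.choice(3, size=m, p=np.asarray(config.category_probs, dtype=float))
    is_lof = (category == 0).astype(int)
    is_pa = (category == 1).astype(int)

    consequence = np.empty(m, dtype=object)
    consequence[category == 0] = rng.choice(_LOF_CONSEQUENCES, size=int(is_lof.sum()))
    consequence[category == 1] = rng.choice(
        _PA_CONSEQUENCES, size=int(is_pa.sum()), p=_PA_PROBS
    )
    consequence[category == 2] = "synonymous_variant"

    truth = np.empty(m)
    truth[category == 0] = rng.beta(9, 1, size=int(is_lof.sum()))
    truth[category == 1] = rng.uniform(0, 1, size=int(is_pa.sum()))
    truth[category == 2] = rng.beta(1, 9, size=int((category == 2).sum()))

    pos = np.cumsum(rng.integers(1, 500, size=m)) + 1_000_000
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=m)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    vid = [f"chr1:{p}:{r}:{a}" for p, r, a in zip(pos, ref, alt)]

    return pd.DataFrame(
        {
            "variant_id": vid,
            "gene": config.gene_name,
            "consequence": consequence,
            "maf": maf,
            "is_lof": is_lof,
            "is_protein_altering": is_pa,
            "true_pathogenicity": truth,
        }
    )


def simulate_predictor_panel(
    variants: pd.DataFrame,
    panel_spec,
    seed: int,
    score_all_variants: bool = False,
) -> pd.DataFrame:
    """Attach one rank-score column in (0, 1] per predictor.

    Each predictor blends the latent truth with independent noise,
    ``lambda * truth + (1 - lambda) * noise``, and reports the quantile rank
    of that blend across scored variants, matching the rank-score convention
    of harmonised predictor databases.  By default only protein-altering
    variants receive scores (missense predictors do not score LOF variants);
    ``score_all_variants`` extends coverage to every variant.

    The noise stream of each predictor is keyed by its lambda, so two
    predictors specified with the same informativeness (and seed) produce
    identical columns regardless of name or position in the panel.
    """
    names = [n for n, _ in panel_spec]
    if len(set(names)) != len(names):
        raise ValueError("duplicate predictor names in panel_spec")
    if "true_pathogenicity" not in variants.columns:
        raise ValueError("variants must carry a true_pathogenicity column")

    out = variants.copy()
    scored = (
        np.ones(len(out), dtype=bool)
        if score_all_variants
        else out["is_protein_altering"].to_numpy() == 1
    )
    truth = out["true_pathogenicity"].to_numpy(dtype=float)
    n_scored = int(scored.sum())
    for name, lam in panel_spec:
        key = int(round(lam * 1_000_000))
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_PANEL, key)))
        noise = rng.uniform(0, 1, size=len(out))
        blend = lam * truth + (1.0 - lam) * noise
        col = np.full(len(out), np.nan)
        if n_scored:
            order = blend[scored].argsort().argsort()  # ranks 0..n-1, ties impossible a.s.
            col[scored] = (order + 1) / n_scored
        out[name] = col
    return out


def simulate_genotypes(
    variants: pd.DataFrame, n_individuals: int, seed: int
) -> GenotypeMatrix:
    """Independent Binomial(2, MAF) ALT-allele counts per individual and site."""
    rng = _stream(seed, _STREAM_GENOTYPES)
    maf = variants["maf"].to_numpy(dtype=float)
    dosages = rng.binomial(2, maf, size=(n_individuals, len(maf))).astype(np.int8)
    individual_ids = [f"ind{i:07d}" for i in range(n_individuals)]
    return GenotypeMatrix(dosages, individual_ids, list(variants["variant_id"]))


def true_burden(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    weight_config: WeightConfig | None = None,
) -> np.ndarray:
    """Frequency-weighted latent-truth burden per individual.

    Uses the same aggregation rule as the analysis (dosage x weight x score)
    with the latent true pathogenicity as the score, restricted to variants
    in the LOF or protein-altering categories.
    """
    cfg = weight_config or WeightConfig()
    qualifying = (
        (variants["is_lof"].to_numpy() + variants["is_protein_altering"].to_numpy()) > 0
    ).astype(float)
    score = variants["true_pathogenicity"].to_numpy(dtype=float) * qualifying
    w = frequency_weight(variants["maf"].to_numpy(dtype=float), cfg)
    d = genotypes.dosages.astype(float)
    d[genotypes.dosages < 0] = 0.0
    return d @ (w * score)


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    config: SimulationConfig,
    weight_config: WeightConfig | None = None,
) -> pd.DataFrame:
    """Cohort table: phenotype, sex and 20 principal-component covariates.

    The linear predictor is ``alpha + effect_size * true_burden +
    covariate effects``; ``alpha`` is found by root-finding so the expected
    prevalence over the simulated cohort equals ``target_prevalence`` to
    within 1e-6, then case status is drawn Bernoulli(logistic(lp)).
    """
    n = genotypes.n_individuals
    cov_rng = _stream(config.seed, _STREAM_COVARIATES)
    sex = cov_rng.binomial(1, 0.5, size=n)
    pcs = cov_rng.standard_normal(size=(n, len(PC_COLUMNS)))

    eta = config.effect_size * true_burden(genotypes, variants, weight_config)
    eta = eta + config.covariate_effects.get("sex", 0.0) * sex
    for j, pc in enumerate(PC_COLUMNS):
        beta = config.covariate_effects.get(pc, 0.0)
        if beta:
            eta = eta + beta * pcs[:, j]

    def gap(alpha: float) -> float:
        return float(expit(alpha + eta).mean() - config.target_prevalence)

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            "target prevalence unreachable: attainable range is "
            f"[{expit(lo + eta).mean():.3g}, {expit(hi + eta).mean():.3g}]"
        )
    alpha = brentq(gap, lo, hi, xtol=1e-10)
    assert abs(gap(alpha)) < 1e-6

    phe_rng = _stream(config.seed, _STREAM_PHENOTYPE)
    phenotype = phe_rng.binomial(1, expit(alpha + eta))

    cohort = pd.DataFrame({"individual_id": genotypes.individual_ids})
    cohort["phenotype"] = phenotype
    cohort["sex"] = sex
    for j, pc in enumerate(PC_COLUMNS):
        cohort[pc] = pcs[:, j]
    cohort.attrs["alpha"] = alpha
    return cohort


def simulate_gene_dataset(config: SimulationConfig, weight_config: WeightConfig | None = None):
    """Run the full generator: (variants-with-scores, genotypes, cohort)."""
    variants = simulate_variants(config)
    variants = simulate_predictor_panel(
        variants, config.panel_spec, config.seed, config.score_all_variants
    )
    genotypes = simulate_genotypes(variants, config.n_individuals, config.seed)
    cohort = simulate_phenotype(genotypes, variants, config, weight_config)
    return variants, genotypes, cohort
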