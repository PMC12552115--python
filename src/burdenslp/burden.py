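"""Allele-frequency weights and per-individual weighted burden scores.

A gene's burden score for one individual is

    burden_i = sum_j dosage_ij * w(maf_j) * score_j

over the gene's qualifying rare variants j, where ``dosage`` is the ALT
allele count (0/1/2), ``w`` is a decreasing function of minor allele
frequency so that rarer variants weigh more, and ``score`` is either a
category indicator (LOF or protein-altering) or a pathogenicity-predictor
score.  Variants without a score for a given predictor contribute zero to
that predictor's burden, so every individual has a defined total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeMatrix

__all__ = ["WeightConfig", "frequency_weight", "individual_burden", "gene_profiles"]

CATEGORY_COLUMNS = ("is_lof", "is_protein_altering")


@dataclass(frozen=True)
class WeightConfig:
    """Allele-frequency weight curve.

    Parameters
    ----------
    w_max : float
        Weight at maf = 0 (default 10); must be >= 1.
    f_max : float
        Frequency at which the weight reaches 1; equals the rare-variant
        MAF threshold (default 0.01).
    form : str
        "linear" (default): w = 1 + (w_max - 1) * (1 - maf / f_max);
        "step": w_max below f_max / 2, else 1;
        "logistic": smooth decrease centred at f_max / 2.
    dosage_mode : str
        "count" (default): homozygous ALT counts twice; "carrier": any ALT
        counts once.
    """

    w_max: float = 10.0
    f_max: float = 0.01
    form: str = "linear"
    dosage_mode: str = "count"

    def __post_init__(self):
        if self.w_max < 1:
            raise ValueError("w_max must be >= 1")
        if not 0 < self.f_max <= 0.5:
            raise ValueError("f_max must be in (0, 0.5]")
        if self.form not in ("linear", "step", "logistic"):
            raise ValueError(f"unknown weight form {self.form!r}")
        if self.dosage_mode not in ("count", "carrier"):
            raise ValueError(f"unknown dosage_mode {self.dosage_mode!r}")

    def metadata(self) -> dict:
        return {
            "w_max": self.w_max,
            "f_max": self.f_max,
            "form": self.form,
            "dosage_mode": self.dosage_mode,
        }


def frequency_weight(maf, config: WeightConfig | None = None):
    """Weight for a variant of the given minor allele frequency.

    Lies in [1, w_max], non-increasing in MAF, with w(0) = w_max and
    w(f_max) = 1 for the default linear form.  MAF above ``f_max`` is an
    error: such variants should have been removed by the rarity filter.
    """
    cfg = config or WeightConfig()
    arr = np.asarray(maf, dtype=float)
    if np.any(arr < 0) or np.any(arr > cfg.f_max):
        raise ValueError(
            f"maf outside [0, f_max={cfg.f_max}]; apply the rare-variant filter first"
        )
    if cfg.form == "linear":
        w = 1.0 + (cfg.w_max - 1.0) * (1.0 - arr / cfg.f_max)
    elif cfg.form == "step":
        w = np.where(arr < cfg.f_max / 2, cfg.w_max, 1.0)
    else:  # logistic
        # steepness chosen so the curve is ~flat at both ends of [0, f_max]
        k = 10.0 / cfg.f_max
        w = 1.0 + (cfg.w_max - 1.0) / (1.0 + np.exp(k * (arr - cfg.f_max / 2)))
    return float(w) if arr.ndim == 0 else w


def _dosage_array(genotypes: GenotypeMatrix, config: WeightConfig) -> np.ndarray:
    """Dosage matrix with missing genotypes treated as homozygous reference."""
    d = genotypes.dosages.astype(float)
    d[genotypes.dosages < 0] = 0.0
    if config.dosage_mode == "carrier":
        d = (d > 0).astype(float)
    return d


def _score_vector(variants: pd.DataFrame, score_name: str) -> np.ndarray:
    if score_name not in variants.columns:
        raise KeyError(f"unknown score column {score_name!r}")
    s = pd.to_numeric(variants[score_name], errors="coerce").to_numpy(dtype=float)
    return np.nan_to_num(s, nan=0.0)  # absent score contributes 0


def individual_burden(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    score_name: str,
    config: WeightConfig | None = None,
) -> np.ndarray:
    """Per-individual weighted burden for one score column of one gene.

    ``variants`` must be the gene's MAF-filtered table, aligned with the
    columns of ``genotypes`` (checked by variant_id).  Returns one value per
    individual in the matrix's row order.
    """
    cfg = config or WeightConfig()
    if len(variants) != genotypes.n_variants:
        raise ValueError(
            f"dimension mismatch: {len(variants)} variants in table, "
            f"{genotypes.n_variants} genotype columns"
        )
    if list(variants["variant_id"]) != list(genotypes.variant_ids):
        raise ValueError("variant_id order differs between table and genotypes")
    w = frequency_weight(variants["maf"].to_numpy(dtype=float), cfg)
    s = _score_vector(variants, score_name)
    return _dosage_array(genotypes, cfg) @ (np.atleast_1d(w) * s)


def gene_profiles(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    predictor_names: list[str],
    config: WeightConfig | None = None,
) -> pd.DataFrame:
    """Burden profile table for one gene.

    One row per individual with columns ``lof_burden``,
    ``protein_altering_burden`` and one column per requested predictor,
    indexed by ``individual_id``.
    """
    cfg = config or WeightConfig()
    for name in predictor_names:
        if name not in variants.columns:
            raise KeyError(f"unknown predictor {name!r}")
    data = {
        "lof_burden": individual_burden(genotypes, variants, "is_lof", cfg),
        "protein_altering_burden": individual_burden(
            genotypes, variants, "is_protein_altering", cfg
        ),
    }
    for name in predictor_names:
        data[name] = individual_burden(genotypes, variants, name, cfg)
    out = pd.DataFrame(data, index=pd.Index(genotypes.individual_ids, name="individual_id"))
    out.attrs["weight_config"] = cfg.metadata()
    return out
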