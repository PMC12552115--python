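"""Shared containers for the burden-testing pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "GenePhenotypePair", "MISSING_DOSAGE"]

#: Sentinel dosage for a missing genotype call.
MISSING_DOSAGE = -1

#: Columns a cohort table must carry besides the 20 principal components.
COHORT_BASE_COLUMNS = ("individual_id", "phenotype", "sex")
N_PCS = 20
PC_COLUMNS = tuple(f"PC{i}" for i in range(1, N_PCS + 1))


@dataclass
class GenotypeMatrix:
    """Individuals x variants ALT-allele counts.

    ``dosages`` is an integer array with entries in {0, 1, 2} and
    :data:`MISSING_DOSAGE` (-1) for a missing call.  Rows follow
    ``individual_ids``, columns follow ``variant_ids``.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        self.individual_ids = list(self.individual_ids)
        self.variant_ids = list(self.variant_ids)
        if self.dosages.shape != (len(self.individual_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.variant_ids)} variants"
            )
        valid = np.isin(self.dosages, (0, 1, 2, MISSING_DOSAGE))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"invalid dosage values {bad.tolist()}; expected 0/1/2/-1")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual_ids")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant_ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_missing(self) -> int:
        return int((self.dosages == MISSING_DOSAGE).sum())

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        """Column subset in the order given."""
        index = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            cols = [index[v] for v in variant_ids]
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not in genotype matrix") from None
        return GenotypeMatrix(self.dosages[:, cols], self.individual_ids, list(variant_ids))

    def allele_frequencies(self) -> np.ndarray:
        """ALT allele frequency per variant over non-missing calls."""
        d = self.dosages.astype(float)
        miss = self.dosages == MISSING_DOSAGE
        d[miss] = 0.0
        n_called = (~miss).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return d.sum(axis=0) / (2.0 * n_called)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.dosages,
            index=pd.Index(self.individual_ids, name="individual_id"),
            columns=self.variant_ids,
        )
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns))


@dataclass(frozen=True)
class GenePhenotypePair:
    """A gene analysed against a phenotype.

    ``direction`` records whether damaging rare variants in the gene
    associate with being a case or with being a control (a protective
    gene); for direction "control" the analysis phenotype is complemented
    so that damaging burden associates positively.
    """

    gene: str
    phenotype_name: str
    direction: str = "case"

    def __post_init__(self):
        if self.direction not in ("case", "control"):
            raise ValueError(f"direction must be 'case' or 'control', got {self.direction!r}")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort table has outcome, sex and the 20 PC covariates."""
    missing = [c for c in COHORT_BASE_COLUMNS + PC_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    pheno = set(pd.unique(cohort["phenotype"]))
    if not pheno <= {0, 1}:
        raise ValueError(f"phenotype must be binary 0/1, found values {sorted(pheno)}")
    return cohort
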