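"""Variant consequence categories, predictor-score transforms and the rare-variant filter.

Variants are classified from their (VEP-style) consequence terms into two
mutually exclusive functional categories:

* **LOF** (loss of function): stop gained, frameshift, essential splice site;
* **protein altering**: protein-altering, missense, start lost, stop lost.

Everything else is excluded from burden analysis.  Score harmonisation
follows the conventions used when pooling heterogeneous predictors:
DNA-language-model log-likelihood-ratio scores are negated so that higher
means more deleterious, AlphaMissense class labels become ordinal scores
{likely_benign: 0, ambiguous: 1, likely_pathogenic: 2}, and raw scores can
be converted to quantile rank scores in (0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "LOF_TERMS",
    "PROTEIN_ALTERING_TERMS",
    "assign_categories",
    "annotate_categories",
    "transform_gpn_msa",
    "map_alphamissense_category",
    "filter_rare",
    "rank_transform",
    "CategoryReport",
]

#: Sequence Ontology terms assigned to the loss-of-function category.
LOF_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)

#: Sequence Ontology terms assigned to the protein-altering category.
PROTEIN_ALTERING_TERMS = frozenset(
    {
        "protein_altering_variant",
        "missense_variant",
        "start_lost",
        "stop_lost",
    }
)

# Plain-text synonyms (as used in the literature) -> Sequence Ontology terms.
# "essential splice site" covers both splice acceptor and donor sites; either
# SO term yields LOF so a single representative is sufficient.
_SYNONYMS = {
    "stop gained": "stop_gained",
    "frameshift": "frameshift_variant",
    "essential splice site": "splice_acceptor_variant",
    "splice acceptor": "splice_acceptor_variant",
    "splice donor": "splice_donor_variant",
    "protein altering": "protein_altering_variant",
    "missense": "missense_variant",
    "start lost": "start_lost",
    "stop lost": "stop_lost",
}

_ALPHAMISSENSE_CODES = {
    "likely_pathogenic": 2,
    "likely_benign": 0,
    "ambiguous": 1,
}


@dataclass
class CategoryReport:
    """Running tally of category assignment for a batch of variants."""

    n_lof: int = 0
    n_protein_altering: int = 0
    n_excluded: int = 0
    unrecognized: list[str] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return self.n_lof + self.n_protein_altering + self.n_excluded


def _normalize_term(term: str) -> str:
    t = term.strip().lower().replace("-", " ")
    if t in _SYNONYMS:
        return _SYNONYMS[t]
    return t.replace(" ", "_")


def assign_categories(
    consequence: str, report: CategoryReport | None = None
) -> tuple[int, int]:
    """Map a consequence annotation to ``(is_lof, is_protein_altering)``.

    ``consequence`` may contain several ``&``- or ``,``-separated terms (one
    per transcript); the most severe one decides, with severity ranked
    LOF > protein altering > other.  Categories are mutually exclusive, so
    the result is one of ``(1, 0)``, ``(0, 1)`` or ``(0, 0)``.  Unrecognized
    terms are excluded with a warning and recorded in ``report``.
    """
    raw_terms = [t for chunk in consequence.split("&") for t in chunk.split(",")]
    terms = [_normalize_term(t) for t in raw_terms if t.strip()]
    if not terms:
        raise ValueError("empty consequence string")

    known = LOF_TERMS | PROTEIN_ALTERING_TERMS
    recognized_other = {
        # common VEP terms that are valid but excluded from burden analysis
        "synonymous_variant", "intron_variant", "splice_region_variant",
        "5_prime_utr_variant", "3_prime_utr_variant", "upstream_gene_variant",
        "downstream_gene_variant", "intergenic_variant", "stop_retained_variant",
        "inframe_insertion", "inframe_deletion", "coding_sequence_variant",
        "non_coding_transcript_exon_variant", "regulatory_region_variant",
    }
    for t in terms:
        if t not in known and t not in recognized_other:
            warnings.warn(f"unrecognized consequence term {t!r}; variant excluded")
            if report is not None:
                report.unrecognized.append(t)

    if any(t in LOF_TERMS for t in terms):
        result = (1, 0)
    elif any(t in PROTEIN_ALTERING_TERMS for t in terms):
        result = (0, 1)
    else:
        result = (0, 0)

    if report is not None:
        if result == (1, 0):
            report.n_lof += 1
        elif result == (0, 1):
            report.n_protein_altering += 1
        else:
            report.n_excluded += 1
    return result


def annotate_categories(variants: pd.DataFrame) -> tuple[pd.DataFrame, CategoryReport]:
    """Add ``is_lof`` / ``is_protein_altering`` columns from ``consequence``.

    Returns a copy of the table plus the :class:`CategoryReport` tally.
    """
    report = CategoryReport()
    cats = [assign_categories(c, report) for c in variants["consequence"]]
    out = variants.copy()
    out["is_lof"] = [c[0] for c in cats]
    out["is_protein_altering"] = [c[1] for c in cats]
    return out, report


def transform_gpn_msa(raw_score):
    """Negate a DNA-language-model log-likelihood-ratio score.

    The score is distributed as log L(ALT)/L(REF); after negation a high
    value indicates an ALT allele with lower likelihood, i.e. higher
    predicted pathogenicity.  An involution: applying it twice is a no-op.
    """
    arr = np.asarray(raw_score, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite score passed to transform_gpn_msa")
    out = -arr
    return float(out) if np.isscalar(raw_score) or arr.ndim == 0 else out


def map_alphamissense_category(label: str) -> int:
    """Convert an AlphaMissense class label to its ordinal score.

    ``likely_pathogenic`` -> 2, ``ambiguous`` -> 1, ``likely_benign`` -> 0.
    """
    key = str(label).strip().lower().replace(" ", "_")
    try:
        return _ALPHAMISSENSE_CODES[key]
    except KeyError:
        raise ValueError(
            f"unknown AlphaMissense category {label!r}; expected one of "
            f"{sorted(_ALPHAMISSENSE_CODES)}"
        ) from None


def filter_rare(variants: pd.DataFrame, maf_threshold: float = 0.01) -> pd.DataFrame:
    """Restrict a variant table to rare variants with ``maf <= maf_threshold``.

    The threshold is inclusive and input order is preserved.  Missing MAFs
    are an error (MAF must be resolved before filtering).
    """
    maf = pd.to_numeric(variants["maf"], errors="coerce")
    if maf.isna().any():
        bad = variants.loc[maf.isna(), "variant_id"].tolist()
        raise ValueError(f"missing maf for variants: {bad}")
    return variants.loc[maf.to_numpy() <= maf_threshold].copy()


def rank_transform(scores) -> np.ndarray:
    """Quantile rank scores in (0, 1], dbNSFP-style.

    Present values are mapped to ``rank / n_present`` with average ranks for
    ties; missing values (NaN) stay missing.  Invariant to any strictly
    increasing transform of the input.
    """
    arr = np.asarray(scores, dtype=float)
    present = ~np.isnan(arr)
    n = int(present.sum())
    if n == 0:
        raise ValueError("rank_transform requires at least one present value")
    out = np.full(arr.shape, np.nan)
    out[present] = rankdata(arr[present], method="average") / n
    return out
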