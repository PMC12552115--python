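"""Multi-predictor, multi-gene comparison of burden-test performance.

Runs the SLP association once per (gene-phenotype pair, predictor),
recoding protective genes so that damaging burden always associates
positively, and assembles the study-level artifacts:

* the SLP matrix (predictors x genes) with per-predictor mean SLP;
* per-gene relative SLPs (each cell scaled by the best positive SLP in its
  gene, the encoding behind dot-size heatmaps);
* the pairwise correlation matrix of predictor scores across missense
  variants, with pairwise-complete handling of missing scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import BurdenAssociationModel, SLPResult
from .types import GenePhenotypePair

__all__ = [
    "flip_protective",
    "PredictorComparison",
    "PredictorComparisonResults",
    "run_comparison",
    "score_correlation_matrix",
    "relative_slp",
]


def flip_protective(cohort: pd.DataFrame, pair: GenePhenotypePair) -> pd.DataFrame:
    """Recode the outcome for a protective gene.

    For ``direction == "control"`` the phenotype of interest is "being a
    control", so the binary outcome is complemented; for "case" the cohort
    is returned unchanged (same object).  Applying the flip twice restores
    the original outcome.
    """
    if pair.direction == "case":
        return cohort
    out = cohort.copy()
    out["phenotype"] = 1 - out["phenotype"].to_numpy()
    return out


class PredictorComparison:
    """Benchmark a panel of predictors over several gene-phenotype pairs.

    Parameters
    ----------
    gene_datasets : list of (GenePhenotypePair, profiles, cohort)
        One burden-profile table and cohort per gene-phenotype pair.
    predictor_names : list of str
        Predictor burden columns to test; must exist in every profile table.
    """

    def __init__(self, gene_datasets, predictor_names):
        if not gene_datasets:
            raise ValueError("no gene datasets supplied")
        names = list(predictor_names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate predictor names")
        for pair, profiles, _ in gene_datasets:
            missing = [p for p in names if p not in profiles.columns]
            if missing:
                raise KeyError(f"gene {pair.gene}: missing predictor burdens {missing}")
        self.gene_datasets = list(gene_datasets)
        self.predictor_names = names

    def fit(self, method: str = "wald", sort_rows: bool = True
            ) -> "PredictorComparisonResults":
        """Run every gene x predictor association and assemble the SLP matrix."""
        slp = {}
        results: dict[tuple[str, str], SLPResult] = {}
        failures: dict[str, str] = {}
        for pair, profiles, cohort in self.gene_datasets:
            analysed = flip_protective(cohort, pair)
            col = {}
            for name in self.predictor_names:
                try:
                    res = BurdenAssociationModel(
                        profiles, analysed, name, gene=pair.gene
                    ).fit(method=method).slp_result
                except Exception as exc:  # hard failure: flag column, keep going
                    failures[pair.gene] = f"{name}: {exc}"
                    res = SLPResult(pair.gene, name, float("nan"), float("nan"),
                                    float("nan"), float("nan"), float("nan"),
                                    converged=False)
                results[(pair.gene, name)] = res
                col[name] = res.slp
            slp[pair.gene] = col
        matrix = pd.DataFrame(slp).loc[self.predictor_names]
        return PredictorComparisonResults(self, matrix, results, failures,
                                          sort_rows=sort_rows)


class PredictorComparisonResults:
    """SLP matrix over predictors x genes, with per-predictor means."""

    def __init__(self, model: PredictorComparison, slp: pd.DataFrame,
                 results, failures, sort_rows: bool = True):
        self.model = model
        self.mean_slp = slp.mean(axis=1)
        if sort_rows:
            order = self.mean_slp.sort_values(ascending=False).index
            slp = slp.loc[order]
            self.mean_slp = self.mean_slp.loc[order]
        self.slp = slp
        self.results = results
        self.failures = failures

    @property
    def table(self) -> pd.DataFrame:
        """SLP matrix with the per-predictor mean appended as a final column."""
        out = self.slp.copy()
        out["mean_slp"] = self.mean_slp
        return out

    def relative(self):
        """Per-gene relative SLPs; see :func:`relative_slp`."""
        return relative_slp(self.slp)

    def summary(self) -> str:
        lines = [
            "Predictor comparison (SLP = signed log10 p)",
            "=" * 60,
            f"genes: {self.slp.shape[1]}   predictors: {self.slp.shape[0]}",
        ]
        lines.append(self.table.round(2).to_string())
        if self.failures:
            lines.append(f"failed genes: {self.failures}")
        return "\n".join(lines)

    def plot_dot_heatmap(self, ax=None):
        """Dot heatmap of relative SLPs: dot area ~ |relative SLP|, open
        circles for negative SLPs."""
        import matplotlib.pyplot as plt

        rel, negative, _ = self.relative()
        if ax is None:
            _, ax = plt.subplots(
                figsize=(1 + 0.45 * rel.shape[1], 1 + 0.35 * rel.shape[0])
            )
        for i, pred in enumerate(rel.index):
            for j, gene in enumerate(rel.columns):
                v = rel.loc[pred, gene]
                if np.isnan(v):
                    continue
                neg = bool(negative.loc[pred, gene])
                ax.scatter(j, i, s=20 + 280 * abs(v),
                           facecolors="white" if neg else "black",
                           edgecolors="black")
        ax.set_xticks(range(rel.shape[1]), rel.columns, rotation=90)
        ax.set_yticks(range(rel.shape[0]), rel.index)
        ax.invert_yaxis()
        return ax


def run_comparison(gene_datasets, predictor_names, method: str = "wald",
                   sort_rows: bool = True) -> PredictorComparisonResults:
    """Functional wrapper around :class:`PredictorComparison`."""
    return PredictorComparison(gene_datasets, predictor_names).fit(
        method=method, sort_rows=sort_rows
    )


def score_correlation_matrix(
    variants: pd.DataFrame,
    predictor_names,
    method: str = "pearson",
    consequence: str | None = "missense_variant",
    min_obs: int = 3,
) -> pd.DataFrame:
    """Pairwise correlations of predictor scores across variants.

    By default restricted to variants annotated as missense (where most
    predictors overlap).  Missing scores are handled pairwise-complete:
    each correlation uses the variants where both predictors are scored,
    and pairs with fewer than ``min_obs`` complete observations are left
    absent (NaN).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    table = variants
    if consequence is not None:
        table = table[table["consequence"] == consequence]
    scores = table.loc[:, list(predictor_names)].apply(pd.to_numeric)
    if len(scores) < 2:
        raise ValueError("need at least 2 variants to correlate scores")
    corr = scores.corr(method=method, min_periods=min_obs)
    np.fill_diagonal(corr.values, 1.0)
    corr.attrs["method"] = method
    corr.attrs["n_variants"] = len(scores)
    return corr


@dataclass
class RelativeSLP:
    """Per-gene relative SLP matrix plus sign and validity flags."""

    ratio: pd.DataFrame
    negative: pd.DataFrame
    flagged_genes: list

    def __iter__(self):  # allow tuple unpacking
        return iter((self.ratio, self.negative, self.flagged_genes))


def relative_slp(slp: pd.DataFrame) -> RelativeSLP:
    """Scale each gene's SLPs by the best positive SLP in that gene.

    The per-gene maximum maps to exactly 1; negative SLPs keep their
    (negative) ratio and are flagged.  A gene whose SLPs are all <= 0 has no
    positive reference point: its column is emitted absent and listed in
    ``flagged_genes``.
    """
    ratio = pd.DataFrame(index=slp.index, columns=slp.columns, dtype=float)
    flagged = []
    for gene in slp.columns:
        col = slp[gene].astype(float)
        top = col.max()
        if not top > 0:
            flagged.append(gene)
            continue
        scaled = col / top
        scaled[col.idxmax()] = 1.0  # column max is exactly 1 by definition
        ratio[gene] = scaled
    negative = slp < 0
    return RelativeSLP(ratio, negative, flagged)
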