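"""Per-gene logistic burden association and the signed log10 p-value (SLP).

For one gene and one pathogenicity predictor, case-control status is
regressed on an intercept, sex, 20 principal components, the gene's LOF
burden, its protein-altering burden, and the predictor's weighted burden.
The two-sided Wald p-value of the predictor-burden coefficient is reported
as a signed log p-value,

    SLP = sign(beta) * (-log10 p),

positive when higher burden associates with being a case.  |SLP| >= 1.301
corresponds to p <= 0.05.

The module exposes a statsmodels-style pair: :class:`BurdenAssociationModel`
holds the aligned data and design; ``fit()`` returns
:class:`BurdenAssociationResults` with the estimate, its uncertainty,
diagnostics and a ``summary()`` table.  :func:`predictor_slp` is the
one-call convenience wrapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .types import PC_COLUMNS, validate_cohort

__all__ = [
    "SLP_CAP",
    "SLPResult",
    "fit_logistic",
    "compute_slp",
    "predictor_slp",
    "BurdenAssociationModel",
    "BurdenAssociationResults",
]

#: |SLP| ceiling: -log10 of the smallest positive double, flagged when hit.
SLP_CAP = 323.0

_MAXITER = 100
_TOL = 1e-10


@dataclass
class SLPResult:
    """Association of one predictor's burden with one gene-phenotype pair."""

    gene: str
    predictor_name: str
    beta: float
    se: float
    wald_z: float
    p: float
    slp: float
    converged: bool
    degenerate: bool = False
    capped: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compute_slp(beta: float, p: float) -> float:
    """Signed log10 p-value: ``sign(beta) * (-log10 p)``.

    Zero when beta is exactly 0 (the sign convention is undefined there);
    magnitude capped at :data:`SLP_CAP`.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if beta == 0 or np.isnan(beta):
        return 0.0
    mag = min(-np.log10(p), SLP_CAP)
    return float(np.sign(beta) * mag)


def _slp_from_z(beta: float, z: float) -> tuple[float, float, bool]:
    """(p, slp, capped) from the Wald z, working in log space to dodge underflow."""
    log10_p = (np.log(2.0) + norm.logsf(abs(z))) / np.log(10.0)
    p = float(min(np.power(10.0, log10_p), 1.0))
    mag = -log10_p
    capped = mag > SLP_CAP
    mag = min(mag, SLP_CAP)
    slp = 0.0 if beta == 0 else float(np.sign(beta) * mag)
    return max(p, 5e-324), slp, capped


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop later columns that are linearly dependent on earlier ones."""
    arr = X.to_numpy(dtype=float)
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(arr.shape[1]):
        cand = arr[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(X.columns[j])
    return X.iloc[:, keep], dropped


def fit_logistic(outcome, design: pd.DataFrame):
    """Maximum-likelihood logistic fit of a binary outcome on a design matrix.

    Returns ``(params, bse, converged, dropped, llf)`` where ``params`` and
    ``bse`` are Series over the retained columns, ``dropped`` lists columns
    removed for exact collinearity, and ``llf`` is the maximised
    log-likelihood.  The outcome is internally complemented when cases are
    the majority class (coefficients sign-restored afterwards), so fits of
    an outcome and its complement go through identical arithmetic and their
    coefficient estimates are exact negations of each other.
    """
    y = np.asarray(outcome, dtype=float)
    classes = np.unique(y)
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    if "const" not in design.columns and "intercept" not in design.columns:
        raise ValueError("design must include an intercept column")

    X, dropped = _drop_collinear(design)
    if dropped:
        warnings.warn(f"dropped collinear design columns: {dropped}")

    # canonicalise: fit the minority class (tie-broken on the first value)
    flip = y.mean() > 0.5 or (y.mean() == 0.5 and y[0] == 1.0)
    y_fit = 1.0 - y if flip else y

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y_fit, X).fit(
                method="newton", maxiter=_MAXITER, tol=_TOL, disp=0
            )
            converged = bool(res.mle_retvals.get("converged", False))
            params, bse, llf = res.params, res.bse, float(res.llf)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            nan = pd.Series(np.nan, index=X.columns)
            return nan, nan.copy(), False, dropped, float("nan")
    if flip:
        params = -params
    return params, bse, converged, dropped, llf


class BurdenAssociationModel:
    """Logistic burden model for one gene-phenotype pair and one predictor.

    Parameters
    ----------
    profiles : DataFrame
        Per-individual burdens indexed by individual_id, with columns
        ``lof_burden``, ``protein_altering_burden`` and the predictor.
    cohort : DataFrame
        Phenotype/covariate table with individual_id, phenotype, sex and
        PC1..PC20.
    predictor : str
        Name of the predictor burden column to test.
    gene : str, optional
        Gene label carried through to results.
    """

    def __init__(self, profiles: pd.DataFrame, cohort: pd.DataFrame, predictor: str,
                 gene: str = ""):
        validate_cohort(cohort)
        if predictor not in profiles.columns:
            raise KeyError(f"predictor {predictor!r} not in burden profiles")
        prof_ids = set(profiles.index)
        coh_ids = set(cohort["individual_id"])
        if prof_ids != coh_ids:
            raise ValueError(
                "individual_id mismatch between burden profiles "
                f"({len(prof_ids)} ids) and cohort ({len(coh_ids)} ids); "
                f"{len(prof_ids & coh_ids)} shared"
            )
        self.predictor = predictor
        self.gene = gene or (profiles.attrs.get("gene") or "")
        coh = cohort.set_index("individual_id").loc[profiles.index]
        self.endog = coh["phenotype"].to_numpy(dtype=float)
        design = pd.DataFrame(index=profiles.index)
        design["const"] = 1.0
        design["sex"] = coh["sex"].to_numpy(dtype=float)
        for pc in PC_COLUMNS:
            design[pc] = coh[pc].to_numpy(dtype=float)
        design["lof_burden"] = profiles["lof_burden"].to_numpy(dtype=float)
        design["protein_altering_burden"] = profiles[
            "protein_altering_burden"
        ].to_numpy(dtype=float)
        design[predictor] = profiles[predictor].to_numpy(dtype=float)
        self.exog = design

    def fit(self, method: str = "wald", allow_nonconverged: bool = False
            ) -> "BurdenAssociationResults":
        """Fit by maximum likelihood and test the predictor coefficient.

        ``method`` selects the p-value for the predictor burden: "wald"
        (default, two-sided normal on beta/se) or "lr" (likelihood-ratio
        cross-check against the model without the predictor term).
        """
        if method not in ("wald", "lr"):
            raise ValueError(f"unknown method {method!r}")
        pred = self.predictor
        col = self.exog[pred].to_numpy()
        if np.ptp(col) == 0:  # zero-variance burden: no information, SLP 0
            return BurdenAssociationResults(
                self, params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
                beta=float("nan"), se=float("nan"), wald_z=float("nan"),
                p=1.0, slp=0.0, converged=True, degenerate=True,
            )
        params, bse, converged, dropped, llf = fit_logistic(self.endog, self.exog)
        if pred in getattr(params, "index", []):
            beta = float(params[pred])
            se = float(bse[pred])
        else:  # predictor itself collinear with covariates
            beta, se = float("nan"), float("nan")
        z = beta / se if se and np.isfinite(se) and se > 0 else float("nan")

        if not converged and not allow_nonconverged:
            return BurdenAssociationResults(
                self, params=params, bse=bse, beta=beta, se=se, wald_z=z,
                p=float("nan"), slp=float("nan"), converged=False,
                dropped_terms=dropped,
            )
        if not np.isfinite(z):
            return BurdenAssociationResults(
                self, params=params, bse=bse, beta=beta, se=se, wald_z=z,
                p=float("nan"), slp=float("nan"), converged=converged,
                degenerate=True, dropped_terms=dropped,
            )
        if method == "lr":
            reduced = self.exog.drop(columns=[pred])
            _, _, conv0, _, llf0 = fit_logistic(self.endog, reduced)
            from scipy.stats import chi2

            lr = max(2.0 * (llf - llf0), 0.0)
            log10_p = chi2.logsf(lr, df=1) / np.log(10.0)
            p = float(min(np.power(10.0, log10_p), 1.0))
            mag = min(-log10_p, SLP_CAP)
            slp = 0.0 if beta == 0 else float(np.sign(beta) * mag)
            capped = -log10_p > SLP_CAP
            p = max(p, 5e-324)
        else:
            p, slp, capped = _slp_from_z(beta, z)
        return BurdenAssociationResults(
            self, params=params, bse=bse, beta=beta, se=se, wald_z=z, p=p,
            slp=slp, converged=converged, capped=capped, dropped_terms=dropped,
        )


class BurdenAssociationResults:
    """Fitted burden association: estimates, SLP and diagnostics."""

    def __init__(self, model: BurdenAssociationModel, *, params, bse, beta, se,
                 wald_z, p, slp, converged, degenerate=False, capped=False,
                 dropped_terms=None):
        self.model = model
        self.params = params
        self.bse = bse
        self.beta = beta
        self.se = se
        self.wald_z = wald_z
        self.p = p
        self.slp = slp
        self.converged = converged
        self.degenerate = degenerate
        self.capped = capped
        self.dropped_terms = dropped_terms or []
        self.nobs = len(model.endog)

    @property
    def slp_result(self) -> SLPResult:
        return SLPResult(
            gene=self.model.gene, predictor_name=self.model.predictor,
            beta=self.beta, se=self.se, wald_z=self.wald_z, p=self.p,
            slp=self.slp, converged=self.converged,
            degenerate=self.degenerate, capped=self.capped,
        )

    def summary(self) -> str:
        lines = [
            "Weighted burden logistic association",
            "=" * 52,
            f"Gene:        {self.model.gene or '-'}",
            f"Predictor:   {self.model.predictor}",
            f"N:           {self.nobs}",
            f"Cases:       {int(self.model.endog.sum())}",
            f"Converged:   {self.converged}   Degenerate: {self.degenerate}",
            "-" * 52,
            f"{'term':<26}{'coef':>12}{'se':>12}",
        ]
        for term in getattr(self.params, "index", []):
            lines.append(f"{term:<26}{self.params[term]:>12.4f}{self.bse[term]:>12.4f}")
        lines += [
            "-" * 52,
            f"beta = {self.beta:.4f}  se = {self.se:.4f}  z = {self.wald_z:.3f}",
            f"p = {self.p:.3g}  SLP = {self.slp:.3f}",
        ]
        if self.dropped_terms:
            lines.append(f"dropped collinear terms: {self.dropped_terms}")
        return "\n".join(lines)


def predictor_slp(
    profiles: pd.DataFrame,
    cohort: pd.DataFrame,
    predictor_name: str,
    gene: str = "",
    method: str = "wald",
) -> SLPResult:
    """SLP of one predictor's burden for one gene-phenotype pair."""
    model = BurdenAssociationModel(profiles, cohort, predictor_name, gene=gene)
    return model.fit(method=method).slp_result
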