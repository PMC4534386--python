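"""Null-model fitting and residual scores for generalized MDR.

The null model regresses the trait on covariates only (no genotypes): an
ordinary least-squares fit for a normal trait with identity link, or a
gamma GLM with log link for right-skewed positive traits.  Per-sample
scores driving the high/low cell classification are either the raw
residuals (ordinary GMDR) or robust transforms of the internally
studentized residuals:

* trimmed (L-estimator style): residuals with |r_i| > T are set to 0 and
  the sample is excluded from the analysis;
* winsorized (M-estimator style): residuals are clamped to [-T, +T], so
  outliers keep their sign but lose leverage.

T (default 1.5) controls how aggressively outlying trait values are
discounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datamodel import DegenerateInputError, PhenotypeTable, ValidationError


@dataclass
class NullModelFit:
    """Fitted covariates-only model.

    ``raw_residuals`` are response-scale residuals y_i - mu_i;
    ``residual_scale`` the estimated residual SD (sqrt dispersion for the
    gamma family); ``resid_sd`` the per-observation residual SD (constant
    for the normal family, proportional to mu_i for gamma).
    """

    coefficients: np.ndarray
    coefficient_names: list[str]
    fitted: np.ndarray
    raw_residuals: np.ndarray
    residual_scale: float
    resid_sd: np.ndarray
    leverages: np.ndarray
    family: str
    pheno: PhenotypeTable

    @property
    def n_samples(self) -> int:
        return len(self.raw_residuals)


@dataclass
class ScoreVector:
    """Per-sample scores with the trimming mask.

    ``included`` is False exactly where a trimmed score was zeroed out;
    those samples are dropped from cell tables and balanced accuracy.
    """

    scores: np.ndarray
    method: str
    threshold_T: float
    included: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.included = np.asarray(self.included, dtype=bool)
        if self.scores.shape != self.included.shape:
            raise ValidationError("scores and included must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.scores)


def _design_matrix(pheno: PhenotypeTable) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack([np.ones(pheno.n_samples), pheno.covariates])
    return X, ["intercept", *pheno.covariate_names]


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # flag columns whose removal does not reduce the rank
        collinear = [
            names[j]
            for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValidationError(f"rank-deficient covariate matrix; collinear columns: {collinear}")


def fit_null_model(pheno: PhenotypeTable, family: str = "normal_identity") -> NullModelFit:
    """Fit the covariates-only null model and populate residual diagnostics.

    normal_identity: OLS; residual_scale^2 = RSS / (n - p); leverages are
    the hat-matrix diagonal.  gamma_log: gamma GLM with log link; residuals
    on the response scale, per-observation SD sqrt(phi)*mu_i with phi the
    Pearson dispersion, leverages from the weighted hat matrix.
    """
    X, names = _design_matrix(pheno)
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"need more samples ({n}) than parameters ({p})")
    _check_rank(X, names)
    y = pheno.trait
    if family == "normal_identity":
        res = sm.OLS(y, X).fit()
        resid = y - res.fittedvalues
        scale = float(np.sqrt(res.scale))
        lev = res.get_influence().hat_matrix_diag
        resid_sd = np.full(n, scale)
        fitted = res.fittedvalues
    elif family == "gamma_log":
        if np.any(y <= 0):
            raise ValidationError("gamma_log requires a strictly positive trait")
        res = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log())).fit()
        fitted = res.fittedvalues
        resid = y - fitted
        scale = float(np.sqrt(res.scale))  # sqrt Pearson dispersion
        lev = res.get_influence().hat_matrix_diag
        resid_sd = scale * fitted
    else:
        raise ValidationError(f"unknown family {family!r}")
    return NullModelFit(
        coefficients=np.asarray(res.params, dtype=float),
        coefficient_names=names,
        fitted=np.asarray(fitted, dtype=float),
        raw_residuals=np.asarray(resid, dtype=float),
        residual_scale=scale,
        resid_sd=np.asarray(resid_sd, dtype=float),
        leverages=np.asarray(lev, dtype=float),
        family=family,
        pheno=pheno,
    )


def studentize(fit: NullModelFit, leverage_adjust: bool = True) -> np.ndarray:
    """Internally studentized residuals r_i / (sd_i * sqrt(1 - h_ii)).

    With ``leverage_adjust=False`` divides by the residual SD only
    ("plain" studentization).
    """
    # relative threshold: a scale at float-roundoff level means a perfect fit
    tol = 1e-10 * max(1.0, float(np.abs(fit.pheno.trait).max()))
    if not fit.residual_scale > tol:
        raise DegenerateInputError(
            "residual scale is (numerically) zero — the null model fits the "
            "trait perfectly, so residual scores are degenerate"
        )
    denom = fit.resid_sd
    if leverage_adjust:
        denom = denom * np.sqrt(1.0 - fit.leverages)
    return fit.raw_residuals / denom


def score_ordinary(fit: NullModelFit) -> ScoreVector:
    """Ordinary GMDR scores: the raw null-model residuals, all samples kept."""
    return ScoreVector(
        fit.raw_residuals.copy(), "ordinary", float("nan"),
        np.ones(fit.n_samples, dtype=bool),
    )


def _refit_studentized(fit: NullModelFit, keep: np.ndarray) -> np.ndarray:
    """Refit the null model on ``keep`` samples, score everyone against it.

    Plain studentization is used on the refit (leverages are undefined for
    the excluded points).
    """
    sub = fit.pheno.take_samples(np.flatnonzero(keep))
    refit = fit_null_model(sub, fit.family)
    X, _ = _design_matrix(fit.pheno)
    eta = X @ refit.coefficients
    mu = np.exp(eta) if fit.family == "gamma_log" else eta
    resid = fit.pheno.trait - mu
    if not refit.residual_scale > 0:
        raise DegenerateInputError("refit residual scale is zero")
    sd = refit.residual_scale * (mu if fit.family == "gamma_log" else 1.0)
    return resid / sd


def score_trimmed(fit: NullModelFit, T: float = 1.5, refit: bool = False) -> ScoreVector:
    """L-estimator score: studentized residual, zeroed (sample excluded)
    when its magnitude exceeds T; |r| = T is kept.

    ``refit=True`` adds one re-fitting step in the spirit of least trimmed
    squares: fit, trim at T, refit on the retained samples, re-score all
    samples against the refit, trim again.
    """
    if not T > 0:
        raise ValidationError("threshold T must be positive")
    r = studentize(fit)
    if refit:
        keep = np.abs(r) <= T
        if keep.sum() <= len(fit.coefficients):
            raise DegenerateInputError("too few samples survive trimming to refit")
        r = _refit_studentized(fit, keep)
    included = np.abs(r) <= T
    scores = np.where(included, r, 0.0)
    return ScoreVector(scores, "trimmed", T, included)


def score_winsorized(fit: NullModelFit, T: float = 1.5) -> ScoreVector:
    """M-estimator score: studentized residual clamped to [-T, +T].

    All samples are retained; residuals beyond T keep their sign at
    magnitude T.
    """
    if not T > 0:
        raise ValidationError("threshold T must be positive")
    r = studentize(fit)
    scores = np.clip(r, -T, T)
    return ScoreVector(scores, "winsorized", T, np.ones(len(r), dtype=bool))


def compute_scores(fit: NullModelFit, method: str, T: float = 1.5,
                   refit: bool = False) -> ScoreVector:
    """Dispatch on score method name (``ordinary``/``trimmed``/``winsorized``)."""
    if method == "ordinary":
        return score_ordinary(fit)
    if method == "trimmed":
        return score_trimmed(fit, T, refit=refit)
    if method == "winsorized":
        return score_winsorized(fit, T)
    raise ValidationError(f"unknown score method {method!r}")
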