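"""Individual-level estimators for parental effects in trio designs.

Three estimators of the effect of each parent's exposure phenotype on the
child outcome, all with family-clustered sandwich standard errors:

* ``fit_phenotypic_ols`` — mutually adjusted linear regression of the
  outcome on both parents' exposures; biased by genetic confounding.
* ``fit_wf_mvmr`` — within-family multivariable Mendelian randomization:
  two-stage least squares with the mother's and father's polygenic indices
  instrumenting their exposures and the child's polygenic index included
  as a covariate in both stages.  Conditioning on the child's index blocks
  the direct-transmission path, so the parental indices are valid
  instruments for dynastic (parent-on-child) effects even under
  assortative mating.
* ``fit_standard_mr`` — the same 2SLS without the child's index, the
  conventional analysis; biased by direct genetic effects and assortment.

Instrument strength is summarised by the Sanderson-Windmeijer conditional
F-statistic (strength of an exposure's instruments net of the other
exposure) and the instrument's partial R^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import TrioCohort

__all__ = ["TrioDesignMatrix", "IVEstimate", "design_from_cohort",
           "fit_phenotypic_ols", "fit_wf_mvmr", "fit_standard_mr",
           "conditional_f_statistic", "results_table"]

PARENTS = ("mother", "father")


class UnderIdentifiedError(ValueError):
    """Fewer usable instruments than exposures."""


class RankDeficientError(ValueError):
    """Collinear design matrix; names the offending columns."""


@dataclass
class TrioDesignMatrix:
    """Row-aligned arrays for one outcome in a trio analysis.

    ``exposures`` and ``instruments`` are (n, 2) DataFrames with columns
    'mother' and 'father'; ``child_score`` is the child's polygenic index
    (the conditioning covariate); ``covariates`` is an (n, c) matrix and
    ``clusters`` labels the family of each row.
    """

    y: np.ndarray
    exposures: pd.DataFrame
    instruments: pd.DataFrame
    child_score: np.ndarray
    clusters: np.ndarray
    covariates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.y)
        if self.covariates is None:
            self.covariates = np.empty((n, 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        for name, arr in (("exposures", self.exposures),
                          ("instruments", self.instruments),
                          ("child_score", self.child_score),
                          ("clusters", self.clusters),
                          ("covariates", self.covariates)):
            if len(arr) != n:
                raise ValueError(f"{name} has {len(arr)} rows, outcome has {n}")
        for df in (self.exposures, self.instruments):
            if list(df.columns) != list(PARENTS):
                raise ValueError(
                    f"expected columns {PARENTS}, got {list(df.columns)}")
        blocks = np.column_stack([
            np.asarray(self.y, float), self.exposures.to_numpy(float),
            self.instruments.to_numpy(float),
            np.asarray(self.child_score, float), self.covariates])
        if not np.all(np.isfinite(blocks)):
            raise ValueError("design contains missing or non-finite values; "
                             "drop incomplete rows before assembly")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class IVEstimate:
    """One parent's fitted effect with clustered inference and diagnostics."""

    exposure: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    n_clusters: int
    estimator: str
    conditional_f: float = math.nan
    partial_r2: float = math.nan

    @classmethod
    def from_point(cls, exposure, estimate, se, **kw):
        return cls(exposure=exposure, estimate=float(estimate), se=float(se),
                   ci_low=float(estimate - 1.96 * se),
                   ci_high=float(estimate + 1.96 * se), **kw)


def design_from_cohort(cohort: TrioCohort,
                       instrument_mother: np.ndarray | None = None,
                       instrument_father: np.ndarray | None = None,
                       child_score: np.ndarray | None = None,
                       covariates: np.ndarray | None = None) -> TrioDesignMatrix:
    """Assemble a design matrix from a simulated or loaded cohort.

    For a single-locus cohort the raw dosages are the natural instruments
    and are used when none are supplied; multi-locus cohorts must supply
    polygenic-index vectors (see :mod:`triomr.pgi`).
    """
    if instrument_mother is None or instrument_father is None or child_score is None:
        if cohort.n_snps != 1:
            raise ValueError("multi-locus cohorts need explicit instrument "
                             "and child-score vectors (e.g. polygenic indices)")
        instrument_mother = cohort.dosage_mother[:, 0].astype(float)
        instrument_father = cohort.dosage_father[:, 0].astype(float)
        child_score = cohort.dosage_child[:, 0].astype(float)
    ph = cohort.phenotypes
    return TrioDesignMatrix(
        y=ph["outcome_child"].to_numpy(float),
        exposures=pd.DataFrame({"mother": ph["exposure_mother"].to_numpy(float),
                                "father": ph["exposure_father"].to_numpy(float)}),
        instruments=pd.DataFrame({"mother": np.asarray(instrument_mother, float),
                                  "father": np.asarray(instrument_father, float)}),
        child_score=np.asarray(child_score, float),
        clusters=np.asarray(cohort.family_id),
        covariates=covariates)


# ---------------------------------------------------------------------------
# linear-algebra core

def _check_rank(mat: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        bad = []
        for j in range(mat.shape[1]):
            others = np.delete(mat, j, axis=1)
            resid = mat[:, j] - others @ np.linalg.lstsq(others, mat[:, j],
                                                         rcond=None)[0]
            denom = np.sum((mat[:, j] - mat[:, j].mean()) ** 2)
            if denom == 0 or np.sum(resid ** 2) / max(denom, 1e-300) < 1e-10:
                bad.append(names[j])
        raise RankDeficientError(f"collinear design columns: {bad or names}")


def _cluster_cov(score_basis: np.ndarray, resid: np.ndarray,
                 clusters: np.ndarray) -> tuple[np.ndarray, int]:
    """CR0 cluster sandwich with a G/(G-1) finite-sample factor.

    ``score_basis`` is the matrix whose cross-product forms the bread
    (X for OLS, projected X for 2SLS); ``resid`` the residuals used in
    the meat.
    """
    bread = np.linalg.inv(score_basis.T @ score_basis)
    codes, _ = pd.factorize(clusters)
    n_g = codes.max() + 1
    scores = score_basis * resid[:, None]
    meat_half = np.zeros((n_g, score_basis.shape[1]))
    np.add.at(meat_half, codes, scores)
    meat = meat_half.T @ meat_half
    cov = bread @ meat @ bread * (n_g / (n_g - 1))
    return cov, int(n_g)


def _exog_block(design: TrioDesignMatrix, include_child: bool) -> tuple[np.ndarray, list[str]]:
    n = design.n
    cols = [np.ones(n)]
    names = ["const"]
    if include_child:
        cols.append(np.asarray(design.child_score, float))
        names.append("child_pgi")
    for j in range(design.covariates.shape[1]):
        cols.append(design.covariates[:, j])
        names.append(f"cov{j}")
    return np.column_stack(cols), names


def fit_phenotypic_ols(design: TrioDesignMatrix,
                       include_child_score: bool = False) -> list[IVEstimate]:
    """Mutually adjusted regression of the outcome on both exposures.

    Returns mother and father estimates from the single joint fit with
    family-clustered standard errors.
    """
    W, wnames = _exog_block(design, include_child_score)
    X = np.column_stack([design.exposures.to_numpy(float), W])
    names = [f"exposure_{p}" for p in PARENTS] + wnames
    _check_rank(X, names)
    beta = np.linalg.lstsq(X, design.y, rcond=None)[0]
    resid = design.y - X @ beta
    cov, n_g = _cluster_cov(X, resid, design.clusters)
    return [IVEstimate.from_point(p, beta[i], math.sqrt(cov[i, i]),
                                  n=design.n, n_clusters=n_g, estimator="ols")
            for i, p in enumerate(PARENTS)]


def _fit_2sls(design: TrioDesignMatrix, include_child: bool,
              tag: str) -> list[IVEstimate]:
    W, wnames = _exog_block(design, include_child)
    Xend = design.exposures.to_numpy(float)
    Zexc = design.instruments.to_numpy(float)
    X = np.column_stack([Xend, W])
    Z = np.column_stack([Zexc, W])
    names = [f"exposure_{p}" for p in PARENTS] + wnames
    znames = [f"instrument_{p}" for p in PARENTS] + wnames
    _check_rank(X, names)
    if np.linalg.matrix_rank(Z) < Xend.shape[1] + W.shape[1]:
        raise UnderIdentifiedError(
            "instrument matrix rank-deficient: fewer independent instruments "
            f"than exposures among {znames}")
    # first stage: project every regressor on the instrument set
    Xhat = Z @ np.linalg.lstsq(Z, X, rcond=None)[0]
    beta = np.linalg.lstsq(Xhat, design.y, rcond=None)[0]
    # sandwich uses residuals from OBSERVED exposures, projected regressors
    resid = design.y - X @ beta
    cov, n_g = _cluster_cov(Xhat, resid, design.clusters)
    out = []
    for i, p in enumerate(PARENTS):
        f_stat, r2 = conditional_f_statistic(design, p, include_child_score=include_child)
        out.append(IVEstimate.from_point(
            p, beta[i], math.sqrt(cov[i, i]), n=design.n, n_clusters=n_g,
            estimator=tag, conditional_f=f_stat, partial_r2=r2))
    return out


def fit_wf_mvmr(design: TrioDesignMatrix) -> list[IVEstimate]:
    """Within-family multivariable MR: trio 2SLS conditioning on child PGI.

    First stages regress each parental exposure on the child, mother and
    father scores plus covariates; the second stage regresses the outcome
    on the fitted exposures, the child score and covariates.  Standard
    errors are family-clustered and use second-stage residuals computed
    with the observed exposures.
    """
    return _fit_2sls(design, include_child=True, tag="wf_mr")


def fit_standard_mr(design: TrioDesignMatrix) -> list[IVEstimate]:
    """Conventional MR comparator: identical 2SLS without the child score."""
    return _fit_2sls(design, include_child=False, tag="standard_mr")


def fit_single_parent_ols(design: TrioDesignMatrix) -> list[IVEstimate]:
    """One-parent-at-a-time regression of the outcome on each exposure.

    The naive analysis that ignores the other parent entirely.  Under
    assortative mating the spouses' exposures correlate, so the omitted
    parent's effect loads onto the modelled one and the estimate is biased
    upward — the contrast motivating the multivariable trio design.
    """
    out = []
    for p in PARENTS:
        W, wnames = _exog_block(design, include_child=False)
        X = np.column_stack([design.exposures[[p]].to_numpy(float), W])
        _check_rank(X, [f"exposure_{p}"] + wnames)
        beta = np.linalg.lstsq(X, design.y, rcond=None)[0]
        resid = design.y - X @ beta
        cov, n_g = _cluster_cov(X, resid, design.clusters)
        out.append(IVEstimate.from_point(p, beta[0], math.sqrt(cov[0, 0]),
                                         n=design.n, n_clusters=n_g,
                                         estimator="ols_single"))
    return out


def fit_single_parent_mr(design: TrioDesignMatrix) -> list[IVEstimate]:
    """One-parent-at-a-time IV: each exposure instrumented by its own score.

    The conventional one-exposure MR of a parental effect.  Under
    assortative mating a parent's score correlates with the spouse's score
    and hence with the spouse's exposure, violating the exclusion
    restriction and biasing the estimate; the bias grows with assortment
    strength.
    """
    out = []
    for p in PARENTS:
        W, _ = _exog_block(design, include_child=False)
        X = np.column_stack([design.exposures[[p]].to_numpy(float), W])
        Z = np.column_stack([design.instruments[[p]].to_numpy(float), W])
        Xhat = Z @ np.linalg.lstsq(Z, X, rcond=None)[0]
        beta = np.linalg.lstsq(Xhat, design.y, rcond=None)[0]
        resid = design.y - X @ beta
        cov, n_g = _cluster_cov(Xhat, resid, design.clusters)
        out.append(IVEstimate.from_point(p, beta[0], math.sqrt(cov[0, 0]),
                                         n=design.n, n_clusters=n_g,
                                         estimator="standard_mr_single"))
    return out


def conditional_f_statistic(design: TrioDesignMatrix, exposure: str,
                            include_child_score: bool = True
                            ) -> tuple[float, float]:
    """Sanderson-Windmeijer conditional F and instrument partial R^2.

    For exposure k, the statistic measures the joint strength of the
    excluded instruments after netting out the other exposure: 2SLS of
    x_k on the other exposure (instrumented), then an F-test of the
    instruments in the regression of the resulting residual on instruments
    plus exogenous covariates, with numerator degrees of freedom reduced
    by the number of other exposures.  With a single exposure this is the
    ordinary excluded-instrument F.

    Also returns the partial R^2 of the exposure's own instrument given
    the child score, the other parent's instrument and the covariates.
    """
    if exposure not in PARENTS:
        raise KeyError(f"exposure must be one of {PARENTS}")
    W, _ = _exog_block(design, include_child_score)
    Zexc = design.instruments.to_numpy(float)
    x_k = design.exposures[exposure].to_numpy(float)
    other = [p for p in PARENTS if p != exposure]
    X_other = design.exposures[other].to_numpy(float)
    k_other = X_other.shape[1]

    # step 1: residualise x_k on the other (instrumented) exposure
    Xo = np.column_stack([X_other, W])
    Z = np.column_stack([Zexc, W])
    Xo_hat = Z @ np.linalg.lstsq(Z, Xo, rcond=None)[0]
    delta = np.linalg.lstsq(Xo_hat, x_k, rcond=None)[0]
    eps = x_k - Xo @ delta

    # step 2: excluded-instrument F on the residual
    full = np.column_stack([W, Zexc])
    rss_r = _rss(eps, W)
    rss_u = _rss(eps, full)
    df_num = Zexc.shape[1] - k_other
    df_den = design.n - full.shape[1]
    if df_num <= 0 or df_den <= 0:
        raise UnderIdentifiedError("not enough instruments for a conditional F")
    # a numerically-zero unrestricted RSS (instrument == exposure) is
    # reported as an infinite F rather than a floating-point artefact
    if rss_u <= 1e-10 * max(rss_r, 1e-300):
        f_stat = math.inf
    else:
        f_stat = ((rss_r - rss_u) / df_num) / (rss_u / df_den)

    # partial R^2 of the own instrument
    own = design.instruments[exposure].to_numpy(float)[:, None]
    others_z = design.instruments[other].to_numpy(float)
    base = np.column_stack([W, others_z])
    rss0 = _rss(x_k, base)
    rss1 = _rss(x_k, np.column_stack([base, own]))
    r2 = 0.0 if rss0 <= 0 else (rss0 - rss1) / rss0
    return float(f_stat), float(r2)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    r = y - X @ beta
    return float(r @ r)


def conditional_f_single(design: TrioDesignMatrix, exposure: str) -> float:
    """Ordinary first-stage F when only one exposure is modelled.

    Falls back from the conditional statistic; logged so the caller knows
    the conditioning on the other exposure was skipped.
    """
    warnings.warn("single-exposure design: reporting the ordinary "
                  "excluded-instrument F", stacklevel=2)
    W, _ = _exog_block(design, True)
    Zexc = design.instruments[[exposure]].to_numpy(float)
    x_k = design.exposures[exposure].to_numpy(float)
    rss_r = _rss(x_k, W)
    rss_u = _rss(x_k, np.column_stack([W, Zexc]))
    df_den = design.n - W.shape[1] - 1
    return math.inf if rss_u <= 0 else (rss_r - rss_u) / (rss_u / df_den)


def results_table(estimates: list[IVEstimate], outcome: str = "outcome_child"
                  ) -> pd.DataFrame:
    """Tidy one-row-per-(outcome, exposure, estimator) results frame."""
    rows = [{"outcome": outcome, "exposure": e.exposure,
             "estimator": e.estimator, "estimate": e.estimate, "se": e.se,
             "ci_low": e.ci_low, "ci_high": e.ci_high,
             "conditional_f": e.conditional_f, "partial_r2": e.partial_r2,
             "n": e.n, "n_clusters": e.n_clusters}
            for e in estimates]
    return pd.DataFrame(rows)
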