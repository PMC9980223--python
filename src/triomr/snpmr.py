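"""Per-variant trio associations and pleiotropy-robust summary-data MR.

The two-sample workflow: variant-exposure associations come from an
external GWAS of the parents' exposure; variant-outcome associations are
estimated here by regressing the child outcome, variant by variant, on the
child's, mother's and father's dosages jointly (so each parental
coefficient is net of transmission and of the other parent).  The two sets
are harmonized to a common effect allele and combined with four estimators
that trade off efficiency against robustness to horizontal pleiotropy:

* inverse-variance weighted (IVW): no directional pleiotropy;
* MR-Egger: pleiotropy allowed if uncorrelated with instrument strength
  (the intercept estimates its directional component);
* weighted median: valid if >= 50% of the weight is from non-pleiotropic
  variants;
* weighted mode: valid if the largest cluster of variant-specific ratios
  is non-pleiotropic.

IVW and Egger use multiplicative random-effects variances (residual scale
floored at 1); median and mode use a seeded parametric bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import TrioCohort
from .wfmr import _cluster_cov

logger = logging.getLogger(__name__)

__all__ = ["SnpAssociationSet", "SummaryMrResult",
           "estimate_snp_outcome_associations", "harmonize", "wald_ratios",
           "ivw", "mr_egger", "weighted_median", "weighted_mode",
           "run_all_estimators"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SnpAssociationSet:
    """Harmonized per-variant exposure and outcome association estimates."""

    table: pd.DataFrame  # variant_id, beta_exposure, se_exposure,
    #                      beta_outcome, se_outcome, effect_allele
    n_flipped: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        req = {"variant_id", "beta_exposure", "se_exposure",
               "beta_outcome", "se_outcome"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"association table missing columns {missing}")
        if (self.table[["se_exposure", "se_outcome"]] <= 0).any().any():
            raise ValueError("standard errors must be > 0")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SummaryMrResult:
    estimator: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_snps: int
    q_statistic: float = np.nan
    q_df: int = 0
    intercept: float = np.nan
    intercept_se: float = np.nan
    intercept_p: float = np.nan

    @classmethod
    def build(cls, estimator, estimate, se, n_snps, **kw):
        return cls(estimator=estimator, estimate=float(estimate),
                   se=float(se), ci_low=float(estimate - 1.96 * se),
                   ci_high=float(estimate + 1.96 * se), n_snps=n_snps, **kw)


def estimate_snp_outcome_associations(cohort: TrioCohort, parent_role: str,
                                      covariates: np.ndarray | None = None
                                      ) -> pd.DataFrame:
    """Per-variant outcome association for one parent, trio-adjusted.

    For each variant j fits the child outcome on the child's, mother's and
    father's dosages at j (plus covariates) in one linear model and keeps
    the requested parent's coefficient with a family-clustered standard
    error.  Monomorphic variants are dropped with a warning, not an error.
    """
    if parent_role not in ("mother", "father"):
        raise KeyError("parent_role must be 'mother' or 'father'")
    y = cohort.phenotypes["outcome_child"].to_numpy(float)
    n = len(y)
    cov = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    if cov.ndim == 1:
        cov = cov[:, None]
    coef_index = 2 if parent_role == "mother" else 3
    rows = []
    for j, vid in enumerate(cohort.variant_ids):
        gc = cohort.dosage_child[:, j].astype(float)
        gm = cohort.dosage_mother[:, j].astype(float)
        gf = cohort.dosage_father[:, j].astype(float)
        if gm.std() == 0 or gf.std() == 0 or gc.std() == 0:
            logger.warning("dropping monomorphic variant %s", vid)
            continue
        X = np.column_stack([np.ones(n), gc, gm, gf, cov])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        covmat, _ = _cluster_cov(X, resid, cohort.family_id)
        rows.append({"variant_id": vid, "beta": beta[coef_index],
                     "se": float(np.sqrt(covmat[coef_index, coef_index])),
                     "n": n})
    return pd.DataFrame(rows)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize(exposure_panel: pd.DataFrame, outcome_assoc: pd.DataFrame,
              ambiguous_freq_window: tuple[float, float] = (0.42, 0.58)
              ) -> SnpAssociationSet:
    """Align exposure- and outcome-side effect alleles on shared variants.

    Rules, per shared variant id:
      * same effect/other alleles (or their strand complements): keep;
      * effect and other alleles swapped: negate the outcome beta;
      * palindromic (A/T or G/C) with effect-allele frequency inside the
        ambiguity window: drop — strand cannot be resolved;
      * any other allele pattern: drop with a warning.

    ``exposure_panel`` needs variant_id, effect_allele, other_allele,
    weight (beta), se and optionally effect_allele_freq; ``outcome_assoc``
    needs variant_id, beta, se and optionally effect_allele/other_allele
    (absent means already aligned to the exposure panel's alleles).
    """
    exp = exposure_panel.set_index("variant_id")
    out = outcome_assoc.set_index("variant_id")
    shared = exp.index.intersection(out.index)
    rows, flipped, dropped = [], 0, 0
    lo, hi = ambiguous_freq_window
    for vid in shared:
        e = exp.loc[vid]
        o = out.loc[vid]
        ea, oa = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        beta_y = float(o["beta"])
        if "effect_allele" in out.columns:
            oea = str(o["effect_allele"]).upper()
            ooa = str(o.get("other_allele", oa)).upper()
            comp = (_COMPLEMENT.get(oea, "?"), _COMPLEMENT.get(ooa, "?"))
            if (oea, ooa) == (ea, oa) or comp == (ea, oa):
                pass
            elif (oea, ooa) == (oa, ea) or comp == (oa, ea):
                beta_y = -beta_y
                flipped += 1
            else:
                warnings.warn(f"{vid}: alleles {oea}/{ooa} irreconcilable "
                              f"with {ea}/{oa}; dropped", stacklevel=2)
                dropped += 1
                continue
        if _is_palindromic(ea, oa):
            freq = float(e.get("effect_allele_freq", np.nan))
            if np.isnan(freq) or lo < freq < hi:
                dropped += 1
                continue
        rows.append({"variant_id": vid,
                     "beta_exposure": float(e["weight"]),
                     "se_exposure": float(e["se"]),
                     "beta_outcome": beta_y,
                     "se_outcome": float(o["se"]),
                     "effect_allele": ea})
    return SnpAssociationSet(pd.DataFrame(
        rows, columns=["variant_id", "beta_exposure", "se_exposure",
                       "beta_outcome", "se_outcome", "effect_allele"]),
        n_flipped=flipped, n_dropped=dropped)


# ---------------------------------------------------------------------------
# estimators

def _arrays(assoc: SnpAssociationSet):
    t = assoc.table
    return (t["beta_exposure"].to_numpy(float), t["se_exposure"].to_numpy(float),
            t["beta_outcome"].to_numpy(float), t["se_outcome"].to_numpy(float))


def wald_ratios(assoc: SnpAssociationSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant ratio estimates beta_y/beta_x and first-order SEs."""
    bx, _, by, sy = _arrays(assoc)
    if np.any(bx == 0):
        raise ZeroDivisionError("zero exposure association: Wald ratio undefined")
    return by / bx, sy / np.abs(bx)


def wald_ratio(assoc: SnpAssociationSet) -> SummaryMrResult:
    """Single-instrument estimate; the reduction every estimator shares."""
    if len(assoc) != 1:
        raise ValueError("wald_ratio needs exactly one variant")
    r, se = wald_ratios(assoc)
    return SummaryMrResult.build("wald_ratio", r[0], se[0], 1)


def ivw(assoc: SnpAssociationSet) -> SummaryMrResult:
    """Inverse-variance-weighted slope with multiplicative random effects.

    slope = sum(w b_x b_y) / sum(w b_x^2), w = 1/se_y^2 — the zero-
    intercept weighted regression of the outcome betas on the exposure
    betas.  The SE is scaled by the residual dispersion (floored at 1) and
    Cochran's Q over n-1 df summarises heterogeneity.  A single variant
    reduces to the Wald ratio.
    """
    if len(assoc) == 1:
        return wald_ratio(assoc)
    if len(assoc) < 2:
        raise ValueError("IVW needs >= 2 variants")
    bx, _, by, sy = _arrays(assoc)
    w = 1.0 / sy ** 2
    denom = np.sum(w * bx ** 2)
    slope = np.sum(w * bx * by) / denom
    q = float(np.sum(w * (by - slope * bx) ** 2))
    df = len(bx) - 1
    scale = max(1.0, q / df)
    se = np.sqrt(scale / denom)
    return SummaryMrResult.build("ivw", slope, se, len(bx),
                                 q_statistic=q, q_df=df)


def mr_egger(assoc: SnpAssociationSet) -> SummaryMrResult:
    """Weighted regression of outcome on exposure betas with free intercept.

    Exposure betas are oriented non-negative (outcome betas flipped in
    tandem) so the intercept is identified; the intercept estimates the
    average directional pleiotropic effect and the slope the causal
    effect.  Multiplicative random-effects variance, floored at 1.
    """
    if len(assoc) < 3:
        raise ValueError("MR-Egger needs >= 3 variants")
    bx, _, by, sy = _arrays(assoc)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    df = len(bx) - 2
    q = float(np.sum(w * resid ** 2))
    scale = max(1.0, q / df)
    cov = np.linalg.inv(xtx) * scale
    icpt, slope = coef
    icpt_se = np.sqrt(cov[0, 0])
    # t-test on the intercept against zero directional pleiotropy
    icpt_p = 2 * stats.t.sf(abs(icpt / icpt_se), df)
    return SummaryMrResult.build("egger", slope, np.sqrt(cov[1, 1]), len(bx),
                                 q_statistic=q, q_df=df, intercept=float(icpt),
                                 intercept_se=float(icpt_se),
                                 intercept_p=float(icpt_p))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, v))


def _bootstrap_se(assoc: SnpAssociationSet, statistic, n_boot: int,
                  seed) -> float:
    bx, sx, by, sy = _arrays(assoc)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        est[b] = statistic(bxb, sx, byb, sy)
    return float(est.std(ddof=1))


def _median_stat(bx, sx, by, sy) -> float:
    ratios = by / bx
    weights = bx ** 2 / sy ** 2  # inverse first-order variance of the ratio
    return _weighted_median(ratios, weights)


def weighted_median(assoc: SnpAssociationSet, n_boot: int = 1000,
                    seed: int = 0) -> SummaryMrResult:
    """Weighted median of the Wald ratios.

    Consistent when variants contributing >= 50% of the weight are valid
    instruments.  Weights are normalized inverse variances of the ratios;
    the estimate interpolates the weighted 50th percentile; the SE comes
    from a parametric bootstrap of the summary statistics.
    """
    if len(assoc) == 1:
        return wald_ratio(assoc)
    if len(assoc) < 3:
        raise ValueError("weighted median needs >= 3 variants")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap SEs", stacklevel=2)
    bx, sx, by, sy = _arrays(assoc)
    est = _median_stat(bx, sx, by, sy)
    se = _bootstrap_se(assoc, _median_stat, n_boot, seed)
    return SummaryMrResult.build("weighted_median", est, se, len(assoc))


def _mode_stat(bx, sx, by, sy, bandwidth_factor=1.0) -> float:
    ratios = by / bx
    weights = bx ** 2 / sy ** 2
    weights = weights / weights.sum()
    med = _weighted_median(ratios, weights)
    mad = _weighted_median(np.abs(ratios - med), weights) * 1.4826
    spread = mad if mad > 0 else max(ratios.std(), np.finfo(float).eps)
    h = bandwidth_factor * 0.9 * spread * len(ratios) ** (-0.2)
    if h <= 0:
        raise ValueError("zero kernel bandwidth")
    lo = ratios.min() - 3 * h
    hi = ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 2048)
    dens = (weights[None, :] *
            np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(assoc: SnpAssociationSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> SummaryMrResult:
    """Mode of the smoothed weighted density of Wald ratios.

    Consistent when the largest group of variants sharing a ratio is
    valid (plurality assumption).  A Gaussian kernel with a weighted-MAD
    Silverman-type bandwidth (scaled by ``bandwidth_factor``) smooths the
    weight-scaled ratio density; the estimate is its argmax on a fine
    grid; SE via parametric bootstrap.
    """
    if len(assoc) == 1:
        return wald_ratio(assoc)
    if len(assoc) < 3:
        raise ValueError("weighted mode needs >= 3 variants")
    if bandwidth_factor <= 0:
        raise ValueError("zero kernel bandwidth")
    bx, sx, by, sy = _arrays(assoc)
    est = _mode_stat(bx, sx, by, sy, bandwidth_factor)
    se = _bootstrap_se(
        assoc, lambda *a: _mode_stat(*a, bandwidth_factor=bandwidth_factor),
        n_boot, seed)
    return SummaryMrResult.build("weighted_mode", est, se, len(assoc))


def run_all_estimators(assoc: SnpAssociationSet, n_boot: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """IVW, Egger, weighted median and weighted mode on one variant set."""
    results = [ivw(assoc), mr_egger(assoc),
               weighted_median(assoc, n_boot=n_boot, seed=seed),
               weighted_mode(assoc, n_boot=n_boot, seed=seed)]
    return pd.DataFrame([vars(r) for r in results])
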