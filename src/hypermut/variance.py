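"""Variance decomposition of per-child de novo SNV counts.

Counts are Poisson-noisy observations of an underlying per-child rate, so
only the super-Poisson part of the count variance, Var(Y) - mean(Y), is
explainable by covariates.  The fraction of that explainable variance
attributed to a model is

    F = R^2 * Var(Y) / (Var(Y) - mean(Y))

where R^2 defaults to the explained-variance ratio Var(fitted)/Var(Y)
(the ordinary-least-squares R^2 when the fit is OLS); McFadden's
likelihood-ratio pseudo-R^2 is available behind ``r2_method`` but is not
commensurable with variance fractions and will not recover a configured
explainable share.  Three nested identity-link NB models (parental age;
+ data-quality covariates; + hypermutation excess) give the component
increments; uncertainty comes from a case bootstrap over trios, and the
small-cohort instability of age-effect estimates is quantified by
repeatedly resampling 78 trios and refitting by OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agemodel import NbFit, build_design, fit_nb_identity

__all__ = [
    "poisson_corrected_fraction",
    "fraction_variance_explained",
    "VarianceReport",
    "hm_excess_covariate",
    "attribute_variance_components",
    "bootstrap_ci",
    "resampling_experiment",
    "DEFAULT_QC_COLUMNS",
]

DEFAULT_QC_COLUMNS = [
    "child_mean_rd", "mother_mean_rd", "father_mean_rd",
    "child_prop_aligned", "mother_prop_aligned", "father_prop_aligned",
    "child_snvs", "mother_snvs", "father_snvs",
    "median_vaf", "median_bf",
]


def poisson_corrected_fraction(r2: float, ybar: float, var: float,
                               formula: str = "corrected") -> float:
    """Rescale an R^2 to the non-Poisson (explainable) count variance.

    ``formula="corrected"``: F = r2 * Var/(Var - Ybar), the Poisson
    correction (share of super-Poisson variance explained).
    ``formula="printed"`` computes the literal published expression
    r2 * (1 - Ybar)/Var, which is dimensionally inconsistent (negative
    whenever Ybar > 1) and is provided for comparison only.
    """
    if formula == "printed":
        return r2 * (1.0 - ybar) / var
    if var <= ybar:
        raise ValueError(
            "Var(Y) <= mean(Y): no super-Poisson variance, F undefined")
    f = r2 * var / (var - ybar)
    if not 0.0 <= f <= 1.0:
        warnings.warn(f"Poisson-corrected fraction {f:.3f} outside [0, 1]; "
                      "clipping", stacklevel=2)
        f = float(np.clip(f, 0.0, 1.0))
    return float(f)


def _r2(fit: NbFit, y: np.ndarray, method: str) -> float:
    if method == "mcfadden":
        return fit.pseudo_r2
    if method == "variance":
        return float(np.var(fit.fitted) / np.var(y))
    raise ValueError(f"unknown r2 method {method!r}")


def fraction_variance_explained(fit: NbFit, counts,
                                r2_method: str = "variance",
                                formula: str = "corrected") -> float:
    """Poisson-corrected fraction of count variance explained by a fit."""
    y = np.asarray(counts, dtype=float)
    return poisson_corrected_fraction(
        _r2(fit, y, r2_method), float(y.mean()), float(y.var()),
        formula=formula)


@dataclass
class VarianceReport:
    f_age: float
    f_age_qc: float
    f_full: float
    increment_age: float
    increment_qc: float
    increment_hm: float
    residual_fraction: float
    pseudo_r2: dict = field(default_factory=dict)
    ybar: float = np.nan
    var: float = np.nan
    bootstrap_ci: tuple | None = None
    dropped_qc: list = field(default_factory=list)
    fits: dict = field(default_factory=dict)


def hm_excess_covariate(counts, child_ids, flagged_ids,
                        cohort_median: float | None = None) -> np.ndarray:
    """Excess-mutation covariate: observed - cohort median for flagged
    children, 0 for everyone else."""
    y = np.asarray(counts, dtype=float)
    med = float(np.median(y)) if cohort_median is None else cohort_median
    flagged = pd.Series(child_ids).isin(set(flagged_ids)).to_numpy()
    return np.where(flagged, y - med, 0.0)


def _drop_collinear(table: pd.DataFrame, cols: list[str]) -> tuple[list, list]:
    keep, dropped = [], []
    for c in cols:
        if table[c].std() == 0:
            dropped.append(c)
            continue
        X = table[keep + [c]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(X - X.mean(0)) <= len(keep):
            dropped.append(c)
        else:
            keep.append(c)
    if dropped:
        warnings.warn(f"dropping collinear/constant QC columns: {dropped}",
                      stacklevel=2)
    return keep, dropped


def attribute_variance_components(trios: pd.DataFrame, flagged_ids,
                                  count_col: str = "n_snv",
                                  qc_columns: list[str] | None = None,
                                  cohort_median: float | None = None,
                                  r2_method: str = "variance",
                                  standardize_qc: bool = True
                                  ) -> VarianceReport:
    """Fit the three nested identity-link NB models and split F.

    Model 1: parental ages.  Model 2: + per-member data-quality metrics.
    Model 3: + hypermutation excess (observed minus cohort median for the
    flagged children, zero otherwise).  Component increments telescope to
    the full-model F by construction; the residual fraction is 1 - F_full.
    """
    qc_columns = DEFAULT_QC_COLUMNS if qc_columns is None else qc_columns
    y = trios[count_col].to_numpy(dtype=float)
    work = trios.copy()
    qc_keep, dropped = _drop_collinear(work, qc_columns)
    if standardize_qc:
        for c in qc_keep:
            work[c] = (work[c] - work[c].mean()) / work[c].std()
    work["hm_excess"] = hm_excess_covariate(
        y, work["child_id"], flagged_ids, cohort_median)

    designs = {
        "age": ["father_age", "mother_age"],
        "age_qc": ["father_age", "mother_age"] + qc_keep,
        "full": ["father_age", "mother_age"] + qc_keep + ["hm_excess"],
    }
    fits, fvals, r2s = {}, {}, {}
    for name, cols in designs.items():
        fit = fit_nb_identity(y, build_design(work, cols),
                              names=["intercept"] + cols)
        fits[name] = fit
        fvals[name] = fraction_variance_explained(fit, y, r2_method)
        r2s[name] = {"mcfadden": fit.pseudo_r2,
                     "variance": _r2(fit, y, "variance")}
    return VarianceReport(
        f_age=fvals["age"], f_age_qc=fvals["age_qc"], f_full=fvals["full"],
        increment_age=fvals["age"],
        increment_qc=fvals["age_qc"] - fvals["age"],
        increment_hm=fvals["full"] - fvals["age_qc"],
        residual_fraction=1.0 - fvals["full"],
        pseudo_r2=r2s, ybar=float(y.mean()), var=float(y.var()),
        dropped_qc=dropped, fits=fits)


def bootstrap_ci(trios: pd.DataFrame, statistic, reps: int = 1000,
                 seed: int = 0, percentiles=(2.5, 97.5)
                 ) -> tuple[float, float, int]:
    """Case bootstrap over trios: percentile interval of ``statistic``.

    ``statistic(resampled_frame) -> float``.  Replicates in which the
    statistic fails are dropped and counted (third return value).
    """
    if reps < 2:
        raise ValueError("need reps >= 2")
    rng = np.random.default_rng(seed)
    n = len(trios)
    values, failures = [], 0
    for _ in range(reps):
        idx = rng.integers(0, n, n)
        try:
            values.append(float(statistic(trios.iloc[idx])))
        except Exception:
            failures += 1
    lo, hi = np.percentile(values, percentiles)
    return float(lo), float(hi), failures


def _ols_f(y: np.ndarray, x: np.ndarray) -> float:
    """OLS of counts on paternal age; Poisson-corrected F of its R^2."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    r2 = 1.0 - np.sum((y - fitted) ** 2) / np.sum((y - y.mean()) ** 2)
    var, ybar = y.var(), y.mean()
    if var <= ybar:
        return np.nan
    return float(np.clip(r2 * var / (var - ybar), 0.0, 1.5))


def resampling_experiment(trios: pd.DataFrame, n: int = 78,
                          reps: int = 10_000, seed: int = 0,
                          count_col: str = "n_snv") -> dict:
    """Stability of small-cohort age-effect estimates.

    Repeatedly subsample ``n`` trios without replacement, fit OLS of the
    SNV count on paternal age, and compute the Poisson-corrected explained
    fraction.  Summarizes the spread of the estimates (median, sd,
    2.5/97.5 percentiles, share of estimates at or above 0.95).
    """
    if len(trios) < n:
        raise ValueError("cohort smaller than the subsample size")
    rng = np.random.default_rng(seed)
    y_all = trios[count_col].to_numpy(dtype=float)
    x_all = trios["father_age"].to_numpy(dtype=float)
    fs = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(len(trios), size=n, replace=False)
        fs[r] = _ols_f(y_all[idx], x_all[idx])
    fs = fs[np.isfinite(fs)]
    fs_clipped = np.clip(fs, 0.0, 1.0)
    lo, hi = np.percentile(fs_clipped, [2.5, 97.5])
    return {
        "median": float(np.median(fs_clipped)),
        "sd": float(fs_clipped.std()),
        "ci": (float(lo), float(hi)),
        "frac_ge_95": float((fs_clipped >= 0.95).mean()),
        "n_valid": int(len(fs)),
    }
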