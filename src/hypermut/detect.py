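"""Detection and characterization of germline hypermutators.

A child is flagged when its de novo SNV count is a Bonferroni-significant
outlier of the identity-link NB parental-age model, tested at alpha / N
where N counts the analysed children after artifact exclusions (the model
is refit whenever the exclusion set changes).  Reports carry both the
studentized residual with its t p-value (df = N - 3) and the exact NB
tail p-value that drives the default flagging rule; see
``detect_hypermutators`` for why the two differ.

The artifact screen targets the known false-positive mode — a parental
somatic blood deletion ("loss of transmitted allele") that produces
clustered pseudo-DNM calls on one chromosome together with a regional
collapse of the parent's heterozygous/homozygous ratio.  Flagged children
are then characterized with per-type Poisson enrichment tests, a
phase-bias binomial test, a low-VAF shift test (post-zygotic signal) and
a transcriptional strand-bias test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .agemodel import NbFit, build_design, fit_nb_identity
from .stats import binom_two_sided_p, poisson_two_sided_p

__all__ = [
    "HypermutationReport",
    "studentized_residuals",
    "detect_hypermutators",
    "artifact_screen",
    "characterize_hypermutator",
    "excess_and_fold",
    "disease_risk",
    "MUTATION_TYPES",
]

MUTATION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G", "indel")


@dataclass
class HypermutationReport:
    child_id: str
    observed: int
    expected: float
    residual: float  # studentized residual
    p: float  # flagging p-value (see detect_hypermutators pvalue_method)
    threshold: float
    flagged: bool
    p_t: float | None = None  # studentized-residual t p (always reported)
    excess: int | None = None
    fold: float | None = None
    type_enrichment: dict = field(default_factory=dict)
    phase_bias_p: float | None = None
    vaf_shift_p: float | None = None
    strand_bias_p: float | None = None
    artifact_flags: dict = field(default_factory=dict)


def studentized_residuals(fit: NbFit) -> np.ndarray:
    """Pearson residuals scaled by sqrt(1 - leverage)."""
    h = np.clip(fit.leverage, 0.0, 1.0 - 1e-8)
    return fit.pearson_resid / np.sqrt(1.0 - h)


def nb_tail_pvalues(y: np.ndarray, mu: np.ndarray,
                    theta: float) -> np.ndarray:
    """Exact two-sided NB tail p-values (doubled smaller tail, capped)."""
    if np.isinf(theta):
        lo = stats.poisson.cdf(y, mu)
        hi = stats.poisson.sf(y - 1, mu)
    else:
        pr = theta / (theta + mu)
        lo = stats.nbinom.cdf(y, theta, pr)
        hi = stats.nbinom.sf(y - 1, theta, pr)
    return np.minimum(1.0, 2.0 * np.minimum(lo, hi))


def detect_hypermutators(trios: pd.DataFrame, count_col: str = "n_snv",
                         alpha: float = 0.05,
                         exclusions: set[str] | frozenset = frozenset(),
                         age_cols: tuple[str, str] = ("father_age",
                                                      "mother_age"),
                         pvalue_method: str = "exact",
                         ) -> tuple[list[HypermutationReport], NbFit]:
    """Scan a cohort for hypermutated children.

    Children in ``exclusions`` (identified artifacts) are removed before
    fitting, so the parental-age model and the Bonferroni denominator N
    reflect only the analysed children.  Every report carries the
    studentized residual and its two-sided t p-value with df = N - 3
    (``p_t``, the conventional GLM outlier construction); the
    flagging p-value is selected by ``pvalue_method``:

    - ``"exact"`` (default): two-sided tail of the fitted NB itself.
      Count distributions are right-skewed, so normal-approximation
      residual tests over-reject several-fold at Bonferroni-scale
      thresholds; the exact tail restores the family-wise guarantee at
      no material cost in power for 2-fold-and-above hypermutators.
    - ``"t"``: flag on the studentized-residual t p-value itself.
    """
    work = trios[~trios["child_id"].isin(exclusions)].reset_index(drop=True)
    n = len(work)
    if n <= 3:
        raise ValueError("need more than 3 analysed children")
    X = build_design(work, list(age_cols))
    y = work[count_col].to_numpy(dtype=float)
    fit = fit_nb_identity(y, X, names=["intercept", *age_cols])
    resid = studentized_residuals(fit)
    df = n - 3
    p_t = 2.0 * stats.t.sf(np.abs(resid), df)
    if pvalue_method == "t":
        pvals = p_t
    elif pvalue_method == "exact":
        pvals = nb_tail_pvalues(y, fit.fitted, fit.theta)
    else:
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
    threshold = alpha / n
    reports = [
        HypermutationReport(
            child_id=cid, observed=int(obs), expected=float(mu),
            residual=float(r), p=float(p), threshold=threshold,
            flagged=bool(p < threshold), p_t=float(pt))
        for cid, obs, mu, r, p, pt in zip(
            work["child_id"], y, fit.fitted, resid, pvals, p_t)
    ]
    reports.sort(key=lambda r: r.p)
    return reports, fit


def iterative_detection(trios: pd.DataFrame, screen_exclusions,
                        count_col: str = "n_snv", alpha: float = 0.05,
                        max_rounds: int = 5
                        ) -> tuple[list[HypermutationReport], NbFit, set[str]]:
    """Detect, screen flagged children for artifacts, exclude, refit.

    ``screen_exclusions(flagged_ids) -> set of artifact child ids`` is
    called on each round's flagged set; newly identified artifacts are
    excluded and the model refit, one round per exclusion update, until
    the exclusion set is stable.
    """
    excluded: set[str] = set()
    for _ in range(max_rounds):
        reports, fit = detect_hypermutators(
            trios, count_col=count_col, alpha=alpha, exclusions=excluded)
        flagged = [r.child_id for r in reports if r.flagged]
        artifacts = set(screen_exclusions(flagged)) - excluded
        if not artifacts:
            return reports, fit, excluded
        excluded |= artifacts
    return reports, fit, excluded


# ---------------------------------------------------------------------------

def artifact_screen(calls: pd.DataFrame, parental_bins: pd.DataFrame,
                    max_chrom_fraction: float = 0.5,
                    window_bp: int = 100_000,
                    loh_ratio_fraction: float = 0.5) -> dict:
    """Screen one child's calls for the loss-of-transmitted-allele mode.

    Sub-flag ``clustered``: more than ``max_chrom_fraction`` of the
    child's DNMs sit on a single chromosome AND concentrate within one
    ``window_bp`` window on it.  Sub-flag ``parental_loh``: within the
    implicated region (the trimmed extent of the clustered calls), a
    parent's het/hom ratio falls below ``loh_ratio_fraction`` of that
    parent's genome-wide ratio.  ``artifact`` requires both.
    """
    out = {"clustered": False, "parental_loh": False, "artifact": False,
           "chrom": None, "window": None, "parent": None}
    if len(calls) == 0:
        return out
    by_chrom = calls.groupby("chrom").size()
    top_chrom = by_chrom.idxmax()
    frac_chrom = by_chrom.max() / len(calls)
    pos = np.sort(calls.loc[calls["chrom"] == top_chrom, "pos"].to_numpy())
    # max number of calls inside any window of length window_bp
    j = np.searchsorted(pos, pos + window_bp, side="right")
    in_window = (j - np.arange(len(pos))).max() if len(pos) else 0
    frac_window = in_window / len(calls)
    concentrated = (frac_chrom > max_chrom_fraction
                    and frac_window > max_chrom_fraction)
    if concentrated:
        k = int(np.argmax(j - np.arange(len(pos))))
        # implicated region: trimmed extent of the calls inside the densest
        # window — robust to stray background calls at the flanks, which
        # would otherwise dilute the parental LOH signal
        inside = pos[k:j[k]]
        lo = int(np.percentile(inside, 2.5))
        hi = int(np.percentile(inside, 97.5)) + 1
        out.update(clustered=True, chrom=top_chrom, window=(lo, hi))
        if parental_bins is not None and len(parental_bins):
            for parent, g in parental_bins.groupby("parent"):
                genome_ratio = g["n_het"].sum() / max(g["n_hom"].sum(), 1)
                reg = g[(g["chrom"] == top_chrom)
                        & (g["bin_start"] < hi) & (g["bin_end"] > lo)]
                if len(reg) == 0:
                    continue
                ratio = reg["n_het"].sum() / max(reg["n_hom"].sum(), 1)
                if ratio < loh_ratio_fraction * genome_ratio:
                    out.update(parental_loh=True, parent=parent)
    out["artifact"] = out["clustered"] and out["parental_loh"]
    return out


# ---------------------------------------------------------------------------

@dataclass
class CohortReference:
    """Cohort-level expectations used to characterize a flagged child."""

    type_means: dict  # mutation type -> mean count per child
    paternal_fraction: float
    vaf_low_proportion: float  # cohort-wide P(VAF < 0.4)
    n_flagged: int  # Bonferroni denominator for the per-individual tests
    n_types: int = len(MUTATION_TYPES)


def cohort_reference(cohort_dnms: pd.DataFrame, phased_counts: pd.DataFrame,
                     n_children: int, n_flagged: int) -> CohortReference:
    """Build the reference expectations from cohort tables."""
    snv = cohort_dnms[cohort_dnms["vartype"] == "SNV"]
    cls = snv["context96"].str.extract(r"\[([ACGT]>[ACGT])\]")[0]
    type_means = {t: float((cls == t).sum()) / n_children
                  for t in MUTATION_TYPES if t != "indel"}
    type_means["indel"] = float(
        (cohort_dnms["vartype"] == "indel").sum()) / n_children
    n_pat = phased_counts["n_paternal"].sum()
    n_ph = n_pat + phased_counts["n_maternal"].sum()
    return CohortReference(
        type_means=type_means,
        paternal_fraction=float(n_pat / n_ph) if n_ph else 0.5,
        vaf_low_proportion=float((snv["vaf_child"] < 0.4).mean()),
        n_flagged=n_flagged)


def characterize_hypermutator(report: HypermutationReport,
                              calls: pd.DataFrame,
                              n_paternal: int, n_maternal: int,
                              reference: CohortReference,
                              alpha: float = 0.05) -> HypermutationReport:
    """Fill a flagged child's report with the per-individual tests.

    Per mutation type: two-sided Poisson test of the child's count against
    the cohort mean (Bonferroni over n_flagged x 7 tests).  Phase bias:
    two-sided binomial test of the maternal count among phased DNMs
    against the cohort paternal fraction.  VAF shift: two-sided binomial
    test of the number of low-VAF (< 0.4) SNVs against the cohort
    proportion.  Strand bias: two-sided Poisson test of transcribed-strand
    SNVs against half of the stranded total.
    """
    snv = calls[calls["vartype"] == "SNV"]
    cls = snv["context96"].str.extract(r"\[([ACGT]>[ACGT])\]")[0]
    enrich = {}
    for t in MUTATION_TYPES:
        obs = int((calls["vartype"] == "indel").sum()) if t == "indel" \
            else int((cls == t).sum())
        mean = reference.type_means.get(t, 0.0)
        if mean <= 0:
            enrich[t] = {"observed": obs, "expected": mean,
                         "enrichment": None, "p": None,
                         "note": "undefined (zero cohort mean)"}
            continue
        enrich[t] = {
            "observed": obs, "expected": mean,
            "enrichment": obs / mean,
            "p": poisson_two_sided_p(obs, mean),
        }
    report.type_enrichment = enrich
    n_ph = n_paternal + n_maternal
    report.phase_bias_p = binom_two_sided_p(
        n_maternal, n_ph, 1.0 - reference.paternal_fraction) if n_ph else None
    n_low = int((snv["vaf_child"] < 0.4).sum())
    report.vaf_shift_p = binom_two_sided_p(
        n_low, len(snv), reference.vaf_low_proportion) if len(snv) else None
    stranded = snv[snv["tx_strand"].isin(["T", "U"])]
    n_t = int((stranded["tx_strand"] == "T").sum())
    report.strand_bias_p = poisson_two_sided_p(
        n_t, len(stranded) / 2.0) if len(stranded) else None
    return report


def multiple_testing_threshold(alpha: float, n_individuals: int,
                               n_types: int = 7) -> float:
    """Bonferroni threshold for the per-type enrichment test battery."""
    return alpha / (n_individuals * n_types)


def excess_and_fold(observed: int, cohort_median: float
                    ) -> tuple[int, float]:
    """Excess = observed - cohort median; fold = observed / median
    (reported to one decimal)."""
    if cohort_median <= 0:
        raise ValueError("cohort median must be positive")
    excess = int(observed - cohort_median)
    fold = round(observed / cohort_median, 1)
    return excess, fold


def disease_risk(fold_increase: float, baseline: float = 1 / 300) -> float:
    """Absolute risk of a dominant developmental disorder caused by a DNM,
    scaled from the population baseline by the child's fold increase."""
    if fold_increase < 0:
        raise ValueError("fold must be >= 0")
    return fold_increase * baseline
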