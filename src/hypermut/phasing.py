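"""Read-backed parent-of-origin phasing of de novo mutations.

A DNM is phased through heterozygous "informative" sites within 500 bp
whose child alleles can each be attributed to a unique parent (sites
heterozygous in both parents and the child carry no information and are
excluded).  Read pairs observing both loci vote: a DNM is called paternal
or maternal only when every DNM-bearing read co-occurs with alleles of a
single parent; mixed evidence is a conflict, and absent co-coverage is
unphaseable.

The cohort-level paternal fraction is modelled as a linear (identity-link
binomial) function of paternal age, mirroring the additive per-year
statement of the phased-fraction trend; a logit link is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import Cohort, InformativeSite

__all__ = [
    "PhaseCall",
    "find_informative_sites",
    "phase_dnm",
    "phase_reads_table",
    "phase_cohort",
    "BinomialIdentityFit",
    "fit_paternal_fraction",
]

WINDOW_BP = 500  # inclusive boundary


@dataclass
class PhaseCall:
    dnm_id: str
    result: str  # paternal | maternal | unphased_no_data | unphased_conflict
    n_paternal_reads: int
    n_maternal_reads: int


def _split_gt(gt: str) -> list[str]:
    return gt.replace("|", "/").split("/")


def find_informative_sites(dnm, trio_variants: pd.DataFrame,
                           window: int = WINDOW_BP) -> list[InformativeSite]:
    """Informative heterozygous sites within ``window`` bp of the DNM.

    ``trio_variants`` columns: chrom, pos, a1, a2 (child alleles),
    gt_child, gt_father, gt_mother expressed as allele strings
    (e.g. "A/G").  A site is informative iff the child is heterozygous and
    each child allele is attributable to exactly one parent; sites
    heterozygous in both parents and the child are excluded.
    """
    out: list[InformativeSite] = []
    near = trio_variants[
        (trio_variants["chrom"] == dnm["chrom"])
        & (np.abs(trio_variants["pos"] - dnm["pos"]) <= window)
        & (trio_variants["pos"] != dnm["pos"])]
    for _, site in near.iterrows():
        child = _split_gt(site["gt_child"])
        if len(set(child)) != 2:
            continue
        a1, a2 = child
        fa = set(_split_gt(site["gt_father"]))
        mo = set(_split_gt(site["gt_mother"]))
        if set(child) <= fa and set(child) <= mo:
            continue  # heterozygous in both parents and offspring
        assignment: dict[str, str] = {}
        for allele, other in ((a1, a2), (a2, a1)):
            in_fa, in_mo = allele in fa, allele in mo
            if in_fa and not in_mo:
                assignment[allele] = "father"
                assignment.setdefault(other, "mother")
            elif in_mo and not in_fa:
                assignment[allele] = "mother"
                assignment.setdefault(other, "father")
        if (len(assignment) == 2
                and set(assignment.values()) == {"father", "mother"}
                and assignment[a1] != assignment[a2]
                and a1 in (fa | mo) and a2 in (fa | mo)):
            out.append(InformativeSite(
                chrom=site["chrom"], pos=int(site["pos"]), a1=a1, a2=a2,
                parent_of={a1: assignment[a1], a2: assignment[a2]},
                distance=int(abs(site["pos"] - dnm["pos"]))))
    return out


def phase_dnm(dnm, sites: list[InformativeSite],
              reads: pd.DataFrame) -> PhaseCall:
    """Phase one DNM from read evidence across its informative sites.

    Counts reads that carry the DNM alternative allele together with a
    parent-attributable site allele.  Paternal/maternal only if all
    evidence points to one parent; both parents observed is a conflict;
    no co-covering DNM-bearing read is no-data.  A read pair counts once
    per (read_id, site) even if both mates cover both loci.
    """
    dnm_id = dnm.get("dnm_id", "dnm")
    locus_a = f"{dnm['chrom']}:{dnm['pos']}"
    n_pat = n_mat = 0
    if len(reads) == 0:
        sites = []
    for site in sites:
        locus_b = f"{site.chrom}:{site.pos}"
        sub = reads[(reads["locus_a"] == locus_a)
                    & (reads["locus_b"] == locus_b)]
        sub = sub.drop_duplicates(subset="read_id")
        carrying = sub[sub["allele_a"] == dnm["alt"]]
        for allele in carrying["allele_b"]:
            parent = site.parent_of.get(allele)
            if parent == "father":
                n_pat += 1
            elif parent == "mother":
                n_mat += 1
    if n_pat == 0 and n_mat == 0:
        result = "unphased_no_data"
    elif n_pat > 0 and n_mat > 0:
        result = "unphased_conflict"
    else:
        result = "paternal" if n_pat > 0 else "maternal"
    return PhaseCall(dnm_id=dnm_id, result=result,
                     n_paternal_reads=n_pat, n_maternal_reads=n_mat)


def phase_reads_table(dnms: pd.DataFrame, sites: pd.DataFrame,
                      reads: pd.DataFrame) -> pd.DataFrame:
    """Vectorized phasing of many DNMs against the site/read tables
    produced by the simulator (one informative site per DNM).

    Returns a frame with dnm_id, result and per-parent read counts.
    """
    alt = dnms.set_index("dnm_id")["alt"]
    r = reads.merge(
        sites[["dnm_id", "a1", "a2", "parent_of_a1", "parent_of_a2"]],
        on="dnm_id", how="inner")
    r = r.drop_duplicates(subset=["read_id", "dnm_id"])
    r["dnm_alt"] = r["dnm_id"].map(alt)
    carrying = r[r["allele_a"] == r["dnm_alt"]].copy()
    parent = np.where(carrying["allele_b"] == carrying["a1"],
                      carrying["parent_of_a1"], carrying["parent_of_a2"])
    carrying["vote"] = parent
    votes = carrying.pivot_table(index="dnm_id", columns="vote",
                                 aggfunc="size", fill_value=0)
    out = pd.DataFrame(index=dnms["dnm_id"])
    out["n_paternal_reads"] = votes.get(
        "father", pd.Series(0, index=votes.index)).reindex(
            out.index).fillna(0).astype(int)
    out["n_maternal_reads"] = votes.get(
        "mother", pd.Series(0, index=votes.index)).reindex(
            out.index).fillna(0).astype(int)
    np_, nm = out["n_paternal_reads"], out["n_maternal_reads"]
    out["result"] = np.select(
        [(np_ == 0) & (nm == 0), (np_ > 0) & (nm > 0), np_ > 0],
        ["unphased_no_data", "unphased_conflict", "paternal"], "maternal")
    return out.reset_index()


@dataclass
class BinomialIdentityFit:
    """Binomial regression of the paternal proportion on paternal age."""

    intercept: float
    slope: float
    se: np.ndarray
    pvalues: np.ndarray
    loglik: float
    link: str
    nobs: int
    reference_age: float = 0.0

    def predict(self, age) -> np.ndarray:
        x = np.asarray(age, dtype=float) - self.reference_age
        if self.link == "identity":
            return np.clip(self.intercept + self.slope * x, 0.0, 1.0)
        return special.expit(self.intercept + self.slope * x)


def fit_paternal_fraction(n_paternal, n_phased, paternal_age,
                          link: str = "identity") -> BinomialIdentityFit:
    """ML binomial regression of paternal counts out of phased counts.

    With the identity link, p_i = a + b * paternal_age_i (constrained to
    (0,1)); the slope is the additive change in paternal fraction per year
    of paternal age.  Trios with zero phased DNMs are excluded.
    """
    k = np.asarray(n_paternal, dtype=float)
    n = np.asarray(n_phased, dtype=float)
    x = np.asarray(paternal_age, dtype=float)
    use = n > 0
    k, n, x = k[use], n[use], x[use]
    if len(k) == 0:
        raise ValueError("no trios with phased DNMs")

    if link == "logit":
        import statsmodels.api as sm

        X = np.column_stack([np.ones_like(x), x])
        res = sm.GLM(np.column_stack([k, n - k]), X,
                     family=sm.families.Binomial()).fit()
        return BinomialIdentityFit(
            intercept=float(res.params[0]), slope=float(res.params[1]),
            se=np.asarray(res.bse), pvalues=np.asarray(res.pvalues),
            loglik=float(res.llf), link="logit", nobs=len(k))

    eps = 1e-9
    if np.all(k == n) or np.all(k == 0):
        # degenerate boundary: fraction 0 or 1 for every trio, flat in age
        p_hat = float(k.sum() / n.sum())
        return BinomialIdentityFit(
            intercept=p_hat, slope=0.0, se=np.full(2, np.nan),
            pvalues=np.full(2, np.nan), loglik=0.0, link="identity",
            nobs=len(k))

    def negll(par):
        p = par[0] + par[1] * x
        if np.any(p <= 0) or np.any(p >= 1):
            return np.inf
        return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    def jac(par):
        p = np.clip(par[0] + par[1] * x, eps, 1 - eps)
        g = k / p - (n - k) / (1 - p)
        return -np.array([g.sum(), (g * x).sum()])

    p0 = np.clip(k.sum() / n.sum(), eps, 1 - eps)
    start = np.array([p0, 0.0])
    cons = [{"type": "ineq", "fun": lambda b: b[0] + b[1] * x - eps},
            {"type": "ineq", "fun": lambda b: 1 - eps - (b[0] + b[1] * x)}]
    res = optimize.minimize(negll, start, jac=jac, method="SLSQP",
                            constraints=cons,
                            options={"maxiter": 300, "ftol": 1e-12})
    if not res.success:
        raise RuntimeError(f"binomial identity fit failed: {res.message}")
    a, b = res.x
    # observed information by finite differences of the analytic score
    h = 1e-6
    H = np.zeros((2, 2))
    for j in range(2):
        dp = res.x.copy(); dp[j] += h
        dm = res.x.copy(); dm[j] -= h
        H[:, j] = (jac(dp) - jac(dm)) / (2 * h)
    try:
        cov = np.linalg.inv((H + H.T) / 2)
        var = np.diag(cov).copy()
        var[var < 0] = np.nan
        se = np.sqrt(var)
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
    z = res.x / se
    pv = 2 * stats.norm.sf(np.abs(z))
    return BinomialIdentityFit(intercept=float(a), slope=float(b), se=se,
                               pvalues=pv, loglik=-float(res.fun),
                               link="identity", nobs=len(k))


def phase_cohort(cohort: Cohort, sites: pd.DataFrame, reads: pd.DataFrame
                 ) -> tuple[pd.DataFrame, pd.DataFrame, BinomialIdentityFit]:
    """Phase every SNV DNM in the cohort and model the paternal fraction.

    Returns (per-DNM phase calls, per-trio counts with columns
    n_paternal/n_maternal/n_conflict/n_unphased, identity-link binomial
    fit of paternal proportion on paternal age).
    """
    if cohort.dnms is None:
        raise ValueError("cohort has no DNM records")
    snv = cohort.dnms[cohort.dnms["vartype"] == "SNV"]
    calls = phase_reads_table(snv, sites, reads)
    calls = calls.merge(snv[["dnm_id", "trio_id"]], on="dnm_id")
    per_trio = calls.pivot_table(index="trio_id", columns="result",
                                 aggfunc="size", fill_value=0)
    counts = pd.DataFrame(index=cohort.trios["trio_id"])
    for col, name in [("paternal", "n_paternal"), ("maternal", "n_maternal"),
                      ("unphased_conflict", "n_conflict"),
                      ("unphased_no_data", "n_unphased")]:
        counts[name] = per_trio.get(
            col, pd.Series(0, index=per_trio.index)).reindex(
                counts.index).fillna(0).astype(int)
    counts = counts.reset_index().merge(
        cohort.trios[["trio_id", "father_age", "mother_age"]], on="trio_id")
    n_phased = counts["n_paternal"] + counts["n_maternal"]
    fit = fit_paternal_fraction(counts["n_paternal"], n_phased,
                                counts["father_age"])
    return calls, counts, fit
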