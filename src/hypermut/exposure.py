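"""Parental cancer / chemotherapy exposure before conception.

Parents are classified from coded hospital records (ICD10-like): a parent
is *eligible* for comparison if any record predates the child's birth
year by at least two years (the year-resolution proxy for "before
conception"); a cancer diagnosis before conception is any 'C'-prefix
(malignant neoplasm) or 'Z85' (personal history of malignant neoplasm)
code at least two years before the birth year, and 'Z511' marks an
antineoplastic-chemotherapy encounter.

Offspring effects are tested on the residuals of the full NB model
(two-sided Wilcoxon rank-sum), by an age-matched control comparison
(20 controls per case, sampled with replacement), and by a Fisher exact
test of hypermutation status between exposed and unexposed parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stats import fisher_two_sided

__all__ = [
    "ParentalHistory",
    "classify_parental_history",
    "exposure_group_test",
    "matched_cohort_test",
    "hypermutation_enrichment_test",
]


@dataclass
class ParentalHistory:
    parent_id: str
    eligible: bool
    cancer_before_conception: bool
    chemo_code: bool
    qualifying_codes: list = field(default_factory=list)
    n_malformed: int = 0


def _valid_code(code) -> bool:
    return isinstance(code, str) and len(code) >= 1 and code[0].isalpha()


def classify_parental_history(records: pd.DataFrame,
                              child_birth_year: int,
                              parent_id: str | None = None
                              ) -> ParentalHistory:
    """Classify one parent's records against a child's birth year.

    ``records`` columns: parent_id, icd10_code, year.  Malformed codes are
    ignored and tallied.  Classification is deterministic and independent
    of record order.
    """
    if parent_id is None:
        if records["parent_id"].nunique() > 1:
            raise ValueError("records contain several parents; "
                             "pass parent_id")
        parent_id = records["parent_id"].iloc[0] if len(records) else "NA"
    rec = records[records["parent_id"] == parent_id]
    cutoff = child_birth_year - 2
    malformed = 0
    eligible = False
    cancer = False
    chemo = False
    qualifying = []
    for _, row in rec.iterrows():
        code, year = row["icd10_code"], row["year"]
        if not _valid_code(code) or pd.isna(year):
            malformed += 1
            continue
        code = code.strip().upper()
        year = int(year)
        if year <= cutoff:
            eligible = True
            if code.startswith("C") or code.startswith("Z85"):
                cancer = True
                qualifying.append((code, year))
            if code.startswith("Z511"):
                chemo = True
                qualifying.append((code, year))
    return ParentalHistory(
        parent_id=parent_id, eligible=eligible,
        cancer_before_conception=cancer, chemo_code=chemo,
        qualifying_codes=sorted(qualifying), n_malformed=malformed)


def exposure_group_test(residuals, exposed_flags) -> dict:
    """Two-sided Wilcoxon rank-sum test of exposed vs unexposed residuals.

    ``residuals`` are per-child residuals from the full NB model
    (parental age + data quality + hypermutation status).
    """
    r = np.asarray(residuals, dtype=float)
    g = np.asarray(exposed_flags, dtype=bool)
    if g.sum() == 0 or (~g).sum() == 0:
        raise ValueError("both groups must be non-empty")
    exposed, unexposed = r[g], r[~g]
    if np.array_equal(np.sort(exposed), np.sort(unexposed)):
        p = 1.0
    else:
        _, p = stats.mannwhitneyu(exposed, unexposed,
                                  alternative="two-sided")
    return {
        "p": float(p),
        "median_exposed": float(np.median(exposed)),
        "median_unexposed": float(np.median(unexposed)),
        "n_exposed": int(g.sum()),
        "n_unexposed": int((~g).sum()),
    }


def matched_cohort_test(cases: pd.DataFrame, cohort: pd.DataFrame,
                        k: int = 20, seed: int = 0,
                        count_col: str = "n_snv",
                        calipers=(0, 1, 2)) -> dict:
    """Compare case counts with age-matched controls.

    For each case, ``k`` controls are drawn with replacement from cohort
    children matched on paternal AND maternal age: an exact year match is
    attempted first, then the caliper widens (default to +-1 then +-2
    years).  Cases with no control inside the widest caliper are dropped
    with a warning count.  Reports the case-vs-matched-control median
    difference and a two-sided Wilcoxon rank-sum p.
    """
    rng = np.random.default_rng(seed)
    pool = cohort[~cohort["child_id"].isin(set(cases["child_id"]))]
    pa = np.round(pool["father_age"].to_numpy(dtype=float))
    ma = np.round(pool["mother_age"].to_numpy(dtype=float))
    control_counts, dropped = [], 0
    for _, case in cases.iterrows():
        cfa = round(float(case["father_age"]))
        cma = round(float(case["mother_age"]))
        chosen = None
        for cal in calipers:
            ok = (np.abs(pa - cfa) <= cal) & (np.abs(ma - cma) <= cal)
            if ok.any():
                chosen = rng.choice(np.flatnonzero(ok), size=k, replace=True)
                break
        if chosen is None:
            dropped += 1
            continue
        control_counts.extend(pool[count_col].to_numpy()[chosen])
    case_counts = cases[count_col].to_numpy(dtype=float)
    if len(control_counts) == 0:
        raise ValueError("no matched controls found")
    controls = np.asarray(control_counts, dtype=float)
    _, p = stats.mannwhitneyu(case_counts, controls, alternative="two-sided")
    return {
        "median_cases": float(np.median(case_counts)),
        "median_controls": float(np.median(controls)),
        "median_difference": float(np.median(case_counts)
                                   - np.median(controls)),
        "p": float(p),
        "n_cases_dropped": dropped,
    }


def hypermutation_enrichment_test(exposed: tuple[int, int],
                                  unexposed: tuple[int, int]) -> dict:
    """Fisher exact test of hypermutation between exposure groups.

    ``exposed``/``unexposed`` are (n_hypermutated, n_total) pairs; the 2x2
    table is hyper/non-hyper by exposed/unexposed.
    """
    (a, na), (b, nb) = exposed, unexposed
    if not (0 <= a <= na and 0 <= b <= nb):
        raise ValueError("need 0 <= n_hyper <= n_total in each group")
    if na == 0 or nb == 0:
        raise ValueError("empty margin")
    table = [[a, na - a], [b, nb - b]]
    odds, p = fisher_two_sided(table)
    return {"odds_ratio": odds, "p": p, "table": table}
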