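"""De novo mutation call filters.

Two filter sets with per-rule accounting:

* the whole-genome trio-cohort set (autosomal + X rules): trio genotype
  configuration, per-member read depth, parental alternative reads, child
  allele balance, a 20-bp SNV cluster rule, an upper depth bound, and
  segmental-duplication / simple-repeat masks;
* the follow-up whole-genome set for exome-flagged trios (the
  eleven-rule list): looser depths, a
  child alt-read minimum, strand-bias and population-frequency rules,
  parental VAF bounds, a caller-posterior cutoff, a per-site error-rate
  test and an upper depth bound.

All printed inequalities are applied strictly as written (">" excludes
equality).  A call is kept iff it passes every rule; the returned tally
counts failures per rule, and a call may fail several.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionMask",
    "read_bed",
    "apply_autosomal_filters",
    "cluster_filter",
    "apply_x_filters",
    "apply_followup_wgs_filters",
]


@dataclass
class RegionMask:
    """A labelled set of half-open 0-based intervals per chromosome."""

    label: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.intervals = {c: self._normalize(iv)
                          for c, iv in self.intervals.items()}

    @staticmethod
    def _normalize(iv) -> np.ndarray:
        iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
        if len(iv) == 0:
            return iv
        iv = iv[np.argsort(iv[:, 0])]
        merged = [iv[0].tolist()]
        for s, e in iv[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return np.asarray(merged, dtype=np.int64)

    def contains(self, chroms, pos_1based) -> np.ndarray:
        """Vectorized point-in-interval on 1-based call positions."""
        chroms = np.asarray(chroms, dtype=object)
        pos0 = np.asarray(pos_1based, dtype=np.int64) - 1
        out = np.zeros(len(pos0), dtype=bool)
        for chrom, iv in self.intervals.items():
            if len(iv) == 0:
                continue
            m = chroms == chrom
            if not m.any():
                continue
            idx = np.searchsorted(iv[:, 0], pos0[m], side="right") - 1
            hit = (idx >= 0) & (pos0[m] < iv[np.clip(idx, 0, None), 1])
            out[m] = hit
        return out


def read_bed(path, label: str) -> RegionMask:
    """Read a standard BED (0-based half-open; first three columns used)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    intervals = {c: g[["start", "end"]].to_numpy()
                 for c, g in df.groupby("chrom")}
    return RegionMask(label=label, intervals=intervals)


def _gt_config(df, child="0/1", father="0/0", mother="0/0",
               child_alt=None) -> np.ndarray:
    ok_child = df["gt_child"].isin([child] if child_alt is None
                                   else [child, child_alt])
    return (ok_child & (df["gt_father"] == father)
            & (df["gt_mother"] == mother)).to_numpy()


def _require(df, columns) -> np.ndarray:
    """Rows with every required field present and non-null."""
    ok = np.ones(len(df), dtype=bool)
    for c in columns:
        if c not in df.columns:
            return np.zeros(len(df), dtype=bool)
        ok &= df[c].notna().to_numpy()
    return ok


_AUTOSOMAL_REQUIRED = ["gt_child", "gt_father", "gt_mother", "rd_child",
                       "rd_father", "rd_mother", "altreads_father",
                       "altreads_mother", "vaf_child", "chrom", "pos"]


def _tally(rules: dict[str, np.ndarray]) -> pd.Series:
    """Failure counts per rule (a call may fail several)."""
    return pd.Series({name: int((~ok).sum()) for name, ok in rules.items()},
                     name="n_failed")


def apply_autosomal_filters(calls: pd.DataFrame, masks=()
                            ) -> tuple[pd.DataFrame, pd.Series]:
    """Autosomal rules of the whole-genome trio filter set.

    Rules: child heterozygous 0/1 with both parents 0/0; all three read
    depths > 20; at most 1 alternative read in each parent; child VAF
    strictly inside (0.3, 0.7); child depth <= 98; outside every supplied
    mask; SNVs without another SNV from the same child within 20 bp.
    Incomplete records fail "incomplete-record" and are never silently
    passed.
    """
    df = calls.reset_index(drop=True)
    complete = _require(df, _AUTOSOMAL_REQUIRED)
    incomplete = ~complete

    # incomplete records fail only "incomplete-record", not every rule
    rules: dict[str, np.ndarray] = {"incomplete-record": complete}
    rules["genotype"] = _gt_config(df) | incomplete
    with np.errstate(invalid="ignore"):
        rd = lambda c: pd.to_numeric(df[c], errors="coerce").to_numpy(float)
        rules["depth"] = ((rd("rd_child") > 20) & (rd("rd_mother") > 20)
                          & (rd("rd_father") > 20)) | incomplete
        rules["parental-alt"] = ((rd("altreads_father") <= 1)
                                 & (rd("altreads_mother") <= 1)) | incomplete
        vaf = rd("vaf_child")
        rules["vaf"] = ((vaf > 0.3) & (vaf < 0.7)) | incomplete
        rules["max-depth"] = (rd("rd_child") <= 98) | incomplete
    masked = np.zeros(len(df), dtype=bool)
    for mask in masks:
        masked |= mask.contains(df["chrom"], df["pos"])
    rules["region-mask"] = ~masked
    rules["snv-cluster"] = _cluster_ok(df)
    kept = np.ones(len(df), dtype=bool)
    for ok in rules.values():
        kept &= ok
    return df[kept].copy(), _tally(rules)


def _cluster_ok(df: pd.DataFrame) -> np.ndarray:
    """True for calls not violating the 20-bp same-child SNV cluster rule.

    Clustering is per child, per chromosome and transitive: every SNV
    within 20 bp (inclusive) of another SNV from the same child fails, as
    do all members of a chained cluster.  Indels are exempt.
    """
    ok = np.ones(len(df), dtype=bool)
    if "vartype" in df.columns:
        is_snv = (df["vartype"] == "SNV").to_numpy()
    else:
        is_snv = (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)
        is_snv = is_snv.to_numpy()
    child_col = "child_id" if "child_id" in df.columns else "trio_id"
    sub = df[is_snv]
    for (child, chrom), g in sub.groupby([child_col, "chrom"], sort=False):
        pos = g["pos"].to_numpy()
        order = np.argsort(pos)
        ps = pos[order]
        close_next = np.diff(ps) <= 20
        bad_sorted = np.zeros(len(ps), dtype=bool)
        bad_sorted[:-1] |= close_next
        bad_sorted[1:] |= close_next
        bad = np.zeros(len(ps), dtype=bool)
        bad[order] = bad_sorted
        ok[g.index[bad]] = False
    return ok


def cluster_filter(snv_calls: pd.DataFrame) -> pd.DataFrame:
    """Remove all members of 20-bp same-child SNV clusters."""
    df = snv_calls.reset_index(drop=True)
    return df[_cluster_ok(df)].copy()


def apply_x_filters(calls: pd.DataFrame, par_mask: RegionMask | None,
                    child_sex: pd.Series | dict
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """X-chromosome rules.

    Pseudoautosomal (PAR) calls use the autosomal rules, additionally
    allowing hemizygous (1) child genotypes in males.  Outside the PAR:
    males need a hemizygous child and homozygous-reference mother with
    child and mother depth > 20 (no paternal depth rule); females keep the
    heterozygous configuration with father depth > 10 instead of > 20.
    Children of unknown sex fail "sex-unknown".
    """
    df = calls.reset_index(drop=True)
    sexes = pd.Series(child_sex)
    child_col = "child_id" if "child_id" in df.columns else "trio_id"
    sex = df[child_col].map(sexes)
    known = sex.isin(["M", "F"]).to_numpy()
    complete = _require(df, _AUTOSOMAL_REQUIRED) & known

    in_par = np.zeros(len(df), dtype=bool)
    if par_mask is not None:
        in_par = par_mask.contains(df["chrom"], df["pos"])

    rd = lambda c: pd.to_numeric(df[c], errors="coerce").to_numpy(float)
    vaf = rd("vaf_child")
    male = (sex == "M").to_numpy()
    female = (sex == "F").to_numpy()

    # PAR: autosomal rules, hemizygous allowed for males
    het = _gt_config(df)
    hemi = ((df["gt_child"] == "1") & (df["gt_father"] == "0/0")
            & (df["gt_mother"] == "0/0")).to_numpy()
    gt_par = het | (male & hemi)
    depth_par = (rd("rd_child") > 20) & (rd("rd_mother") > 20) & \
        (rd("rd_father") > 20)
    keep_par = gt_par & depth_par & (rd("altreads_father") <= 1) & \
        (rd("altreads_mother") <= 1) & (vaf > 0.3) & (vaf < 0.7) & \
        (rd("rd_child") <= 98)

    # non-PAR males: hemizygous child, mother 0/0, no father depth rule
    gt_m = ((df["gt_child"] == "1") & (df["gt_mother"] == "0/0")).to_numpy()
    keep_m = gt_m & (rd("rd_child") > 20) & (rd("rd_mother") > 20)
    # non-PAR females: heterozygous configuration, father depth > 10
    keep_f = het & (rd("rd_child") > 20) & (rd("rd_mother") > 20) & \
        (rd("rd_father") > 10)

    keep = complete & np.where(
        in_par, keep_par, np.where(male, keep_m, keep_f))
    rules = {
        "sex-unknown": known,
        "incomplete-record": _require(df, _AUTOSOMAL_REQUIRED),
        "x-rules": keep | ~complete,
    }
    return df[keep].copy(), _tally(rules)


_FOLLOWUP_REQUIRED = ["rd_child", "rd_father", "rd_mother", "altreads_child",
                 "altreads_father", "altreads_mother", "vaf_father",
                 "vaf_mother", "gnomad_af", "posterior", "site_error_rate"]


def apply_followup_wgs_filters(calls: pd.DataFrame, masks=(),
                      strand_bias_level: float = 0.001,
                      error_test_alpha: float = 0.05
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """The eleven-rule follow-up whole-genome filter set.

    Rules: all three depths > 10; child alt reads > 2; strand-bias Fisher
    p > 0.001; outside segmental-duplication and repeat masks; gnomAD
    allele frequency < 0.01; both parental VAFs < 0.1; not both parents
    with > 1 alt read; child VAF above the per-site error rate (one-sided
    binomial test at ``error_test_alpha``); caller posterior > 0.00781;
    child depth <= 200.

    A rule whose input field is absent or null is recorded as
    "not-evaluable" and the call removed (conservative).
    """
    df = calls.reset_index(drop=True)
    n = len(df)
    rd = lambda c: (pd.to_numeric(df[c], errors="coerce").to_numpy(float)
                    if c in df.columns else np.full(n, np.nan))

    def both(a, b):
        """Elementwise AND of 1/0/nan arrays, nan-propagating."""
        return a * b

    # 1.0 = pass, 0.0 = fail, nan = not evaluable (missing inputs)
    rules: dict[str, np.ndarray] = {}
    with np.errstate(invalid="ignore"):
        def cmp(vals, op):
            out = op(vals).astype(float)
            out[~np.isfinite(vals)] = np.nan
            return out

        rules["depth"] = both(both(cmp(rd("rd_child"), lambda v: v > 10),
                                   cmp(rd("rd_mother"), lambda v: v > 10)),
                              cmp(rd("rd_father"), lambda v: v > 10))
        rules["child-alt-reads"] = cmp(rd("altreads_child"), lambda v: v > 2)
        rules["strand-bias"] = _strand_bias_ok(df, strand_bias_level)
        masked = np.zeros(n, dtype=bool)
        for mask in masks:
            masked |= mask.contains(df["chrom"], df["pos"])
        rules["region-mask"] = (~masked).astype(float)
        rules["gnomad-af"] = cmp(rd("gnomad_af"), lambda v: v < 0.01)
        rules["parental-vaf"] = both(cmp(rd("vaf_father"), lambda v: v < 0.1),
                                     cmp(rd("vaf_mother"), lambda v: v < 0.1))
        fa_hi = cmp(rd("altreads_father"), lambda v: v > 1)
        mo_hi = cmp(rd("altreads_mother"), lambda v: v > 1)
        rules["both-parents-alt"] = 1.0 - both(fa_hi, mo_hi)
        rules["site-error"] = _error_site_ok(df, error_test_alpha)
        rules["posterior"] = cmp(rd("posterior"), lambda v: v > 0.00781)
        rules["max-depth"] = cmp(rd("rd_child"), lambda v: v <= 200)

    not_evaluable = np.zeros(n, dtype=bool)
    for name, ok in rules.items():
        ok = np.asarray(ok, dtype=float)
        nan_rows = ~np.isfinite(ok)
        not_evaluable |= nan_rows
        rules[name] = np.where(nan_rows, False, ok > 0.5)
    rules["not-evaluable"] = ~not_evaluable

    kept = np.ones(n, dtype=bool)
    for ok in rules.values():
        kept &= ok
    return df[kept].copy(), _tally(rules)


def _strand_bias_ok(df: pd.DataFrame, level: float) -> np.ndarray:
    """Strand-bias rule: keep if Fisher p > level.

    Uses a precomputed ``strand_bias_p`` column when present; otherwise the
    2x2 table is forward/reverse alternative reads in the child versus both
    parents combined (columns ``sb_child_fwd``, ``sb_child_rev``,
    ``sb_parents_fwd``, ``sb_parents_rev``).
    """
    n = len(df)
    if "strand_bias_p" in df.columns:
        p = pd.to_numeric(df["strand_bias_p"], errors="coerce").to_numpy(float)
        out = (p > level).astype(float)
        out[~np.isfinite(p)] = np.nan
        return out
    cols = ["sb_child_fwd", "sb_child_rev", "sb_parents_fwd", "sb_parents_rev"]
    if not all(c in df.columns for c in cols):
        return np.full(n, np.nan)
    out = np.empty(n)
    for i, row in enumerate(df[cols].to_numpy()):
        if np.any(pd.isna(row)):
            out[i] = np.nan
            continue
        _, p = stats.fisher_exact(
            [[row[0], row[1]], [row[2], row[3]]])
        out[i] = p > level
    return out


def _error_site_ok(df: pd.DataFrame, alpha: float) -> np.ndarray:
    """Child VAF must exceed the per-site error rate: one-sided binomial
    test of child alt reads out of child depth against the error rate."""
    n = len(df)
    need = ["altreads_child", "rd_child", "site_error_rate"]
    if not all(c in df.columns for c in need):
        return np.full(n, np.nan)
    out = np.empty(n)
    for i, (k, nn, e) in enumerate(df[need].to_numpy()):
        if pd.isna(k) or pd.isna(nn) or pd.isna(e) or k > nn:
            out[i] = np.nan  # inconsistent support is not evaluable
            continue
        p = stats.binomtest(int(k), int(nn), float(e),
                            alternative="greater").pvalue
        out[i] = p < alpha
    return out
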