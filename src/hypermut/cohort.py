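"""Synthetic trio-cohort generator.

Emulates a large whole-genome-sequenced rare-disease trio cohort at desk
scale: per-child de novo SNV counts follow a negative binomial with an
additive (identity-link) parental-age mean, each mutation is assigned a
parent of origin with an age-dependent paternal fraction (~0.77 overall),
a 96-channel substitution class drawn from an etiology-specific signature
mixture, a genomic position on a scaled genome, and read support sampled
binomially around the heterozygous expectation VAF = 0.5.

Hypermutator trios (paternal repair defects, chemotherapy-like exposures,
post-zygotic mosaicism) and the known false-positive mode — a parental
somatic deletion producing clustered pseudo-DNMs with regional parental
loss of heterozygosity ("loss of transmitted allele", LOTA) — can be
injected with full truth labels so every downstream stage is testable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNELS, parse_channel

__all__ = [
    "AgeDistribution",
    "SimulationConfig",
    "Cohort",
    "TrioRecord",
    "DnmCall",
    "InformativeSite",
    "default_genome",
    "simulate_counts",
    "simulate_cohort",
    "inject_hypermutators",
    "inject_lota_artifact",
    "simulate_phasing_reads",
    "cohort_phasing_reads",
    "parental_genotype_bins",
    "write_cohort",
    "read_cohort",
]

# Approximate GRCh38 autosome + X lengths scaled to ~1/100 (desk-scale genome).
_SCALED_LENGTHS = {
    "1": 2_489_000, "2": 2_422_000, "3": 1_983_000, "4": 1_902_000,
    "5": 1_815_000, "6": 1_708_000, "7": 1_593_000, "8": 1_451_000,
    "9": 1_384_000, "10": 1_338_000, "11": 1_351_000, "12": 1_333_000,
    "13": 1_144_000, "14": 1_070_000, "15": 1_020_000, "16": 903_000,
    "17": 832_000, "18": 803_000, "19": 586_000, "20": 644_000,
    "21": 467_000, "22": 508_000, "X": 1_560_000,
}


def default_genome() -> dict[str, int]:
    """Named chromosomes with lengths (~1/100 of the human genome)."""
    return dict(_SCALED_LENGTHS)


@dataclass
class AgeDistribution:
    """Parental ages at birth: maternal truncated normal, paternal offset.

    Defaults centre the cohort at paternal/maternal medians of 33/30 years.
    """

    mother_mean: float = 30.0
    mother_sd: float = 4.0
    father_offset: float = 3.0
    father_noise_sd: float = 2.5
    min_age: float = 16.0
    max_age: float = 55.0

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        ma = rng.normal(self.mother_mean, self.mother_sd, n)
        ma = np.clip(ma, self.min_age, self.max_age)
        fa = ma + self.father_offset + rng.normal(0.0, self.father_noise_sd, n)
        fa = np.clip(fa, self.min_age, self.max_age)
        return fa, ma


def _default_signature_mix() -> dict[str, dict[str, float]]:
    baseline = {"sig_cpg_deamination": 0.25, "sig_clocklike_flat": 0.75}
    return {
        "baseline": dict(baseline),
        "repair_defect": {"sig_repair_tc": 1.0},
        "chemo_signature": {"sig_platinum_like": 1.0},
        "postzygotic": dict(baseline),
        "lota_artifact": dict(baseline),
    }


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic trio cohort.

    The de novo SNV count of child *i* is NB-distributed with mean
    ``beta0 + beta_pat * paternal_age_i + beta_mat * maternal_age_i`` and
    variance ``mu + mu**2 / dispersion``.  Each SNV is paternal with
    probability ``paternal_fraction_base + paternal_fraction_slope *
    (paternal_age - paternal_reference_age)``.
    """

    n_trios: int = 1000
    beta0: float = 20.0
    beta_pat: float = 1.28
    beta_mat: float = 0.35
    dispersion: float = 240.0
    paternal_fraction_base: float = 0.77
    paternal_fraction_slope: float = 0.0017
    paternal_reference_age: float = 33.0
    age_distribution: AgeDistribution = field(default_factory=AgeDistribution)
    signature_mix: dict[str, dict[str, float]] = field(
        default_factory=_default_signature_mix
    )
    vaf_depth: float = 35.0
    # identity-link NB mean for de novo indel counts (desk-scale defaults
    # giving a median of ~5 indels per child)
    indel_beta0: float = 2.6
    indel_beta_pat: float = 0.071
    indel_beta_mat: float = 0.019
    genome: dict[str, int] = field(default_factory=default_genome)
    seed: int = 0

    def validate(self) -> None:
        if self.n_trios < 0:
            raise ValueError("n_trios must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for name in ("beta0", "beta_pat", "beta_mat",
                     "indel_beta0", "indel_beta_pat", "indel_beta_mat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        ad = self.age_distribution
        for fa in (ad.min_age, ad.max_age):
            for ma in (ad.min_age, ad.max_age):
                if self.beta0 + self.beta_pat * fa + self.beta_mat * ma <= 0:
                    raise ValueError(
                        "expected count is not positive over the age range"
                    )
            p = (self.paternal_fraction_base
                 + self.paternal_fraction_slope * (fa - self.paternal_reference_age))
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    "paternal fraction leaves [0, 1] over the age range"
                )
        for etiology, mix in self.signature_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"signature mix for {etiology!r} sums to {total}, not 1"
                )

    def mean_count(self, father_age: float, mother_age: float) -> float:
        return self.beta0 + self.beta_pat * father_age + self.beta_mat * mother_age

    def paternal_fraction(self, father_age) -> np.ndarray:
        p = (self.paternal_fraction_base
             + self.paternal_fraction_slope
             * (np.asarray(father_age, dtype=float) - self.paternal_reference_age))
        return np.clip(p, 0.0, 1.0)


@dataclass
class TrioRecord:
    """One family: identifiers, parental ages, per-member QC metrics."""

    trio_id: str
    child_id: str
    father_id: str
    mother_id: str
    child_sex: str
    father_age: float
    mother_age: float
    qc: dict[str, float] = field(default_factory=dict)


@dataclass
class DnmCall:
    """One candidate de novo mutation with read-level support."""

    trio_id: str
    child_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gt_child: str = "0/1"
    gt_father: str = "0/0"
    gt_mother: str = "0/0"
    rd_child: int = 0
    rd_father: int = 0
    rd_mother: int = 0
    altreads_child: int = 0
    altreads_father: int = 0
    altreads_mother: int = 0
    vaf_child: float = 0.0
    context96: str | None = None
    tx_strand: str = "NA"
    vartype: str = "SNV"
    phase: str = "unknown"


@dataclass
class InformativeSite:
    """A nearby heterozygous site whose alleles are attributable to parents."""

    chrom: str
    pos: int
    a1: str
    a2: str
    parent_of: dict[str, str]  # allele -> "father" | "mother"
    distance: int


@dataclass
class Cohort:
    """A simulated cohort: per-trio table, per-DNM table, and its config."""

    trios: pd.DataFrame
    dnms: pd.DataFrame | None
    config: SimulationConfig

    @property
    def n_trios(self) -> int:
        return len(self.trios)


# ---------------------------------------------------------------------------
# signature profiles used by the generator (synthetic, see catalogue module)

def _signature_profiles() -> pd.DataFrame:
    from .catalogue import synthetic_catalogue

    return synthetic_catalogue()


# ---------------------------------------------------------------------------
# counts-level simulation (fast path)

TRIO_COLUMNS = [
    "trio_id", "child_id", "father_id", "mother_id", "child_sex",
    "father_age", "mother_age", "mu_snv", "n_snv", "n_paternal",
    "n_maternal", "n_indel", "etiology",
]

QC_COLUMNS = [
    "child_mean_rd", "mother_mean_rd", "father_mean_rd",
    "child_prop_aligned", "mother_prop_aligned", "father_prop_aligned",
    "child_snvs", "mother_snvs", "father_snvs",
    "median_vaf", "median_bf",
]


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB draw with mean mu and variance mu + mu**2/theta (gamma-Poisson)."""
    if np.isinf(theta):
        return rng.poisson(mu)
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


def simulate_counts(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the per-trio table (ages, counts, phase truth, QC) only.

    This is the fast path used by detection power/false-positive-rate
    simulations which never need individual mutation records.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trios
    fa, ma = config.age_distribution.sample(n, rng)
    mu = config.beta0 + config.beta_pat * fa + config.beta_mat * ma
    counts = _nb_sample(rng, mu, config.dispersion)
    p_pat = config.paternal_fraction(fa)
    n_pat = rng.binomial(counts, p_pat)
    mu_indel = (config.indel_beta0 + config.indel_beta_pat * fa
                + config.indel_beta_mat * ma)
    n_indel = _nb_sample(rng, mu_indel, config.dispersion)
    ids = np.arange(n)
    trios = pd.DataFrame({
        "trio_id": [f"trio_{i:05d}" for i in ids],
        "child_id": [f"child_{i:05d}" for i in ids],
        "father_id": [f"father_{i:05d}" for i in ids],
        "mother_id": [f"mother_{i:05d}" for i in ids],
        "child_sex": rng.choice(["M", "F"], size=n),
        "father_age": fa,
        "mother_age": ma,
        "mu_snv": mu,
        "n_snv": counts,
        "n_paternal": n_pat,
        "n_maternal": counts - n_pat,
        "n_indel": n_indel,
        "etiology": "baseline",
    })
    # QC metrics independent of counts by default (no injected quality effect)
    depth = config.vaf_depth
    for member in ("child", "mother", "father"):
        trios[f"{member}_mean_rd"] = rng.normal(depth, 2.5, n)
    for member in ("child", "mother", "father"):
        trios[f"{member}_prop_aligned"] = np.clip(
            rng.normal(0.96, 0.01, n), 0.85, 1.0)
    for member in ("child", "mother", "father"):
        trios[f"{member}_snvs"] = rng.normal(42_000, 1_500, n).round()
    trios["median_vaf"] = np.clip(rng.normal(0.50, 0.012, n), 0.0, 1.0)
    trios["median_bf"] = rng.normal(40.0, 5.0, n)
    # artifact bookkeeping (filled by inject_lota_artifact)
    trios["artifact_chrom"] = ""
    trios["artifact_start"] = -1
    trios["artifact_end"] = -1
    trios["artifact_parent"] = ""
    return trios


# ---------------------------------------------------------------------------
# DNM-level simulation

DNM_COLUMNS = [
    "dnm_id", "trio_id", "child_id", "chrom", "pos", "ref", "alt",
    "gt_child", "gt_father", "gt_mother",
    "rd_child", "rd_father", "rd_mother",
    "altreads_father", "altreads_mother", "altreads_child",
    "vaf_child", "context96", "tx_strand", "vartype",
]

TRUTH_COLUMNS = ["dnm_id", "true_parent", "true_signature", "true_vaf",
                 "etiology"]


def _sample_channels(rng: np.random.Generator, mix: dict[str, float],
                     profiles: pd.DataFrame, n: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-mutation signature names and channel indices from a mix."""
    sig_names = list(mix)
    weights = np.array([mix[s] for s in sig_names])
    which = rng.choice(len(sig_names), size=n, p=weights)
    channels = np.empty(n, dtype=int)
    for j, sig in enumerate(sig_names):
        m = which == j
        k = int(m.sum())
        if k:
            channels[m] = rng.choice(96, size=k, p=profiles[sig].to_numpy())
    sigs = np.array(sig_names, dtype=object)[which]
    return sigs, channels


def _sample_positions(rng: np.random.Generator, genome: dict[str, int],
                      n: int, masks=None) -> tuple[np.ndarray, np.ndarray]:
    chroms = np.array(list(genome), dtype=object)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    ci = rng.choice(len(chroms), size=n, p=probs)
    pos = (rng.random(n) * lengths[ci]).astype(np.int64) + 1  # 1-based
    if masks is not None:
        for _ in range(20):
            masked = np.zeros(n, dtype=bool)
            for mask in np.atleast_1d(masks):
                masked |= mask.contains(chroms[ci], pos)
            if not masked.any():
                break
            k = int(masked.sum())
            ci[masked] = rng.choice(len(chroms), size=k, p=probs)
            pos[masked] = (rng.random(k) * lengths[ci[masked]]).astype(np.int64) + 1
    return chroms[ci], pos


def _truncated_poisson_depth(rng: np.random.Generator, depth: float,
                             n: int, floor: int = 20) -> np.ndarray:
    rd = rng.poisson(depth, n)
    for _ in range(20):
        low = rd <= floor
        if not low.any():
            break
        rd[low] = rng.poisson(depth, int(low.sum()))
    return np.maximum(rd, floor + 1)


def _read_support(rng: np.random.Generator, n: int, depth: float,
                  vaf: np.ndarray | float = 0.5
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Child read support: truncated-Poisson depth, binomial alt reads.

    The generator emulates post-calling DNM tables, so read support is
    drawn conditional on looking like a call a trio pipeline would emit:
    depth is Poisson(depth) conditioned on > 20 (callers do not emit
    marginal-depth de novo genotypes), and for true heterozygous calls
    (underlying VAF exactly 0.5) the observed allele balance is resampled
    into (0.3, 0.7), mirroring upstream caller allele-balance behaviour.
    Mosaic calls (true VAF below 0.5) are not conditioned.
    """
    rd = _truncated_poisson_depth(rng, depth, n)
    vaf = np.broadcast_to(np.asarray(vaf, dtype=float), (n,))
    alt = rng.binomial(rd, vaf)
    germline = vaf == 0.5
    for _ in range(20):
        ab = alt / rd
        bad = germline & ((ab <= 0.3) | (ab >= 0.7))
        if not bad.any():
            break
        alt[bad] = rng.binomial(rd[bad], 0.5)
    return rd, alt, alt / rd


def _make_dnm_rows(rng: np.random.Generator, config: SimulationConfig,
                   trio_rows: pd.DataFrame, counts: np.ndarray,
                   parents: np.ndarray, etiology: str,
                   profiles: pd.DataFrame, true_vaf: np.ndarray | float = 0.5,
                   masks=None, mix: dict[str, float] | None = None,
                   region: tuple[str, int, int] | None = None) -> pd.DataFrame:
    """Build a block of DNM records for the given per-trio counts.

    ``parents`` is the flat per-mutation truth label array ("father" /
    "mother"), ``true_vaf`` the per-mutation underlying allele fraction.
    """
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(columns=DNM_COLUMNS + TRUTH_COLUMNS[1:])
    rep = np.repeat(np.arange(len(trio_rows)), counts)
    if mix is None:
        mix = config.signature_mix[etiology]
    sigs, chan_idx = _sample_channels(rng, mix, profiles, total)
    labels = np.array(CHANNELS, dtype=object)[chan_idx]
    ref = np.array([parse_channel(c)[1] for c in labels], dtype=object)
    alt = np.array([parse_channel(c)[2] for c in labels], dtype=object)
    if region is None:
        chrom, pos = _sample_positions(rng, config.genome, total, masks)
    else:
        c, lo, hi = region
        chrom = np.full(total, c, dtype=object)
        pos = rng.integers(lo, hi + 1, size=total)
    rd_c, alt_c, vaf_c = _read_support(rng, total, config.vaf_depth, true_vaf)
    rd_f = _truncated_poisson_depth(rng, config.vaf_depth, total)
    rd_m = _truncated_poisson_depth(rng, config.vaf_depth, total)
    df = pd.DataFrame({
        "trio_id": trio_rows["trio_id"].to_numpy()[rep],
        "child_id": trio_rows["child_id"].to_numpy()[rep],
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "gt_child": "0/1",
        "gt_father": "0/0",
        "gt_mother": "0/0",
        "rd_child": rd_c,
        "rd_father": rd_f,
        "rd_mother": rd_m,
        "altreads_father": 0,
        "altreads_mother": 0,
        "altreads_child": alt_c,
        "vaf_child": vaf_c,
        "context96": labels,
        "tx_strand": rng.choice(["T", "U", "NA"], size=total, p=[0.2, 0.2, 0.6]),
        "vartype": "SNV",
        "true_parent": parents,
        "true_signature": sigs,
        "true_vaf": np.broadcast_to(np.asarray(true_vaf, dtype=float), (total,)),
        "etiology": etiology,
    })
    return df


def _indel_rows(rng: np.random.Generator, config: SimulationConfig,
                trio_rows: pd.DataFrame, counts: np.ndarray,
                masks=None) -> pd.DataFrame:
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(columns=DNM_COLUMNS + TRUTH_COLUMNS[1:])
    rep = np.repeat(np.arange(len(trio_rows)), counts)
    chrom, pos = _sample_positions(rng, config.genome, total, masks)
    rd_c, alt_c, vaf_c = _read_support(rng, total, config.vaf_depth)
    base = rng.choice(["A", "C", "G", "T"], size=total)
    ins = rng.random(total) < 0.5
    ref = np.where(ins, base, base + "A").astype(object)
    alt = np.where(ins, base + "T", base).astype(object)
    p_pat = config.paternal_fraction(
        trio_rows["father_age"].to_numpy()[rep])
    parents = np.where(rng.random(total) < p_pat, "father", "mother")
    df = pd.DataFrame({
        "trio_id": trio_rows["trio_id"].to_numpy()[rep],
        "child_id": trio_rows["child_id"].to_numpy()[rep],
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "gt_child": "0/1", "gt_father": "0/0", "gt_mother": "0/0",
        "rd_child": rd_c,
        "rd_father": _truncated_poisson_depth(rng, config.vaf_depth, total),
        "rd_mother": _truncated_poisson_depth(rng, config.vaf_depth, total),
        "altreads_father": 0, "altreads_mother": 0, "altreads_child": alt_c,
        "vaf_child": vaf_c, "context96": "NA", "tx_strand": "NA",
        "vartype": "indel",
        "true_parent": parents, "true_signature": "NA",
        "true_vaf": 0.5, "etiology": "baseline",
    })
    return df


def _finalize_dnms(dnms: pd.DataFrame) -> pd.DataFrame:
    dnms = dnms.reset_index(drop=True)
    dnms["dnm_id"] = [f"dnm_{i:07d}" for i in range(len(dnms))]
    return dnms[DNM_COLUMNS + TRUTH_COLUMNS[1:]]


def simulate_cohort(config: SimulationConfig, masks=None,
                    counts_only: bool = False) -> Cohort:
    """Simulate a full cohort; deterministic given ``config.seed``.

    With ``counts_only=True`` only the per-trio table is produced
    (``cohort.dnms`` is None).
    """
    rng = np.random.default_rng(config.seed)
    trios = simulate_counts(config, rng)
    if counts_only or config.n_trios == 0:
        dnms = None if counts_only else _finalize_dnms(
            pd.DataFrame(columns=DNM_COLUMNS + TRUTH_COLUMNS[1:]))
        return Cohort(trios=trios, dnms=dnms, config=config)
    profiles = _signature_profiles()
    n_pat = trios["n_paternal"].to_numpy()
    n_mat = trios["n_maternal"].to_numpy()
    # paternal and maternal blocks share trio ordering; interleaving is
    # irrelevant downstream
    pat = _make_dnm_rows(rng, config, trios, n_pat,
                         np.repeat("father", n_pat.sum()).astype(object),
                         "baseline", profiles, masks=masks)
    mat = _make_dnm_rows(rng, config, trios, n_mat,
                         np.repeat("mother", n_mat.sum()).astype(object),
                         "baseline", profiles, masks=masks)
    ind = _indel_rows(rng, config, trios, trios["n_indel"].to_numpy(), masks)
    dnms = _finalize_dnms(pd.concat([pat, mat, ind], ignore_index=True))
    cohort = Cohort(trios=trios, dnms=dnms, config=config)
    _refresh_trio_counts(cohort)
    return cohort


def _refresh_trio_counts(cohort: Cohort) -> None:
    """Recompute per-trio counts and median VAF from the DNM table."""
    if cohort.dnms is None:
        return
    d = cohort.dnms
    snv = d[d["vartype"] == "SNV"]
    by = snv.groupby("trio_id")
    n = by.size()
    npat = snv[snv["true_parent"] == "father"].groupby("trio_id").size()
    nind = d[d["vartype"] == "indel"].groupby("trio_id").size()
    mvaf = by["vaf_child"].median()
    t = cohort.trios.set_index("trio_id")
    t["n_snv"] = n.reindex(t.index).fillna(0).astype(int)
    t["n_paternal"] = npat.reindex(t.index).fillna(0).astype(int)
    t["n_maternal"] = t["n_snv"] - t["n_paternal"]
    t["n_indel"] = nind.reindex(t.index).fillna(0).astype(int)
    t["median_vaf"] = mvaf.reindex(t.index).fillna(0.5)
    cohort.trios = t.reset_index()


# ---------------------------------------------------------------------------
# hypermutator and artifact injection

_ETIOLOGIES = {"repair_defect", "chemo_signature", "postzygotic"}


def inject_hypermutators(cohort: Cohort,
                         specs: list[tuple[str, str, float, str]],
                         seed: int | None = None) -> Cohort:
    """Inject hypermutator trios; returns the same cohort, modified.

    Each spec is ``(trio_id, etiology, fold_or_extra, signature_id)``:

    - ``repair_defect``: multiply the trio's paternal SNV count by ``fold``;
      the extra mutations carry the named signature and paternal truth.
    - ``chemo_signature``: add ``extra`` paternal SNVs from the named
      signature (pre-conception mutagen exposure of the father).
    - ``postzygotic``: add ``extra`` SNVs with ~50/50 parental truth and
      sub-0.5 allele fractions (early embryonic / clonal haematopoiesis).
    """
    if cohort.dnms is None:
        raise ValueError("inject_hypermutators needs a DNM-level cohort")
    rng = np.random.default_rng(cohort.config.seed + 1 if seed is None else seed)
    profiles = _signature_profiles()
    known = set(profiles.columns)
    blocks = [cohort.dnms]
    trios = cohort.trios.set_index("trio_id", drop=False)
    for trio_id, etiology, amount, sig in specs:
        if etiology not in _ETIOLOGIES:
            raise ValueError(f"unknown etiology {etiology!r}")
        if sig not in known:
            raise ValueError(f"unknown signature id {sig!r}")
        row = trios.loc[[trio_id]]
        if etiology == "repair_defect":
            if amount < 1:
                raise ValueError("fold must be >= 1")
            base_pat = int(row["n_paternal"].iloc[0])
            extra = int(round((amount - 1) * base_pat))
            if extra == 0:
                continue
            parents = np.repeat("father", extra).astype(object)
            vaf = 0.5
        elif etiology == "chemo_signature":
            extra = int(round(amount))
            if extra == 0:
                continue
            parents = np.repeat("father", extra).astype(object)
            vaf = 0.5
        else:  # postzygotic
            extra = int(round(amount))
            if extra == 0:
                continue
            parents = np.where(rng.random(extra) < 0.5, "father",
                               "mother").astype(object)
            # early post-zygotic / clonal fractions: below the heterozygous
            # 0.5 but mostly inside the caller's allele-balance window
            vaf = rng.uniform(0.30, 0.45, extra)
        block = _make_dnm_rows(rng, cohort.config, row,
                               np.array([extra]), parents, etiology,
                               profiles, true_vaf=vaf, mix={sig: 1.0})
        blocks.append(block)
        trios.loc[trio_id, "etiology"] = etiology
    cohort.trios = trios.reset_index(drop=True)
    cohort.dnms = _finalize_dnms(pd.concat(blocks, ignore_index=True))
    _refresh_trio_counts(cohort)
    return cohort


def inject_lota_artifact(cohort: Cohort, trio_id: str,
                         region: tuple[str, int, int], n_calls: int,
                         parent: str = "father",
                         seed: int | None = None) -> Cohort:
    """Inject a loss-of-transmitted-allele artifact into one trio.

    Adds ``n_calls`` pseudo-DNMs confined to ``region`` (a parental somatic
    deletion in blood mimicking clustered de novo calls) and records the
    region so the parental genotype-bin generator depresses the parent's
    regional heterozygous/homozygous ratio.
    """
    if cohort.dnms is None:
        raise ValueError("inject_lota_artifact needs a DNM-level cohort")
    chrom, lo, hi = region
    if chrom not in cohort.config.genome:
        raise ValueError(f"region chromosome {chrom!r} not in simulated genome")
    hi = min(hi, cohort.config.genome[chrom])
    if n_calls == 0:
        return cohort
    rng = np.random.default_rng(
        cohort.config.seed + 2 if seed is None else seed)
    profiles = _signature_profiles()
    trios = cohort.trios.set_index("trio_id", drop=False)
    row = trios.loc[[trio_id]]
    parents = np.repeat(parent, n_calls).astype(object)
    # low-level parental mosaicism shows as mildly depressed VAF in the child
    vaf = rng.uniform(0.3, 0.5, n_calls)
    block = _make_dnm_rows(rng, cohort.config, row, np.array([n_calls]),
                           parents, "lota_artifact", profiles, true_vaf=vaf,
                           region=(chrom, lo, hi))
    trios.loc[trio_id, ["etiology", "artifact_chrom", "artifact_start",
                        "artifact_end", "artifact_parent"]] = (
        "lota_artifact", chrom, lo, hi, parent)
    cohort.trios = trios.reset_index(drop=True)
    cohort.dnms = _finalize_dnms(
        pd.concat([cohort.dnms, block], ignore_index=True))
    _refresh_trio_counts(cohort)
    return cohort


# ---------------------------------------------------------------------------
# read-level phasing evidence

READ_COLUMNS = ["read_id", "trio_id", "dnm_id", "locus_a", "allele_a",
                "locus_b", "allele_b"]

_FRAGMENT_SPAN = 600  # read-pair span model: loci farther apart never co-covered


def simulate_phasing_reads(dnm, site: InformativeSite, n_reads: int,
                           error_rate: float = 0.0,
                           seed: int | None = None,
                           rng: np.random.Generator | None = None,
                           true_parent: str = "father") -> pd.DataFrame:
    """Simulate read-pair observations covering a DNM and a nearby site.

    Reads sample the child's two haplotypes equally; the haplotype carrying
    the DNM alt allele also carries the informative-site allele inherited
    from ``true_parent``.  Alleles are flipped independently with
    ``error_rate``.  Offsets beyond the fragment span yield no co-covering
    reads (valid, unphaseable evidence).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cols = READ_COLUMNS
    if abs(site.distance) > _FRAGMENT_SPAN or n_reads == 0:
        return pd.DataFrame(columns=cols)
    ref, alt = dnm["ref"], dnm["alt"]
    same_allele = next(a for a, p in site.parent_of.items() if p == true_parent)
    other_allele = site.a2 if same_allele == site.a1 else site.a1
    hap = rng.random(n_reads) < 0.5  # True: haplotype carrying the DNM
    a = np.where(hap, alt, ref).astype(object)
    b = np.where(hap, same_allele, other_allele).astype(object)
    flip_a = rng.random(n_reads) < error_rate
    flip_b = rng.random(n_reads) < error_rate
    a[flip_a] = np.where(a[flip_a] == alt, ref, alt)
    b[flip_b] = np.where(b[flip_b] == same_allele, other_allele, same_allele)
    return pd.DataFrame({
        "read_id": [f"read_{i:05d}" for i in range(n_reads)],
        "trio_id": dnm["trio_id"],
        "dnm_id": dnm.get("dnm_id", "dnm"),
        "locus_a": f"{dnm['chrom']}:{dnm['pos']}",
        "allele_a": a,
        "locus_b": f"{site.chrom}:{site.pos}",
        "allele_b": b,
    })


def cohort_phasing_reads(cohort: Cohort, p_informative: float = 0.6,
                         mean_reads: float = 8.0, error_rate: float = 0.0,
                         seed: int | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate informative sites and read evidence for a whole cohort.

    Each SNV DNM independently has an informative heterozygous site within
    500 bp with probability ``p_informative``; read-pair counts are Poisson.
    Returns ``(sites, reads)`` tables.  Vectorized; deterministic per seed.
    """
    if cohort.dnms is None:
        raise ValueError("cohort has no DNM records")
    rng = np.random.default_rng(
        cohort.config.seed + 3 if seed is None else seed)
    snv = cohort.dnms[cohort.dnms["vartype"] == "SNV"].reset_index(drop=True)
    n = len(snv)
    has = rng.random(n) < p_informative
    idx = np.flatnonzero(has)
    m = len(idx)
    offset = rng.integers(1, 501, m) * rng.choice([-1, 1], m)
    site_pos = np.maximum(snv["pos"].to_numpy()[idx] + offset, 1)
    pat_allele = rng.choice(["A", "G"], m)
    mat_allele = np.where(pat_allele == "A", "G", "A").astype(object)
    n_reads = rng.poisson(mean_reads, m)
    sites = pd.DataFrame({
        "dnm_id": snv["dnm_id"].to_numpy()[idx],
        "trio_id": snv["trio_id"].to_numpy()[idx],
        "chrom": snv["chrom"].to_numpy()[idx],
        "pos": site_pos,
        "a1": pat_allele,
        "a2": mat_allele,
        "parent_of_a1": "father",
        "parent_of_a2": "mother",
        "distance": np.abs(offset),
    })
    # expand to reads
    rep = np.repeat(np.arange(m), n_reads)
    total = len(rep)
    truth = snv["true_parent"].to_numpy()[idx][rep]
    ref = snv["ref"].to_numpy()[idx][rep]
    alt = snv["alt"].to_numpy()[idx][rep]
    same = np.where(truth == "father", pat_allele[rep], mat_allele[rep])
    other = np.where(truth == "father", mat_allele[rep], pat_allele[rep])
    hap = rng.random(total) < 0.5
    a = np.where(hap, alt, ref).astype(object)
    b = np.where(hap, same, other).astype(object)
    if error_rate > 0:
        flip_a = rng.random(total) < error_rate
        flip_b = rng.random(total) < error_rate
        a[flip_a] = np.where(a[flip_a] == alt[flip_a], ref[flip_a], alt[flip_a])
        b[flip_b] = np.where(b[flip_b] == same[flip_b], other[flip_b],
                             same[flip_b])
    dnm_pos = snv["pos"].to_numpy()[idx][rep]
    chroms = snv["chrom"].to_numpy()[idx][rep]
    reads = pd.DataFrame({
        "read_id": [f"read_{i:07d}" for i in range(total)],
        "trio_id": snv["trio_id"].to_numpy()[idx][rep],
        "dnm_id": snv["dnm_id"].to_numpy()[idx][rep],
        "locus_a": [f"{c}:{p}" for c, p in zip(chroms, dnm_pos)],
        "allele_a": a,
        "locus_b": [f"{c}:{p}" for c, p in zip(chroms, site_pos[rep])],
        "allele_b": b,
    })
    return sites, reads


# ---------------------------------------------------------------------------
# parental genotype bins for the artifact screen

def parental_genotype_bins(cohort: Cohort, child_ids,
                           bin_size: int = 100_000,
                           het_rate_per_kb: float = 0.8,
                           hom_rate_per_kb: float = 0.5,
                           loh_het_fraction: float = 0.15,
                           seed: int | None = None) -> pd.DataFrame:
    """Per-parent heterozygous/homozygous variant counts in genomic bins.

    Generated deterministically per trio on demand (screening is only run
    on flagged candidates).  For a trio carrying an injected
    loss-of-transmitted-allele artifact, the implicated parent's
    heterozygous counts inside the recorded region are depressed to
    ``loh_het_fraction`` of their expectation.
    """
    base_seed = cohort.config.seed + 4 if seed is None else seed
    trios = cohort.trios.set_index("child_id", drop=False)
    rows = []
    genome = cohort.config.genome
    for child_id in child_ids:
        t = trios.loc[child_id]
        srng = np.random.default_rng([base_seed, hash(child_id) % (2**31)])
        for chrom, length in genome.items():
            edges = np.arange(0, length + bin_size, bin_size)
            starts = edges[:-1]
            ends = np.minimum(edges[1:], length)
            widths_kb = (ends - starts) / 1000.0
            for parent in ("father", "mother"):
                het = srng.poisson(het_rate_per_kb * widths_kb)
                hom = srng.poisson(hom_rate_per_kb * widths_kb)
                if (t["etiology"] == "lota_artifact"
                        and t["artifact_parent"] == parent
                        and t["artifact_chrom"] == chrom):
                    in_region = (starts < t["artifact_end"]) & (
                        ends > t["artifact_start"])
                    het[in_region] = srng.poisson(
                        loh_het_fraction * het_rate_per_kb
                        * widths_kb[in_region])
                rows.append(pd.DataFrame({
                    "child_id": child_id, "parent": parent, "chrom": chrom,
                    "bin_start": starts, "bin_end": ends,
                    "n_het": het, "n_hom": hom,
                }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort I/O (plain TSV + JSON; lossless round trip)

def write_cohort(cohort: Cohort, directory) -> None:
    """Write DNM, pedigree, QC/truth tables and the config to a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    trios = cohort.trios
    ped_cols = ["trio_id", "child_id", "father_id", "mother_id", "child_sex",
                "father_age", "mother_age"] + QC_COLUMNS
    ped = trios[ped_cols].rename(columns={
        "father_age": "father_age_years", "mother_age": "mother_age_years"})
    ped.to_csv(d / "pedigree.tsv", sep="\t", index=False)
    truth_cols = [c for c in trios.columns if c not in ped_cols]
    trios[["trio_id"] + truth_cols].to_csv(
        d / "trio_truth.tsv", sep="\t", index=False)
    if cohort.dnms is not None:
        cohort.dnms[DNM_COLUMNS].to_csv(d / "dnms.tsv", sep="\t", index=False)
        cohort.dnms[TRUTH_COLUMNS].to_csv(
            d / "dnm_truth.tsv", sep="\t", index=False)
    cfg = dataclasses.asdict(cohort.config)
    (d / "config.json").write_text(json.dumps(cfg, indent=1))


def read_cohort(directory) -> Cohort:
    d = Path(directory)
    cfg_dict = json.loads((d / "config.json").read_text())
    cfg_dict["age_distribution"] = AgeDistribution(
        **cfg_dict["age_distribution"])
    config = SimulationConfig(**cfg_dict)
    ped = pd.read_csv(d / "pedigree.tsv", sep="\t").rename(columns={
        "father_age_years": "father_age", "mother_age_years": "mother_age"})
    truth = pd.read_csv(
        d / "trio_truth.tsv", sep="\t", keep_default_na=False,
        dtype={"artifact_chrom": str, "artifact_parent": str})
    trios = ped.merge(truth, on="trio_id")
    canonical = [c for c in TRIO_COLUMNS if c in trios.columns]
    rest = [c for c in trios.columns if c not in canonical]
    trios = trios[canonical + rest]
    dnms = None
    if (d / "dnms.tsv").exists():
        dnms = pd.read_csv(d / "dnms.tsv", sep="\t", dtype={"chrom": str},
                           keep_default_na=False)
        dtruth = pd.read_csv(d / "dnm_truth.tsv", sep="\t",
                             keep_default_na=False)
        dnms = dnms.merge(dtruth, on="dnm_id")
    # empty tables lose column dtypes; that is fine for round-trip equality
    return Cohort(trios=trios, dnms=dnms, config=config)
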