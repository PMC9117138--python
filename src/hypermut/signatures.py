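"""Mutational spectra and signature analysis on the 96-channel convention.

Spectra are vectors of SNV counts over the 96 pyrimidine-strand
trinucleotide channels (see :mod:`hypermut.channels`).  Known-signature
attribution is nonnegative least-squares refitting against a reference
catalogue with sparsity pruning; de-novo extraction is small-scale NMF
with multiplicative updates and seeded restarts, reporting a matched-cosine
stability score and reconstruction error per factorization rank so the
caller can choose the rank.  Signatures are compared by cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.optimize import linear_sum_assignment

from .channels import CHANNELS, CLASSES, channel_of
from .stats import binom_two_sided_p

__all__ = [
    "build_spectrum",
    "collapse_to_classes",
    "ExposureFit",
    "fit_exposures_nnls",
    "nmf_multiplicative",
    "NmfSolution",
    "SignatureSet",
    "extract_signatures_nmf",
    "cosine_similarity",
    "match_signatures",
    "compare_phased_spectra",
    "sample_spectrum",
]


def build_spectrum(calls: pd.DataFrame) -> tuple[pd.Series, int]:
    """96-channel spectrum of a set of SNV calls.

    Uses the ``context96`` channel label when present and already folded;
    otherwise folds (context, ref, alt) onto the pyrimidine strand.
    Returns (spectrum indexed by the canonical channels, number of calls
    excluded for ambiguous context).  Counts are conserved:
    ``spectrum.sum() + excluded == len(calls)``.
    """
    counts = pd.Series(0, index=pd.Index(CHANNELS, name="channel"),
                       dtype=int)
    excluded = 0
    if len(calls) == 0:
        return counts, 0
    labels = []
    for _, row in calls.iterrows():
        label = row.get("context96")
        if isinstance(label, str) and label in counts.index:
            labels.append(label)
            continue
        ctx = row.get("context")
        folded = channel_of(ctx, row["ref"], row["alt"]) \
            if isinstance(ctx, str) else None
        if folded is None:
            excluded += 1
        else:
            labels.append(folded)
    vc = pd.Series(labels).value_counts()
    counts.loc[vc.index] = vc.astype(int)
    return counts, excluded


def collapse_to_classes(spectrum: pd.Series) -> pd.Series:
    """Collapse a 96-channel spectrum to the six substitution classes."""
    cls = spectrum.index.str.extract(r"\[([ACGT]>[ACGT])\]")[0].to_numpy()
    return spectrum.groupby(cls).sum().reindex(list(CLASSES)).fillna(0)


def sample_spectrum(signature: np.ndarray | pd.Series, n: int,
                    rng: np.random.Generator) -> pd.Series:
    """Multinomial sample of ``n`` mutations from a signature profile."""
    p = np.asarray(signature, dtype=float)
    draw = rng.multinomial(n, p / p.sum())
    return pd.Series(draw, index=pd.Index(CHANNELS, name="channel"))


# ---------------------------------------------------------------------------
# NNLS refitting against a reference catalogue

@dataclass
class ExposureFit:
    exposures: pd.Series  # counts attributed per signature
    proportions: pd.Series
    residual_norm: float
    relative_residual: float
    pruned: list[str] = field(default_factory=list)


def fit_exposures_nnls(spectrum: pd.Series, catalogue: pd.DataFrame,
                       prune_threshold: float = 0.0) -> ExposureFit:
    """Nonnegative least-squares exposures of a spectrum on a catalogue.

    ``catalogue`` columns are unit-sum signature profiles.  Signatures
    whose fitted proportion falls below ``prune_threshold`` are removed
    and the remainder refit (iterated until stable).  The residual norm is
    always reported — an ill-matching catalogue never fails silently.
    """
    y = spectrum.reindex(catalogue.index).fillna(0).to_numpy(dtype=float)
    total = y.sum()
    if total == 0:
        raise ValueError("empty spectrum")
    sums = catalogue.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("catalogue columns must be unit-sum")
    active = list(catalogue.columns)
    pruned: list[str] = []
    while True:
        A = catalogue[active].to_numpy(dtype=float)
        x, rnorm = optimize.nnls(A, y)
        props = x / total
        drop = [s for s, p in zip(active, props)
                if p < prune_threshold and p > 0]
        weak = [s for s, xx in zip(active, x) if xx == 0.0]
        drop = sorted(set(drop) | (set(weak) if prune_threshold > 0 else set()))
        if not drop or len(active) - len(drop) == 0:
            break
        pruned += drop
        active = [s for s in active if s not in drop]
    exposures = pd.Series(0.0, index=catalogue.columns)
    exposures[active] = x
    return ExposureFit(
        exposures=exposures,
        proportions=exposures / total,
        residual_norm=float(rnorm),
        relative_residual=float(rnorm / np.linalg.norm(y)),
        pruned=pruned)


# ---------------------------------------------------------------------------
# de-novo extraction: NMF with multiplicative updates

def nmf_multiplicative(V: np.ndarray, k: int, rng: np.random.Generator,
                       max_iter: int = 2000, tol: float = 1e-9
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Frobenius NMF V ~ W H by multiplicative updates.

    V is (samples x channels), W (samples x k), H (k x channels).  The
    objective is checked to be non-increasing on every update (a small
    numerical slack); violation raises, as it indicates a broken update.
    Returns (W, H, final objective).
    """
    V = np.asarray(V, dtype=float)
    if k > V.shape[0]:
        raise ValueError("k larger than the number of samples")
    eps = 1e-12
    scale = np.sqrt(V.mean() / k)
    W = rng.random((V.shape[0], k)) * scale + eps
    H = rng.random((k, V.shape[1])) * scale + eps
    prev = np.linalg.norm(V - W @ H) ** 2
    for _ in range(max_iter):
        H *= (W.T @ V) / np.maximum(W.T @ W @ H, eps)
        W *= (V @ H.T) / np.maximum(W @ H @ H.T, eps)
        obj = np.linalg.norm(V - W @ H) ** 2
        if obj > prev * (1 + 1e-9) + 1e-12:
            raise RuntimeError("NMF objective increased: broken update")
        if prev - obj <= tol * max(prev, 1.0):
            prev = obj
            break
        prev = obj
    # normalize signature rows to unit sum, push scale into W
    row_sums = H.sum(axis=1, keepdims=True)
    H = H / np.maximum(row_sums, eps)
    W = W * row_sums.T
    return W, H, float(prev)


@dataclass
class NmfSolution:
    k: int
    signatures: pd.DataFrame  # k x 96, unit-sum rows
    exposures: np.ndarray  # samples x k
    objective: float
    stability: float  # mean matched cosine of restarts vs the best run
    relative_error: float


@dataclass
class SignatureSet:
    """De-novo extraction report across factorization ranks."""

    solutions: dict[int, NmfSolution]

    def best(self, k: int) -> NmfSolution:
        return self.solutions[k]

    def stability_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"k": s.k, "stability": s.stability,
              "relative_error": s.relative_error}
             for s in self.solutions.values()]).set_index("k")


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two nonnegative channel vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector")
    return float(np.dot(a, b) / (na * nb))


def match_signatures(A: np.ndarray, B: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal (Hungarian) pairing of two signature sets by cosine.

    Returns (column indices of B matched to rows of A, matched cosines).
    """
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    C = np.zeros((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            C[i, j] = cosine_similarity(A[i], B[j])
    ri, cj = linear_sum_assignment(-C)
    return cj, C[ri, cj]


def extract_signatures_nmf(spectra: pd.DataFrame, k_values,
                           restarts: int = 20, seed: int = 0,
                           max_iter: int = 2000) -> SignatureSet:
    """Scan factorization ranks with seeded multiplicative-update restarts.

    ``spectra`` is samples x 96 counts.  Per rank: keep the restart with
    the lowest objective; stability is the mean Hungarian-matched cosine
    of every restart's signatures against the best run's (1.0 = all
    restarts find the same factorization).  Rank choice is left to the
    caller via the stability report.
    """
    V = spectra.to_numpy(dtype=float)
    vnorm = np.linalg.norm(V)
    solutions = {}
    for k in k_values:
        rng = np.random.default_rng([seed, k])
        runs = [nmf_multiplicative(V, k, rng, max_iter=max_iter)
                for _ in range(restarts)]
        best = min(range(len(runs)), key=lambda i: runs[i][2])
        W, H, obj = runs[best]
        sims = []
        for i, (_, Hi, _) in enumerate(runs):
            if i == best:
                continue
            _, cos = match_signatures(H, Hi)
            sims.append(cos.mean())
        solutions[k] = NmfSolution(
            k=k,
            signatures=pd.DataFrame(
                H, columns=spectra.columns,
                index=[f"denovo_{k}_{i}" for i in range(k)]),
            exposures=W,
            objective=obj,
            stability=float(np.mean(sims)) if sims else 1.0,
            relative_error=float(np.sqrt(obj) / vnorm) if vnorm else 0.0)
    return SignatureSet(solutions=solutions)


# ---------------------------------------------------------------------------
# phased-spectra comparison

def compare_phased_spectra(paternal: pd.Series, maternal: pd.Series,
                           ) -> pd.DataFrame:
    """Per-class proportions of paternal vs maternal spectra with
    two-sided binomial tests.

    For each of the six substitution classes, the count in one parent's
    set is tested against the proportion observed in the other parent's
    set; because the choice of null side is arbitrary, both directions
    are computed and the reported p is their symmetric average (each is
    also returned).
    """
    p6 = collapse_to_classes(paternal)
    m6 = collapse_to_classes(maternal)
    np_tot, nm_tot = int(p6.sum()), int(m6.sum())
    if np_tot == 0 or nm_tot == 0:
        raise ValueError("both spectra must be non-empty")
    rows = []
    for cls in CLASSES:
        kp, km = int(p6[cls]), int(m6[cls])
        prop_p, prop_m = kp / np_tot, km / nm_tot
        if kp == 0 and km == 0:
            p_pm = p_mp = 1.0
        else:
            p_pm = binom_two_sided_p(kp, np_tot, prop_m) if prop_m > 0 else \
                (1.0 if kp == 0 else 0.0)
            p_mp = binom_two_sided_p(km, nm_tot, prop_p) if prop_p > 0 else \
                (1.0 if km == 0 else 0.0)
        rows.append({
            "class": cls, "paternal_prop": prop_p, "maternal_prop": prop_m,
            "p_paternal_vs_maternal": p_pm, "p_maternal_vs_paternal": p_mp,
            "p": (p_pm + p_mp) / 2.0})
    return pd.DataFrame(rows).set_index("class")
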