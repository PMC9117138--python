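"""Synthetic reference signature catalogue.

A deterministic, unit-sum set of 96-channel signature profiles with shapes
loosely modelled on well-known germline and exposure processes (CpG
deamination, flat clock-like, platinum-adduct-like, alkylating-like,
mismatch-repair-like).  These are synthetic stand-ins constructed for
testing and simulation — they are NOT the published COSMIC vectors, which
users should supply as a TSV (96 rows x one column per signature) for real
analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .channels import CHANNELS, parse_channel

__all__ = ["synthetic_catalogue", "read_catalogue", "write_catalogue"]


def _profile(weights: dict[str, float], sharpness: float,
             rng: np.random.Generator) -> np.ndarray:
    """Dirichlet-perturbed profile concentrated on the given class weights."""
    base = np.zeros(96)
    for i, ch in enumerate(CHANNELS):
        five, ref, alt, three = parse_channel(ch)
        base[i] = weights.get(f"{ref}>{alt}", 0.0) / 16.0
    jitter = rng.dirichlet(np.full(96, sharpness))
    p = 0.85 * base + 0.15 * jitter
    return p / p.sum()


def synthetic_catalogue(seed: int = 20_220_511) -> pd.DataFrame:
    """Build the synthetic catalogue (96 x k DataFrame, unit-sum columns).

    Deterministic: the default seed is fixed so that simulator truth labels
    and downstream refits always refer to the same vectors.
    """
    rng = np.random.default_rng(seed)
    sigs = {}
    # CpG-deamination-like: spiky C>T at NpCpG contexts
    p = np.zeros(96)
    for i, ch in enumerate(CHANNELS):
        five, ref, alt, three = parse_channel(ch)
        if ref == "C" and alt == "T":
            p[i] = 6.0 if three == "G" else 0.3
    p += 0.02
    sigs["sig_cpg_deamination"] = p / p.sum()
    # clock-like: broad, relatively flat across all classes
    sigs["sig_clocklike_flat"] = _profile(
        {"C>A": 0.12, "C>G": 0.10, "C>T": 0.22, "T>A": 0.12, "T>C": 0.30,
         "T>G": 0.14}, sharpness=8.0, rng=rng)
    # platinum-like: C>A / C>T heavy with strong context skew
    sigs["sig_platinum_like"] = _profile(
        {"C>A": 0.20, "C>T": 0.55, "T>A": 0.15, "C>G": 0.05, "T>C": 0.04,
         "T>G": 0.01}, sharpness=0.6, rng=rng)
    # alkylating-like (novel hypermutation shape): C>G and T>G enriched
    sigs["sig_alkylating_like"] = _profile(
        {"C>G": 0.40, "T>G": 0.35, "C>A": 0.10, "C>T": 0.10, "T>A": 0.03,
         "T>C": 0.02}, sharpness=0.6, rng=rng)
    # mismatch-repair-defect-like: overwhelming T>C
    sigs["sig_repair_tc"] = _profile(
        {"T>C": 0.90, "C>T": 0.05, "T>A": 0.05}, sharpness=0.6, rng=rng)
    # NER-defect-like: C>A and T>A with transcriptional asymmetry upstream
    sigs["sig_repair_ca"] = _profile(
        {"C>A": 0.55, "T>A": 0.25, "C>T": 0.10, "C>G": 0.05, "T>C": 0.05},
        sharpness=0.6, rng=rng)
    df = pd.DataFrame(sigs, index=pd.Index(CHANNELS, name="channel"))
    return df


def read_catalogue(path) -> pd.DataFrame:
    """Read a catalogue TSV (channel column + one unit-sum column per
    signature), reindexed to canonical channel order."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df = df.reindex(CHANNELS)
    if df.isna().any().any():
        raise ValueError("catalogue is missing channels or uses "
                         "non-canonical labels")
    sums = df.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("catalogue columns must each sum to 1")
    df.index.name = "channel"
    return df


def write_catalogue(catalogue: pd.DataFrame, path) -> None:
    catalogue.to_csv(path, sep="\t")
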