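"""Allele frequencies, diversity indices, and pairwise genetic distances.

For a biallelic locus i with alternate-allele frequency p, the indices are
    he_i = 1 - p^2 - (1-p)^2 = 2p(1-p)        expected heterozygosity
    ho_i = (# heterozygotes) / (# called)     observed heterozygosity
    f_i  = 1 - ho_i / he_i                    inbreeding coefficient
    sh_i = -p log2 p - (1-p) log2 (1-p)       Shannon index (0 log 0 := 0)
he peaks at 0.5 and sh at 1.0 when p = 0.5; 2*he rescales diversity to [0,1].

The modified Rogers distance between individuals x and y over L loci is the
Euclidean distance between their per-locus allele-frequency vectors
(dosage/2, 1-dosage/2) scaled by 1/sqrt(2L), bounded on [0,1]. Under missing
data it is computed over the pairwise-complete loci with per-pair rescaling
(1/sqrt(2 L_xy)); pairs with fewer than ``min_overlap`` complete loci are
flagged missing. The Jaccard similarity for presence/absence markers is
n_pp / (n_pp + n_ap + n_pa): (absent, absent) agreements count neither in
the numerator nor the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DistanceMatrix, GenotypeMatrix, PresenceMatrix


@dataclass
class AlleleFreqTable:
    """Per-locus reference/alternate frequencies and call counts."""

    markers: list[str]
    p_alt: np.ndarray
    n_called: np.ndarray

    @property
    def p_ref(self) -> np.ndarray:
        return 1.0 - self.p_alt

    def defined(self) -> np.ndarray:
        """Loci with at least one non-missing call."""
        return self.n_called > 0


def allele_frequencies(geno: GenotypeMatrix) -> AlleleFreqTable:
    """p_alt = (sum of dosages) / (2 * called samples), per locus.

    All-missing loci are flagged (n_called = 0, p_alt = NaN) and excluded
    from downstream averages.
    """
    called = (~geno.missing_mask()).sum(axis=0)
    total = np.nansum(geno.dosage, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, total / (2.0 * np.maximum(called, 1)), np.nan)
    return AlleleFreqTable(list(geno.markers), p, called)


def expected_heterozygosity(freqs: AlleleFreqTable | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-locus he = 1 - p^2 - (1-p)^2 and its average over defined loci."""
    p = freqs.p_alt if isinstance(freqs, AlleleFreqTable) else np.asarray(freqs, dtype=float)
    he = 1.0 - p**2 - (1.0 - p) ** 2
    avg = float(np.nanmean(he)) if np.isfinite(he).any() else np.nan
    return he, avg


def observed_heterozygosity(geno: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """Per-locus proportion of heterozygotes among called samples."""
    called = (~geno.missing_mask()).sum(axis=0)
    hets = np.nansum(geno.dosage == 1.0, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(called > 0, hets / np.maximum(called, 1), np.nan)
    avg = float(np.nanmean(ho)) if np.isfinite(ho).any() else np.nan
    return ho, avg


def inbreeding_coefficient(ho: np.ndarray, he: np.ndarray) -> tuple[np.ndarray, float]:
    """f = 1 - ho/he per locus; loci with he = 0 are undefined (NaN) and
    excluded from the average."""
    ho = np.asarray(ho, dtype=float)
    he = np.asarray(he, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(he > 0, 1.0 - ho / np.where(he > 0, he, 1.0), np.nan)
    avg = float(np.nanmean(f)) if np.isfinite(f).any() else np.nan
    return f, avg


def shannon_index(freqs: AlleleFreqTable | np.ndarray) -> tuple[np.ndarray, float]:
    """Base-2 Shannon index over the two allele frequencies; 0 log 0 := 0."""
    p = freqs.p_alt if isinstance(freqs, AlleleFreqTable) else np.asarray(freqs, dtype=float)
    sh = np.zeros_like(p)
    for q in (p, 1.0 - p):
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(q > 0, q * np.log2(np.where(q > 0, q, 1.0)), 0.0)
        sh = sh - term
    sh = np.where(np.isnan(p), np.nan, sh)
    avg = float(np.nanmean(sh)) if np.isfinite(sh).any() else np.nan
    return sh, avg


def diversity_summary(geno: GenotypeMatrix) -> pd.DataFrame:
    """Population-average he, 2he, ho, f, sh with the locus counts they
    were averaged over."""
    freqs = allele_frequencies(geno)
    he, he_avg = expected_heterozygosity(freqs)
    ho, ho_avg = observed_heterozygosity(geno)
    f, f_avg = inbreeding_coefficient(ho, he)
    sh, sh_avg = shannon_index(freqs)
    rows = {
        "he": (he_avg, int(np.isfinite(he).sum())),
        "2he": (2.0 * he_avg, int(np.isfinite(he).sum())),
        "ho": (ho_avg, int(np.isfinite(ho).sum())),
        "f": (f_avg, int(np.isfinite(f).sum())),
        "sh": (sh_avg, int(np.isfinite(sh).sum())),
    }
    return pd.DataFrame(
        {"value": {k: v[0] for k, v in rows.items()},
         "n_loci": {k: v[1] for k, v in rows.items()}}
    )


def mrd_matrix(geno: GenotypeMatrix, min_overlap: int = 10) -> DistanceMatrix:
    """Modified Rogers distance matrix.

    With complete data this is the Euclidean distance between dosage/2
    vectors scaled by 1/sqrt(2L) (each locus contributes
    (dx/2 - dy/2)^2 + ((1-dx/2) - (1-dy/2))^2 = 2*(dx/2 - dy/2)^2).
    Under missingness, pairs use their pairwise-complete loci L_xy with
    scaling 1/sqrt(2 L_xy); pairs below ``min_overlap`` are NaN.
    """
    x = geno.dosage / 2.0
    miss = np.isnan(x)
    if not miss.any():
        diff2 = _pairwise_sq_euclid(x)
        L = geno.n_markers
        d = np.sqrt(np.maximum(2.0 * diff2, 0.0) / (2.0 * L))
        overlap = np.full((geno.n_samples, geno.n_samples), L, dtype=np.int64)
    else:
        filled = np.where(miss, 0.0, x)
        obs = (~miss).astype(np.float64)
        # sum over pairwise-complete loci of (x_i - x_j)^2, via masked expansion
        sq = filled**2
        s_xx = (sq @ obs.T) + (obs @ sq.T) - 2.0 * (filled @ filled.T)
        overlap = (obs @ obs.T).astype(np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt(np.maximum(2.0 * s_xx, 0.0) / (2.0 * np.maximum(overlap, 1)))
        d[overlap < max(min_overlap, 1)] = np.nan
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # symmetrize away float round-off
    return DistanceMatrix(list(geno.samples), np.clip(d, 0.0, 1.0), "MRD", overlap)


def _pairwise_sq_euclid(x: np.ndarray) -> np.ndarray:
    sq = (x**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    return np.maximum(d2, 0.0)


def jaccard_matrix(presence: PresenceMatrix, as_distance: bool = False) -> DistanceMatrix:
    """Jaccard similarity n_pp/(n_pp + n_ap + n_pa) over pairwise-complete
    loci; pairs whose denominator is zero (both profiles all-absent) are NaN.
    ``as_distance`` returns 1 - similarity instead."""
    p = presence.presence
    miss = np.isnan(p)
    pres = np.where(miss, 0.0, p)
    obs = (~miss).astype(np.float64)
    n_pp = pres @ pres.T
    # disagreements: present in one, absent (but observed) in the other
    absent_obs = obs - pres
    n_pa = pres @ absent_obs.T
    n_ap = absent_obs @ pres.T
    denom = n_pp + n_pa + n_ap
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, n_pp / np.maximum(denom, 1.0), np.nan)
    ov = (obs @ obs.T).astype(np.int64)
    np.fill_diagonal(sim, 1.0)
    sim = 0.5 * (sim + sim.T)
    sim = np.clip(sim, 0.0, 1.0)
    if as_distance:
        return DistanceMatrix(list(presence.samples), 1.0 - sim, "jaccard-distance", ov)
    return DistanceMatrix(list(presence.samples), sim, "jaccard-similarity", ov)


def allele_retention(full: GenotypeMatrix, core: GenotypeMatrix) -> float:
    """Fraction of the full population's segregating alleles still present in
    the core subset (both alleles counted per segregating locus)."""
    if list(core.markers) != list(full.markers):
        raise ValueError("core and full matrices must share the marker set")
    pf = allele_frequencies(full).p_alt
    pc = allele_frequencies(core).p_alt
    seg = np.isfinite(pf) & (pf > 0) & (pf < 1)
    if not seg.any():
        return 1.0
    alt_kept = np.nan_to_num(pc[seg]) > 0
    ref_kept = np.nan_to_num(1.0 - pc[seg]) > 0
    return float((alt_kept.sum() + ref_kept.sum()) / (2.0 * seg.sum()))
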