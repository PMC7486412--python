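"""Nei-style population differentiation: per-locus and global FST, AMOVA
tables, permutation significance, windowed scans, and per-split selection
footprints.

At a biallelic locus, with subpopulation alternate-allele frequencies p_k,
    H_S = average within-subpopulation diversity, mean_k 2 p_k (1 - p_k)
    H_T = diversity of the pooled frequency, 2 pbar (1 - pbar)
    D_ST = H_T - H_S        (among-subpopulation diversity, >= 0 by Jensen)
    F_ST = D_ST / H_T       (undefined when H_T = 0)
The default pooling is the plain (equal-weight) average of subpopulation
frequencies; size-weighted pooling is available. Global FST over loci is the
ratio of sums sum(D_ST) / sum(H_T), with the mean per-locus FST reported as
a secondary summary.

FST has no standard null distribution, so significance comes from label
permutations: group assignments are shuffled (group sizes preserved), global
FST is recomputed per permutation, and the observed value is compared with
the 90th/95th percentiles of the null; the p-value uses the add-one
estimator (#{null >= observed} + 1) / (n_perm + 1).

Windowed scans tile each chromosome with fixed non-overlapping windows
(0-based half-open [m*W, (m+1)*W) over the 1-based bp positions), aggregate
by ratio-of-sums within the window, and omit empty windows. The per-split
footprint scan runs a windowed FST between the two daughter groups of every
merge of a cluster tree, top-down, ranking windows per split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .structure import ClusterTree


@dataclass
class FstRecord:
    locus: str
    h_t: float
    h_s: float
    d_st: float
    f_st: float  # NaN flags H_T = 0
    group_sizes: list[int] = field(default_factory=list)


def _he(p: np.ndarray) -> np.ndarray:
    return 2.0 * p * (1.0 - p)


def group_frequencies(
    geno: GenotypeMatrix, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-group alternate-allele frequencies.

    Returns (groups, P, C): group codes, a K x L frequency matrix (NaN where
    a group has no calls), and the K x L matrix of called-sample counts.
    """
    labels = np.asarray(labels)
    if len(labels) != geno.n_samples:
        raise ValueError("labels must cover all samples")
    groups = np.unique(labels)
    X = np.nan_to_num(geno.dosage, nan=0.0)
    Cmask = (~geno.missing_mask()).astype(np.float64)
    P = np.empty((len(groups), geno.n_markers))
    C = np.empty_like(P)
    for gi, g in enumerate(groups):
        rows = labels == g
        C[gi] = Cmask[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            P[gi] = np.where(C[gi] > 0, X[rows].sum(axis=0) / (2.0 * np.maximum(C[gi], 1)), np.nan)
    return groups, P, C


def _fst_components(
    P: np.ndarray, C: np.ndarray, weighting: str = "equal"
) -> tuple[np.ndarray, np.ndarray]:
    """(H_T, H_S) per locus; NaN where any group lacks calls."""
    if weighting not in ("equal", "size"):
        raise ValueError(f"unknown weighting {weighting!r}")
    defined = (C > 0).all(axis=0)
    with np.errstate(invalid="ignore"):
        if weighting == "equal":
            h_s = _he(P).mean(axis=0)
            pbar = P.mean(axis=0)
        else:
            w = C / np.maximum(C.sum(axis=0, keepdims=True), 1)
            h_s = (w * _he(P)).sum(axis=0)
            pbar = (w * P).sum(axis=0)
        h_t = _he(pbar)
    h_t = np.where(defined, h_t, np.nan)
    h_s = np.where(defined, h_s, np.nan)
    # clip tiny negative round-off in D_ST at the source
    h_s = np.minimum(h_s, h_t)
    return h_t, h_s


def nei_fst_locus(
    group_freqs, group_sizes, weighting: str = "equal", locus: str = "locus"
) -> FstRecord:
    """Single-locus Nei FST from group frequencies and sample sizes."""
    p = np.asarray(group_freqs, dtype=float)
    sizes = np.asarray(group_sizes, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("need frequencies for >= 2 groups")
    if np.isnan(p).any():
        raise ValueError("undefined group frequency at this locus")
    h_t, h_s = _fst_components(p[:, None], sizes[:, None], weighting)
    h_t, h_s = float(h_t[0]), float(h_s[0])
    d_st = h_t - h_s
    f_st = d_st / h_t if h_t > 0 else np.nan
    return FstRecord(locus, h_t, h_s, d_st, f_st, [int(s) for s in sizes])


def fst_table(
    geno: GenotypeMatrix, labels: np.ndarray, weighting: str = "equal"
) -> pd.DataFrame:
    """Per-locus H_T, H_S, D_ST, F_ST over the given grouping."""
    _, P, C = group_frequencies(geno, labels)
    h_t, h_s = _fst_components(P, C, weighting)
    d_st = h_t - h_s
    with np.errstate(invalid="ignore", divide="ignore"):
        f_st = np.where(h_t > 0, d_st / np.where(h_t > 0, h_t, 1.0), np.nan)
    return pd.DataFrame(
        {"H_T": h_t, "H_S": h_s, "D_ST": d_st, "F_ST": f_st},
        index=pd.Index(geno.markers, name="marker"),
    )


def global_fst(table: pd.DataFrame) -> tuple[float, float]:
    """(ratio-of-sums FST, mean per-locus FST) over loci with H_T > 0."""
    ok = table["H_T"] > 0
    if not ok.any():
        return np.nan, np.nan
    ratio = float(table.loc[ok, "D_ST"].sum() / table.loc[ok, "H_T"].sum())
    return ratio, float(table.loc[ok, "F_ST"].mean())


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    percentile_90: float
    percentile_95: float
    n_perm: int
    seed: int
    null_values: np.ndarray | None = None


def fst_permutation_test(
    geno: GenotypeMatrix,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    weighting: str = "equal",
    keep_null: bool = False,
) -> PermutationResult:
    """Permutation null for the global ratio-of-sums FST.

    Labels are shuffled uniformly (group sizes preserved); deterministic
    given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if (counts == 0).any():
        raise ValueError("empty group")

    X = np.nan_to_num(geno.dosage, nan=0.0)
    Cmask = (~geno.missing_mask()).astype(np.float64)

    def _global(perm_labels: np.ndarray) -> float:
        P = np.empty((len(groups), geno.n_markers))
        C = np.empty_like(P)
        for gi, g in enumerate(groups):
            rows = perm_labels == g
            C[gi] = Cmask[rows].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                P[gi] = np.where(C[gi] > 0, X[rows].sum(axis=0) / (2.0 * np.maximum(C[gi], 1)), np.nan)
        h_t, h_s = _fst_components(P, C, weighting)
        ok = np.nan_to_num(h_t) > 0
        if not ok.any():
            return np.nan
        return float((h_t[ok] - h_s[ok]).sum() / h_t[ok].sum())

    observed = _global(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _global(rng.permutation(labels))
    p = (np.sum(null >= observed) + 1.0) / (n_perm + 1.0)
    return PermutationResult(
        observed,
        float(p),
        float(np.percentile(null, 90)),
        float(np.percentile(null, 95)),
        n_perm,
        seed,
        null if keep_null else None,
    )


def windowed_fst(
    geno: GenotypeMatrix,
    marker_info: pd.DataFrame,
    labels: np.ndarray,
    window_bp: int = 1_000_000,
    weighting: str = "equal",
) -> pd.DataFrame:
    """Fixed non-overlapping windowed FST profile.

    Columns: chrom, start, end (0-based half-open bp), n_loci, weighted_fst
    (ratio of sums within the window), mean_fst. Loci without a bp position
    are excluded; their count is available as ``df.attrs['n_unplaced']``.
    Windows with no informative loci (all H_T = 0 or undefined) are omitted.
    """
    info = marker_info.reindex(geno.markers)
    if info["chrom"].isna().any():
        raise ValueError("marker registry does not cover the genotype markers")
    table = fst_table(geno, labels, weighting)
    bp = info["bp"]
    placed = bp.notna().to_numpy()
    n_unplaced = int((~placed).sum())

    rows = []
    bp_arr = bp.to_numpy(dtype=float)
    chrom_arr = info["chrom"].to_numpy()
    h_t = table["H_T"].to_numpy()
    d_st = table["D_ST"].to_numpy()
    f_st = table["F_ST"].to_numpy()
    usable = placed & np.isfinite(h_t) & (h_t > 0)
    for chrom in pd.unique(chrom_arr[placed]):
        sel = usable & (chrom_arr == chrom)
        if not sel.any():
            continue
        # 1-based bp -> 0-based coordinate, then fixed tiling
        win = ((bp_arr[sel] - 1) // window_bp).astype(int)
        for w in np.unique(win):
            m = sel.copy()
            m[sel] = win == w
            rows.append(
                (
                    chrom,
                    int(w * window_bp),
                    int((w + 1) * window_bp),
                    int(m.sum()),
                    float(d_st[m].sum() / h_t[m].sum()),
                    float(np.nanmean(f_st[m])),
                )
            )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_loci", "weighted_fst", "mean_fst"]
    )
    out.attrs["n_unplaced"] = n_unplaced
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


@dataclass
class SplitScan:
    split: int  # 0 = root split (level 1 -> 2)
    k_level: int  # partition level this split creates
    left: np.ndarray
    right: np.ndarray
    profile: pd.DataFrame  # windowed FST, ranked by weighted_fst desc


def split_footprint_scan(
    tree: ClusterTree,
    geno: GenotypeMatrix,
    marker_info: pd.DataFrame,
    k_max: int = 2,
    window_bp: int = 1_000_000,
    weighting: str = "equal",
) -> list[SplitScan]:
    """Windowed FST between the two daughter groups of each cluster split,
    from the root split down to the split creating level ``k_max``. Splits
    with a daughter group of fewer than 2 samples are skipped."""
    if list(tree.ids) != list(geno.samples):
        raise ValueError("tree and genotype matrix must share the sample set")
    scans: list[SplitScan] = []
    for split in range(0, max(k_max - 1, 1)):
        left, right = tree.split_members(split)
        if len(left) < 2 or len(right) < 2:
            continue
        idx = np.concatenate([left, right])
        sub = geno.subset(sample_idx=idx)
        labels = np.concatenate([np.zeros(len(left), int), np.ones(len(right), int)])
        prof = windowed_fst(sub, marker_info, labels, window_bp, weighting)
        prof = prof.sort_values("weighted_fst", ascending=False, kind="stable").reset_index(drop=True)
        scans.append(SplitScan(split, split + 2, left, right, prof))
    return scans


def _polymorphic(P: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Loci polymorphic in the pooled sample of the given groups."""
    with np.errstate(invalid="ignore"):
        tot = (2.0 * C * P).sum(axis=0)
        alleles = 2.0 * C.sum(axis=0)
    p = np.where(alleles > 0, tot / np.maximum(alleles, 1), np.nan)
    return np.isfinite(p) & (p > 0) & (p < 1)


def amova(
    geno: GenotypeMatrix,
    labels: np.ndarray,
    marker_mode: str = "all_informative",
    weighting: str = "equal",
) -> dict:
    """AMOVA between/within groups under one of three marker-informativeness
    modes:

    - ``all_informative``: loci polymorphic in the pooled sample of all
      groups; one table over all groups.
    - ``pair_informative``: for every group pair, loci polymorphic in the
      pooled sample of that pair; one table per pair.
    - ``common_informative``: loci polymorphic within every group; one table
      over all groups.

    Each result holds the per-locus table, the marker count, and the global
    (ratio-of-sums) and mean FST.
    """
    labels = np.asarray(labels)
    groups, P, C = group_frequencies(geno, labels)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")

    def _result(sub_labels_mask: np.ndarray, loci_mask: np.ndarray) -> dict:
        sub = geno.subset(
            sample_idx=np.flatnonzero(sub_labels_mask),
            marker_idx=np.flatnonzero(loci_mask),
        )
        tab = fst_table(sub, labels[sub_labels_mask], weighting)
        ratio, mean = global_fst(tab)
        return {
            "table": tab,
            "n_markers": int(loci_mask.sum()),
            "global_fst": ratio,
            "mean_fst": mean,
        }

    if marker_mode == "all_informative":
        loci = _polymorphic(P, C)
        return {"all": _result(np.ones(len(labels), bool), loci)}
    if marker_mode == "common_informative":
        with np.errstate(invalid="ignore"):
            loci = np.all(np.isfinite(P) & (P > 0) & (P < 1), axis=0)
        return {"all": _result(np.ones(len(labels), bool), loci)}
    if marker_mode == "pair_informative":
        out = {}
        for a, b in combinations(range(len(groups)), 2):
            pair_mask = np.isin(labels, [groups[a], groups[b]])
            loci = _polymorphic(P[[a, b]], C[[a, b]])
            out[(groups[a], groups[b])] = _result(pair_mask, loci)
        return out
    raise ValueError(f"unknown marker_mode {marker_mode!r}")
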