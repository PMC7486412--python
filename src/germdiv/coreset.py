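"""Core-subset construction by the D-method.

A core collection is a small sample (20% by default) of a genebank chosen
to preserve its genetic diversity. The workflow: (1) Ward-cluster the
accessions on their pairwise modified Rogers distances; (2) allocate to each
cluster a number of core slots proportional to the cluster's diversity,
measured as its mean within-cluster MRD (the D-method) — not to its size;
(3) draw 1000 candidate subsets by stratified random sampling honoring the
allocation; (4) keep the candidate with the maximum mean pairwise distance;
(5) compare diversity indices of core vs full collection.

Allocation is integerized by largest remainder so the total hits
round(fraction * n) exactly, with a floor of one slot per non-empty cluster
and caps at cluster size (surplus redistributed by remainder order). If all
within-cluster diversities are zero, allocation falls back to
size-proportional shares (logged in the allocation object).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DistanceMatrix, GenotypeMatrix
from .popgen import allele_retention, diversity_summary
from .structure import hierarchical_tree, pseudo_f_profile


@dataclass
class Allocation:
    cluster_ids: list
    sizes: np.ndarray
    mean_mrd: np.ndarray  # within-cluster mean pairwise distance d_k
    allocated: np.ndarray
    fraction: float
    fallback_size_proportional: bool = False

    @property
    def total(self) -> int:
        return int(self.allocated.sum())


@dataclass
class CoreSubset:
    selected: list[str]
    score: float  # mean pairwise distance within the selected set
    n_candidates: int
    seed: int
    allocation: Allocation | None = None


def within_cluster_mean_distance(D: DistanceMatrix, labels: np.ndarray) -> pd.Series:
    """Mean pairwise distance inside each cluster; singletons get 0."""
    labels = np.asarray(labels)
    vals = {}
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            vals[c] = 0.0
            continue
        sub = D.values[np.ix_(idx, idx)]
        vals[c] = float(sub[np.triu_indices(len(idx), k=1)].mean())
    return pd.Series(vals)


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(shares).astype(int)
    rem = shares - base
    short = total - base.sum()
    order = np.argsort(-rem, kind="stable")
    out = base.copy()
    out[order[:short]] += 1
    return out


def d_method_allocation(
    sizes,
    mean_mrds,
    fraction: float = 0.20,
    min_per_cluster: int = 1,
    cluster_ids=None,
) -> Allocation:
    """Diversity-proportional core slots per cluster.

    Raw shares are N_core * d_k / sum(d_j) with N_core = round(fraction*n);
    largest-remainder integerization preserves the total, then floors
    (min_per_cluster on non-empty clusters) and caps (cluster size) are
    enforced by redistributing the imbalance along remainder order.
    """
    sizes = np.asarray(sizes, dtype=int)
    d = np.asarray(mean_mrds, dtype=float)
    if (d < 0).any():
        raise ValueError("mean within-cluster distances must be >= 0")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    if cluster_ids is None:
        cluster_ids = list(range(len(sizes)))
    n = int(sizes.sum())
    n_core = int(round(fraction * n))
    n_core = max(n_core, min_per_cluster * int((sizes > 0).sum()))
    n_core = min(n_core, n)

    fallback = False
    weights = d.copy()
    if weights.sum() == 0:
        if len(weights) > 1:
            fallback = True
        weights = sizes.astype(float)
    shares = n_core * weights / weights.sum()
    alloc = _largest_remainder(shares, n_core)

    # floors and caps with iterative redistribution
    lo = np.where(sizes > 0, min_per_cluster, 0)
    hi = sizes
    alloc = np.clip(alloc, lo, hi)
    rem = shares - np.floor(shares)
    for _ in range(10 * len(alloc) + 10):
        diff = n_core - alloc.sum()
        if diff == 0:
            break
        if diff > 0:
            room = np.flatnonzero(alloc < hi)
            give = room[np.argsort(-rem[room], kind="stable")][0]
            alloc[give] += 1
        else:
            room = np.flatnonzero(alloc > lo)
            take = room[np.argsort(rem[room], kind="stable")][0]
            alloc[take] -= 1
    if alloc.sum() != n_core:
        raise RuntimeError("allocation could not satisfy floors/caps/total")
    return Allocation(list(cluster_ids), sizes, d, alloc, fraction, fallback)


def sample_candidates(
    allocation: Allocation,
    memberships: np.ndarray,
    n_candidates: int = 1000,
    seed: int = 0,
) -> list[np.ndarray]:
    """Stratified random candidate subsets: each candidate draws, without
    replacement, the allocated count from every cluster. Deterministic given
    ``seed``; candidates are index arrays into the sample order."""
    memberships = np.asarray(memberships)
    rng = np.random.default_rng(seed)
    per_cluster = {}
    for cid, count, size in zip(allocation.cluster_ids, allocation.allocated, allocation.sizes):
        idx = np.flatnonzero(memberships == cid)
        if len(idx) != size:
            raise ValueError(f"cluster {cid} membership size {len(idx)} != allocation size {size}")
        if count > len(idx):
            raise ValueError(f"allocation {count} exceeds cluster {cid} size {len(idx)}")
        per_cluster[cid] = (idx, int(count))
    out = []
    for _ in range(n_candidates):
        parts = [rng.choice(idx, size=cnt, replace=False) for idx, cnt in per_cluster.values()]
        out.append(np.sort(np.concatenate(parts)))
    return out


def select_core(
    candidates: list[np.ndarray], D: DistanceMatrix, seed: int = 0
) -> CoreSubset:
    """Pick the candidate with the maximum mean pairwise distance; ties go to
    the first candidate in (seeded) generation order."""
    if not candidates:
        raise ValueError("no candidates")
    best_i, best_score = 0, -np.inf
    for i, idx in enumerate(candidates):
        if len(idx) < 2:
            score = 0.0
        else:
            sub = D.values[np.ix_(idx, idx)]
            score = float(sub[np.triu_indices(len(idx), k=1)].mean())
        if score > best_score:
            best_i, best_score = i, score
    chosen = candidates[best_i]
    return CoreSubset(
        [D.ids[i] for i in chosen], best_score, len(candidates), seed
    )


def core_diagnostics(full: GenotypeMatrix, core: GenotypeMatrix) -> pd.DataFrame:
    """Diversity indices of the full collection vs the core subset, plus the
    fraction of the full population's segregating alleles retained."""
    f = diversity_summary(full)["value"]
    c = diversity_summary(core)["value"]
    out = pd.DataFrame({"full": f, "core": c})
    out.loc["allele_retention"] = [1.0, allele_retention(full, core)]
    return out


def build_core(
    geno: GenotypeMatrix,
    D: DistanceMatrix,
    fraction: float = 0.20,
    n_candidates: int = 1000,
    n_strata: int | None = None,
    k_max: int = 30,
    seed: int = 0,
) -> tuple[CoreSubset, pd.DataFrame]:
    """End-to-end D-method core construction.

    Ward-clusters the MRD matrix; the number of strata is the pseudo-F
    global maximum over k = 2..k_max unless fixed by ``n_strata``. Returns
    the core subset and its diversity diagnostics.
    """
    if D.is_similarity:
        D = D.to_distance()
    tree = hierarchical_tree(D, linkage="ward")
    if n_strata is None:
        profile = pseudo_f_profile(D, tree, k_max=min(k_max, D.n - 1))
        n_strata = profile.selected_k
    labels = tree.cut(n_strata)

    uniq = np.unique(labels)
    sizes = np.array([(labels == c).sum() for c in uniq])
    d_k = within_cluster_mean_distance(D, labels).loc[uniq].to_numpy()
    alloc = d_method_allocation(sizes, d_k, fraction=fraction, cluster_ids=list(uniq))
    candidates = sample_candidates(alloc, labels, n_candidates=n_candidates, seed=seed)
    core = select_core(candidates, D, seed=seed)
    core.allocation = alloc

    core_idx = [geno.samples.index(s) for s in core.selected]
    diagnostics = core_diagnostics(geno, geno.subset(sample_idx=core_idx))
    return core, diagnostics
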