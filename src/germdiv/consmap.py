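"""Consensus genetic-map construction.

Linkage-group maps from individual mapping populations are merged into a
single consensus map per chromosome by iterative joining: at each step the
pending group sharing the most information with the current consensus
(commonality = Pearson correlation of shared-marker positions x ln(number of
shared markers), requiring at least three shared markers) is joined by linear
interpolation between shared anchor markers, provided its correlation exceeds
a gate (0.5 by default). Groups failing the gate are removed without joining
and logged.

The commonality log is natural-log: the score's only use is ranking pending
groups, and the ranking is invariant to the log base. Pearson correlation on
cM positions is the default; Spearman is available. Extrapolation beyond the
terminal anchors uses the local scale of the two nearest anchors, so
consensus positions may go negative; ``shift_to_zero`` renormalizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LinkageGroupMap:
    """One linkage group (chromosome) from one mapping population."""

    population: str
    chrom: str
    markers: list[str]
    positions: np.ndarray  # cM

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.markers) != len(self.positions):
            raise ValueError("marker/position length mismatch")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError(f"duplicate markers in group {self.population}/{self.chrom}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite cM positions")
        order = np.argsort(self.positions, kind="stable")
        self.markers = [self.markers[i] for i in order]
        self.positions = self.positions[order]

    def as_series(self) -> pd.Series:
        return pd.Series(self.positions, index=self.markers)


@dataclass
class ConsensusChromosome:
    chrom: str
    positions: "pd.Series"  # marker id -> consensus cM, sorted
    provenance: dict[str, str] = field(default_factory=dict)  # marker -> population

    def ordered_markers(self) -> list[str]:
        return list(self.positions.index)


@dataclass
class ConsensusMap:
    chromosomes: dict[str, ConsensusChromosome]
    join_log: pd.DataFrame  # population, chrom, n_common, r, score, action

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, cc in sorted(self.chromosomes.items()):
            for m, pos in cc.positions.items():
                rows.append((m, chrom, pos, cc.provenance.get(m, "seed")))
        return pd.DataFrame(rows, columns=["marker", "chrom", "cM", "source"]).set_index("marker")


def commonality(
    group: LinkageGroupMap,
    consensus: pd.Series,
    method: str = "pearson",
) -> tuple[float, int, float] | None:
    """Commonality of a pending group with the consensus chromosome.

    Returns ``(r, n_common, score)`` with ``score = r * ln(n_common)``, or
    None when the group is ineligible (fewer than 3 shared markers, or zero
    positional variance among the shared markers).
    """
    shared = [m for m in group.markers if m in consensus.index]
    n_common = len(shared)
    if n_common < 3:
        return None
    g = group.as_series()[shared].to_numpy(dtype=float)
    c = consensus[shared].to_numpy(dtype=float)
    if np.ptp(g) == 0 or np.ptp(c) == 0:
        return None
    if method == "spearman":
        r = float(stats.spearmanr(g, c).statistic)
    else:
        r = float(np.corrcoef(g, c)[0, 1])
    if not math.isfinite(r):
        return None
    return r, n_common, r * math.log(n_common)


def join_by_interpolation(
    group: LinkageGroupMap, consensus: pd.Series
) -> pd.Series:
    """Join a group's markers into the consensus chromosome.

    Shared markers act as anchors and keep their consensus positions; each
    new marker is placed by linear interpolation of its group-cM position
    between the flanking anchors, or extrapolated from the two nearest
    anchors beyond the ends. Coincident anchors bracketing a new marker give
    the midpoint of their consensus positions.
    """
    gser = group.as_series()
    anchors = [m for m in gser.index if m in consensus.index]
    if len(anchors) < 2:
        raise ValueError("need >= 2 anchors to interpolate")
    gx = gser[anchors].to_numpy(dtype=float)
    cy = consensus[anchors].to_numpy(dtype=float)
    order = np.argsort(gx, kind="stable")
    gx, cy = gx[order], cy[order]

    new = {m: p for m, p in gser.items() if m not in consensus.index}
    placed: dict[str, float] = {}
    for m, x in new.items():
        placed[m] = _interp_extrap(x, gx, cy)
    out = pd.concat([consensus, pd.Series(placed, dtype=float)])
    return out.sort_values(kind="stable")


def _interp_extrap(x: float, gx: np.ndarray, cy: np.ndarray) -> float:
    """Piecewise-linear through the anchors; linear beyond the ends."""
    n = len(gx)
    if x <= gx[0]:
        lo, hi = 0, 1
    elif x >= gx[-1]:
        lo, hi = n - 2, n - 1
    else:
        hi = int(np.searchsorted(gx, x, side="left"))
        lo = hi - 1
        if gx[hi] == x:
            return float(cy[hi])
    span = gx[hi] - gx[lo]
    if span == 0:
        return float(0.5 * (cy[lo] + cy[hi]))  # coincident anchors: midpoint
    return float(cy[lo] + (x - gx[lo]) / span * (cy[hi] - cy[lo]))


def build_consensus(
    seed_map: list[LinkageGroupMap] | dict[str, pd.Series],
    groups: list[LinkageGroupMap],
    r_gate: float = 0.5,
    method: str = "pearson",
    shift_to_zero: bool = False,
) -> ConsensusMap:
    """Merge linkage groups into the seed map, chromosome by chromosome.

    Per chromosome the pending subset is scanned repeatedly: the eligible
    group with the highest commonality score is joined if its correlation
    exceeds ``r_gate``; otherwise it is removed without joining. Ties on
    score break by population id order. Groups on chromosomes absent from
    the seed are rejected.
    """
    if isinstance(seed_map, dict):
        cons: dict[str, pd.Series] = {c: s.sort_values(kind="stable") for c, s in seed_map.items()}
    else:
        cons = {}
        for g in seed_map:
            if g.chrom in cons:
                raise ValueError(f"seed map has duplicate chromosome {g.chrom}")
            cons[g.chrom] = g.as_series()
    provenance: dict[str, dict[str, str]] = {
        c: {m: "seed" for m in s.index} for c, s in cons.items()
    }
    log_rows = []

    pending_by_chrom: dict[str, list[LinkageGroupMap]] = {}
    for g in groups:
        pending_by_chrom.setdefault(g.chrom, []).append(g)

    for chrom, pending in sorted(pending_by_chrom.items()):
        pending = sorted(pending, key=lambda g: g.population)
        if chrom not in cons:
            for g in pending:
                log_rows.append((g.population, chrom, 0, np.nan, np.nan, "rejected_no_seed_chromosome"))
            continue
        while pending:
            scored = []
            for g in pending:
                res = commonality(g, cons[chrom], method=method)
                if res is not None:
                    scored.append((g, *res))
            if not scored:
                for g in pending:
                    log_rows.append((g.population, chrom, 0, np.nan, np.nan, "rejected_ineligible"))
                break
            # max returns the first maximum; pending is population-sorted, so
            # score ties break by population id order
            best, r, n_common, score = max(scored, key=lambda t: t[3])
            if r > r_gate:
                new_markers = [m for m in best.markers if m not in cons[chrom].index]
                cons[chrom] = join_by_interpolation(best, cons[chrom])
                for m in new_markers:
                    provenance[chrom][m] = best.population
                log_rows.append((best.population, chrom, n_common, r, score, "joined"))
            else:
                log_rows.append((best.population, chrom, n_common, r, score, "rejected_low_r"))
            pending = [g for g in pending if g is not best]

    if shift_to_zero:
        cons = {c: s - s.min() for c, s in cons.items()}

    chromosomes = {
        c: ConsensusChromosome(c, s, provenance.get(c, {})) for c, s in cons.items()
    }
    log = pd.DataFrame(
        log_rows, columns=["population", "chrom", "n_common", "r", "score", "action"]
    )
    return ConsensusMap(chromosomes, log)
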