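"""Data-cleaning filters and genome-fraction ploidy QC.

The SNP cleaning sequence keeps markers with missing fraction <= 0.50 and
minor-allele frequency strictly > 0.001 (computed on non-missing calls),
then keeps samples with missing fraction <= 0.50 (domesticated wheat) or
0.75 (wild relatives). SilicoDArT presence/absence markers are kept at
missing fraction <= 0.80. The order — marker filters first, then samples —
is fixed and reported.

Ploidy QC exploits bread wheat's AABBDD constitution: a hexaploid accession
scores markers across the D genome while a tetraploid (AABB) does not, so
the fraction of a sample's scored markers on D-labeled chromosomes exposes
passport misclassification. Declared tetraploids with D fraction > 10% are
suspect (> 20% strongly so); declared hexaploids with D fraction < 20% are
suspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GENOME_CLASSES, GenotypeMatrix, PresenceMatrix


@dataclass
class FilterReport:
    axis: str  # "markers" or "samples"
    n_in: int
    n_out: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_out + sum(self.removed_by_rule.values()) != self.n_in:
            # rules may overlap; store the union count explicitly
            self.removed_by_rule.setdefault("_union_removed", self.n_in - self.n_out)

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


def filter_markers(
    geno: GenotypeMatrix, max_missing: float = 0.50, min_maf: float = 0.001
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep markers with missing fraction <= max_missing AND MAF strictly >
    min_maf; marker order is preserved. MAF uses non-missing calls only;
    all-missing markers fail both rules."""
    n, L = geno.n_samples, geno.n_markers
    miss = geno.missing_mask()
    miss_frac = miss.mean(axis=0)
    called = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, np.nansum(geno.dosage, axis=0) / (2.0 * np.maximum(called, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)
    pass_miss = miss_frac <= max_missing
    pass_maf = np.nan_to_num(maf, nan=0.0) > min_maf
    keep = pass_miss & pass_maf
    out = geno.subset(marker_idx=np.flatnonzero(keep))
    report = FilterReport(
        axis="markers",
        n_in=L,
        n_out=int(keep.sum()),
        removed_by_rule={
            "missing_rate": int((~pass_miss).sum()),
            "maf": int((~pass_maf).sum()),
        },
        thresholds={"max_missing": max_missing, "min_maf": min_maf},
    )
    return out, report


def filter_samples(
    geno: GenotypeMatrix, max_missing: float = 0.50
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep samples with missing fraction <= max_missing (0.50 for
    domesticated wheat; 0.75 is the conventional relaxation for wild
    relatives)."""
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    miss_frac = geno.missing_mask().mean(axis=1)
    keep = miss_frac <= max_missing
    out = geno.subset(sample_idx=np.flatnonzero(keep))
    report = FilterReport(
        axis="samples",
        n_in=geno.n_samples,
        n_out=int(keep.sum()),
        removed_by_rule={"missing_rate": int((~keep).sum())},
        thresholds={"max_missing": max_missing},
    )
    return out, report


def filter_presence_markers(
    presence: PresenceMatrix, max_missing: float = 0.80
) -> tuple[PresenceMatrix, FilterReport]:
    """Keep SilicoDArT markers with missing fraction <= max_missing."""
    miss_frac = np.isnan(presence.presence).mean(axis=0)
    keep = miss_frac <= max_missing
    out = presence.subset(marker_idx=np.flatnonzero(keep))
    report = FilterReport(
        axis="markers",
        n_in=presence.n_markers,
        n_out=int(keep.sum()),
        removed_by_rule={"missing_rate": int((~keep).sum())},
        thresholds={"max_missing": max_missing},
    )
    return out, report


def filter_reproducibility(
    geno: GenotypeMatrix,
    reproducibility: pd.Series,
    min_reproducibility: float = 0.95,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Optional genotyping-stage pre-filter on a per-marker replicate
    concordance column (markers absent from the column are dropped)."""
    rep = reproducibility.reindex(geno.markers)
    keep = (rep >= min_reproducibility).fillna(False).to_numpy()
    out = geno.subset(marker_idx=np.flatnonzero(keep))
    report = FilterReport(
        axis="markers",
        n_in=geno.n_markers,
        n_out=int(keep.sum()),
        removed_by_rule={"reproducibility": int((~keep).sum())},
        thresholds={"min_reproducibility": min_reproducibility},
    )
    return out, report


def clean_pipeline(
    geno: GenotypeMatrix,
    max_missing_marker: float = 0.50,
    min_maf: float = 0.001,
    max_missing_sample: float = 0.50,
) -> tuple[GenotypeMatrix, list[FilterReport]]:
    """The full SNP cleaning sequence in its fixed order: marker missing-rate
    and MAF filters, then the sample missing-rate filter."""
    g1, r1 = filter_markers(geno, max_missing_marker, min_maf)
    g2, r2 = filter_samples(g1, max_missing_sample)
    return g2, [r1, r2]


def genome_fractions(
    scores: GenotypeMatrix | PresenceMatrix, marker_info: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample fraction of qualifying markers on each genome class.

    A marker qualifies for a sample when its call is non-missing — and, for
    presence/absence data, present. Rows with zero qualifying markers are
    flagged ``indeterminate``. Fractions sum to 1 over {A, B, D, other}.
    """
    genome = marker_info.reindex(
        scores.markers if isinstance(scores.markers, list) else list(scores.markers)
    )["genome"]
    if genome.isna().any():
        raise ValueError("marker registry missing entries for scored markers")
    if isinstance(scores, PresenceMatrix):
        qual = np.nan_to_num(scores.presence, nan=0.0) == 1.0
    else:
        qual = ~scores.missing_mask()
    counts = {}
    for cls in GENOME_CLASSES:
        mask = (genome == cls).to_numpy()
        counts[cls] = qual[:, mask].sum(axis=1)
    total = sum(counts.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = {cls: np.where(total > 0, c / np.maximum(total, 1), np.nan) for cls, c in counts.items()}
    df = pd.DataFrame(fracs, index=pd.Index(scores.samples, name="sample"))
    df["n_qualifying"] = total
    df["indeterminate"] = total == 0
    return df


def classify_ploidy(
    fractions: pd.DataFrame,
    declared: pd.Series,
    tetra_suspect_d: float = 0.10,
    tetra_strong_d: float = 0.20,
    hexa_suspect_d: float = 0.20,
) -> pd.DataFrame:
    """Flag samples whose declared ploidy conflicts with their D-genome
    marker fraction.

    Declared tetraploids with D fraction > tetra_suspect_d are
    ``suspect_tetraploid`` (``strong`` column set above tetra_strong_d);
    declared hexaploids with D fraction < hexa_suspect_d are
    ``suspect_hexaploid``; everything else (including CWR and indeterminate
    rows) is ``consistent`` with the indeterminate flag carried through.
    """
    declared = declared.reindex(fractions.index)
    d = fractions["D"]
    flag = pd.Series("consistent", index=fractions.index, dtype="object")
    strong = pd.Series(False, index=fractions.index)
    ok = ~fractions["indeterminate"].astype(bool)
    tet = ok & (declared == "tetraploid") & (d > tetra_suspect_d)
    flag[tet] = "suspect_tetraploid"
    strong[tet & (d > tetra_strong_d)] = True
    hexa = ok & (declared == "hexaploid") & (d < hexa_suspect_d)
    flag[hexa] = "suspect_hexaploid"
    out = fractions[["A", "B", "D", "other", "indeterminate"]].copy()
    out["declared"] = declared
    out["flag"] = flag
    out["strong"] = strong
    return out
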