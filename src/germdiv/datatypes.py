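"""Core in-memory containers shared across the pipeline.

Genotypes are allele-dosage matrices (samples x loci, entries 0/1/2 with NaN
for missing calls); SilicoDArT-style dominant markers are presence/absence
matrices (0/1/NaN). Marker metadata (chromosome, A/B/D genome class, bp and
cM positions) and accession passports travel as pandas DataFrames keyed by
marker / accession id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOME_CLASSES = ("A", "B", "D", "other")

BIOLOGICAL_STATUSES = (
    "landrace",
    "cultivar",
    "elite",
    "nursery",
    "genetic stock",
    "primary synthetic",
    "synthetic derivative",
    "unknown",
)

PLOIDY_CLASSES = ("hexaploid", "tetraploid", "CWR")


def _check_ids(ids: list[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")
    return ids


@dataclass
class GenotypeMatrix:
    """Samples x SNP loci allele-dosage matrix.

    ``dosage`` is float64 with entries in {0, 1, 2} and NaN for missing; rows
    are samples, columns are markers.
    """

    samples: list[str]
    markers: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = _check_ids(self.samples, "sample")
        self.markers = _check_ids(self.markers, "marker")
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.markers)})"
            )
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosage[~ok][0]
            raise ValueError(f"dosage entries must be 0/1/2/NaN, found {bad!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            [self.samples[i] for i in si],
            [self.markers[j] for j in mi],
            self.dosage[np.ix_(si, mi)],
        )


@dataclass
class PresenceMatrix:
    """Samples x SilicoDArT loci binary presence/absence matrix (1/0/NaN)."""

    samples: list[str]
    markers: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.samples = _check_ids(self.samples, "sample")
        self.markers = _check_ids(self.markers, "marker")
        self.presence = np.asarray(self.presence, dtype=np.float64)
        if self.presence.shape != (len(self.samples), len(self.markers)):
            raise ValueError("presence shape mismatch with ids")
        ok = np.isnan(self.presence) | np.isin(self.presence, (0.0, 1.0))
        if not ok.all():
            raise ValueError("presence entries must be 0/1/NaN")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset(self, sample_idx=None, marker_idx=None) -> "PresenceMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return PresenceMatrix(
            [self.samples[i] for i in si],
            [self.markers[j] for j in mi],
            self.presence[np.ix_(si, mi)],
        )


def make_marker_info(
    markers: list[str],
    chrom: list[str],
    genome: list[str] | None = None,
    bp=None,
    cM=None,
) -> pd.DataFrame:
    """Build the per-marker registry.

    Columns: ``chrom`` (str), ``genome`` (one of A/B/D/other), ``bp``
    (nullable 1-based integer position), ``cM`` (nullable float).
    """
    n = len(markers)
    if genome is None:
        genome = ["other"] * n
    genome = ["other" if g not in GENOME_CLASSES else g for g in genome]
    df = pd.DataFrame(
        {
            "chrom": pd.array([str(c) for c in chrom], dtype="string"),
            "genome": pd.Categorical(genome, categories=GENOME_CLASSES),
            "bp": pd.array([None] * n if bp is None else bp, dtype="Int64"),
            "cM": pd.array([np.nan] * n if cM is None else cM, dtype="Float64"),
        },
        index=pd.Index(markers, name="marker"),
    )
    if df.index.has_duplicates:
        raise ValueError("duplicate marker ids in registry")
    if ((df["bp"].dropna() < 1)).any():
        raise ValueError("bp positions must be >= 1 (1-based)")
    if ((df["cM"].dropna() < 0)).any():
        raise ValueError("cM positions must be >= 0")
    return df


def make_passport(
    accessions: list[str],
    taxon: list[str] | None = None,
    status: list[str] | None = None,
    country: list[str] | None = None,
    ploidy: list[str] | None = None,
) -> pd.DataFrame:
    """Passport table keyed by accession id; unlisted statuses become 'unknown'."""
    n = len(accessions)
    status = ["unknown"] * n if status is None else [
        s if s in BIOLOGICAL_STATUSES else "unknown" for s in status
    ]
    df = pd.DataFrame(
        {
            "taxon": pd.array(list(taxon) if taxon is not None else ["unknown"] * n, dtype="string"),
            "status": pd.Categorical(status, categories=BIOLOGICAL_STATUSES),
            "country": pd.array(list(country) if country is not None else ["unknown"] * n, dtype="string"),
            "ploidy": pd.array(list(ploidy) if ploidy is not None else ["hexaploid"] * n, dtype="string"),
        },
        index=pd.Index(accessions, name="accession"),
    )
    if df.index.has_duplicates:
        raise ValueError("duplicate accession ids in passport")
    return df


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance/similarity matrix on [0, 1].

    ``metric`` tags the contents (``MRD``, ``jaccard-similarity``,
    ``jaccard-distance``); ``overlap`` counts pairwise-complete loci per pair
    so callers can enforce minimum-overlap rules. Entries with insufficient
    overlap are NaN.
    """

    ids: list[str]
    values: np.ndarray
    metric: str = "MRD"
    overlap: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = _check_ids(self.ids, "sample")
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square matching ids")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_similarity(self) -> bool:
        return self.metric.endswith("similarity")

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_distance(self) -> "DistanceMatrix":
        """Similarity -> distance (1 - s); distances pass through unchanged."""
        if not self.is_similarity:
            return self
        return DistanceMatrix(
            self.ids,
            1.0 - self.values,
            self.metric.replace("similarity", "distance"),
            self.overlap,
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy ``pdist`` order; errors on NaN."""
        if self.has_missing():
            raise ValueError(
                "distance matrix has missing entries; rerun with a lower "
                "min_overlap or drop the affected samples"
            )
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]
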