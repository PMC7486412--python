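"""Synthetic structured germplasm collections with known ground truth.

Emulates the features of a genebank SNP/SilicoDArT dataset that the
downstream pipeline must detect: K drifted subpopulations (Balding-Nichols
Beta model, whose Nei FST has the closed form F(K-1)/(K-F) under equal-weight
pooling), MCAR missing calls, localized high-FST sweep windows, accessions
whose declared ploidy conflicts with their D-genome marker fraction, and
per-population linkage maps that distort a shared true marker order.

Loci are placed uniformly at random on 100-Mb pseudo-chromosomes (then
sorted), so 1-Mb windows hold ~L/(100*n_chrom) loci at desk scale.
Chromosomes cycle through the A, B, D genome classes of bread wheat
(1A, 1B, 1D, 2A, ...), giving every sample a ~1/3 D-genome marker share
unless the generator is told otherwise. Loci are independent (no LD).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .consmap import LinkageGroupMap
from .datatypes import (
    GenotypeMatrix,
    PresenceMatrix,
    make_marker_info,
    make_passport,
)

DEFAULT_CHROM_LENGTH_BP = 100_000_000


@dataclass
class PopulationSpec:
    """Parameters of a structured collection.

    drift_f is the Balding-Nichols drift coefficient F shared by all
    subpopulations: subpopulation allele frequencies are drawn
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p, so the
    expected Nei FST over many loci is F(K-1)/(K-F). admixture_fraction of
    the samples are drawn from a 50/50 mixture of two subpopulation
    frequency vectors.
    """

    n_subpops: int
    samples_per_subpop: list[int]
    n_loci: int
    drift_f: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.0
    admixture_fraction: float = 0.0
    seed: int = 0
    n_chromosomes: int = 3
    chrom_length_bp: int = DEFAULT_CHROM_LENGTH_BP

    def __post_init__(self) -> None:
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if len(self.samples_per_subpop) != self.n_subpops:
            raise ValueError("samples_per_subpop length must equal n_subpops")
        if sum(self.samples_per_subpop) < 2:
            raise ValueError("need at least 2 samples in total")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not (0.0 <= self.drift_f < 1.0):
            raise ValueError("drift_f must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must satisfy 0 < low <= high < 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.admixture_fraction <= 1.0):
            raise ValueError("admixture_fraction must be in [0, 1]")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")


@dataclass
class SweepSpec:
    """A localized differentiation window.

    freq_shift is added to subpopulation ``pop_up``'s allele frequencies and
    subtracted from ``pop_down``'s inside [window_start_bp, window_end_bp)
    on ``chrom``; shifted frequencies are clipped to [0, 1].
    """

    chrom: str
    window_start_bp: int
    window_end_bp: int
    freq_shift: float
    pop_up: int = 0
    pop_down: int = 1

    def __post_init__(self) -> None:
        if self.window_start_bp >= self.window_end_bp:
            raise ValueError("window_start_bp must be < window_end_bp")
        if not (0.0 < self.freq_shift <= 1.0):
            raise ValueError("freq_shift must be in (0, 1]")
        if self.pop_up == self.pop_down:
            raise ValueError("sweep must involve two distinct subpopulations")


@dataclass
class Truth:
    """Ground truth recorded alongside a synthetic collection."""

    labels: np.ndarray  # subpop index per sample
    subpop_freqs: np.ndarray  # K x L allele frequencies actually used
    sweeps: list[SweepSpec] = field(default_factory=list)
    misclassified: list[str] = field(default_factory=list)
    admixed: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class SyntheticCollection:
    geno: GenotypeMatrix
    marker_info: pd.DataFrame
    passport: pd.DataFrame
    truth: Truth
    presence: PresenceMatrix | None = None
    spec: PopulationSpec | None = None

    def __post_init__(self) -> None:
        if len(self.truth.labels) != self.geno.n_samples:
            raise ValueError("truth labels must cover all samples")
        if len(self.marker_info) != self.geno.n_markers:
            raise ValueError("marker registry length must equal number of loci")

    @property
    def labels(self) -> np.ndarray:
        return self.truth.labels


def _wheat_chrom_names(n: int) -> list[str]:
    genomes = "ABD"
    return [f"{i // 3 + 1}{genomes[i % 3]}" for i in range(n)]


def _draw_subpop_freqs(rng: np.random.Generator, p_anc: np.ndarray, k: int, f: float) -> np.ndarray:
    if f == 0.0:
        return np.tile(p_anc, (k, 1))
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    return rng.beta(a[None, :], b[None, :], size=(k, len(p_anc)))


def simulate_structured_snps(spec: PopulationSpec) -> SyntheticCollection:
    """Generate a structured SNP collection under the Balding-Nichols model.

    Deterministic given ``spec`` (including its seed). Dosages are
    Binomial(2, p_subpop) per sample and locus; entries go missing
    independently at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    k, L = spec.n_subpops, spec.n_loci
    lo, hi = spec.ancestral_freq_range

    p_anc = rng.uniform(lo, hi, size=L)
    freqs = _draw_subpop_freqs(rng, p_anc, k, spec.drift_f)

    labels = np.repeat(np.arange(k), spec.samples_per_subpop)
    n = labels.size
    sample_ids = [f"ACC{idx:05d}" for idx in range(n)]

    # per-sample frequency rows; admixed samples get a 50/50 two-parent mixture
    sample_freqs = freqs[labels]
    admixed: dict[str, tuple[int, int]] = {}
    n_adm = int(round(spec.admixture_fraction * n))
    if n_adm and k >= 2:
        adm_idx = rng.choice(n, size=n_adm, replace=False)
        for i in adm_idx:
            a = labels[i]
            b = int(rng.choice([x for x in range(k) if x != a]))
            sample_freqs[i] = 0.5 * (freqs[a] + freqs[b])
            admixed[sample_ids[i]] = (int(a), b)

    dosage = rng.binomial(2, sample_freqs).astype(np.float64)
    if spec.missing_rate > 0:
        dosage[rng.random((n, L)) < spec.missing_rate] = np.nan

    chroms = _wheat_chrom_names(spec.n_chromosomes)
    chrom_of = rng.integers(0, spec.n_chromosomes, size=L)
    bp = rng.integers(1, spec.chrom_length_bp + 1, size=L)
    # sort loci by (chromosome, bp) so the registry reads like a map
    order = np.lexsort((bp, chrom_of))
    chrom_of, bp = chrom_of[order], bp[order]
    dosage = dosage[:, order]
    freqs = freqs[:, order]
    marker_ids = [f"SNP{j:05d}" for j in range(L)]
    info = make_marker_info(
        marker_ids,
        [chroms[c] for c in chrom_of],
        genome=[chroms[c][-1] for c in chrom_of],
        bp=bp,
    )

    geno = GenotypeMatrix(sample_ids, marker_ids, dosage)
    passport = make_passport(
        sample_ids,
        taxon=["Triticum aestivum"] * n,
        status=["landrace"] * n,
        country=["synthetic"] * n,
        ploidy=["hexaploid"] * n,
    )
    truth = Truth(labels=labels, subpop_freqs=freqs, admixed=admixed)
    return SyntheticCollection(geno, info, passport, truth, spec=spec)


def apply_sweeps(
    collection: SyntheticCollection, sweeps: list[SweepSpec]
) -> SyntheticCollection:
    """Overlay sweep windows: shift the two designated subpopulations'
    frequencies inside each window (clipped to [0,1]) and regenerate the
    affected loci's genotypes; loci outside the windows are untouched."""
    if not sweeps:
        return collection
    spec = collection.spec
    if spec is None:
        raise ValueError("collection lacks its generating spec")
    info = collection.marker_info
    freqs = collection.truth.subpop_freqs.copy()
    dosage = collection.geno.dosage.copy()
    labels = collection.truth.labels
    known_chroms = set(info["chrom"].unique())

    for si, sw in enumerate(sweeps):
        if sw.chrom not in known_chroms:
            raise ValueError(f"sweep chromosome {sw.chrom!r} not in the collection")
        if max(sw.pop_up, sw.pop_down) >= spec.n_subpops:
            raise ValueError("sweep subpopulation index out of range")
        bp = info["bp"].to_numpy(dtype=float)
        in_win = (
            (info["chrom"] == sw.chrom).to_numpy()
            & (bp >= sw.window_start_bp)
            & (bp < sw.window_end_bp)
        )
        idx = np.flatnonzero(in_win)
        if idx.size == 0:
            continue
        freqs[sw.pop_up, idx] = np.clip(freqs[sw.pop_up, idx] + sw.freq_shift, 0.0, 1.0)
        freqs[sw.pop_down, idx] = np.clip(freqs[sw.pop_down, idx] - sw.freq_shift, 0.0, 1.0)

        rng = np.random.default_rng([spec.seed, 104729, si])
        new = rng.binomial(2, freqs[labels][:, idx]).astype(np.float64)
        if spec.missing_rate > 0:
            new[rng.random(new.shape) < spec.missing_rate] = np.nan
        dosage[:, idx] = new

    geno = GenotypeMatrix(list(collection.geno.samples), list(collection.geno.markers), dosage)
    truth = replace(
        collection.truth,
        subpop_freqs=freqs,
        sweeps=list(collection.truth.sweeps) + list(sweeps),
    )
    return SyntheticCollection(
        geno, info, collection.passport, truth, presence=collection.presence, spec=spec
    )


def simulate_presence_absence(
    spec: PopulationSpec, presence_prob_per_subpop
) -> PresenceMatrix:
    """SilicoDArT-style dominant markers: Bernoulli presence per locus with a
    subpopulation-specific probability, missing MCAR at the spec's rate.

    ``presence_prob_per_subpop`` is broadcastable to (K, L): a scalar, a
    length-K vector, or a full K x L array.
    """
    rng = np.random.default_rng([spec.seed, 15485863])
    k, L = spec.n_subpops, spec.n_loci
    prob = np.asarray(presence_prob_per_subpop, dtype=float)
    if prob.ndim == 1 and prob.shape[0] == k:
        prob = prob[:, None]
    prob = np.broadcast_to(prob, (k, L))
    if (prob < 0).any() or (prob > 1).any():
        raise ValueError("presence probabilities must be in [0, 1]")

    labels = np.repeat(np.arange(k), spec.samples_per_subpop)
    n = labels.size
    pres = (rng.random((n, L)) < prob[labels]).astype(np.float64)
    if spec.missing_rate > 0:
        pres[rng.random((n, L)) < spec.missing_rate] = np.nan
    sample_ids = [f"ACC{idx:05d}" for idx in range(n)]
    marker_ids = [f"SIL{j:05d}" for j in range(L)]
    return PresenceMatrix(sample_ids, marker_ids, pres)


def simulate_linkage_maps(
    true_map: pd.DataFrame,
    n_populations: int,
    subsample_fraction: float = 0.7,
    distortion_scale: float = 0.1,
    noise_sd_cM: float = 0.5,
    seed: int = 0,
) -> tuple[list[LinkageGroupMap], list[str]]:
    """Per-population maps distorting a shared true order.

    ``true_map`` has marker-id index and columns ``chrom`` and ``cM`` with
    unique, sorted positions per chromosome. Each population receives, per
    chromosome, a random marker subset placed at ``a*x + b + eps`` with
    ``a = exp(N(0, distortion_scale))`` (positive, near 1), ``b`` uniform on
    [0, 10], and ``eps ~ N(0, noise_sd_cM^2)``. Subsets are forced to hold
    at least 3 markers per chromosome when the fraction permits; otherwise a
    warning string is emitted for that group.
    """
    if not {"chrom", "cM"}.issubset(true_map.columns):
        raise ValueError("true_map needs 'chrom' and 'cM' columns")
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValueError("subsample_fraction must be in (0, 1]")
    for chrom, grp in true_map.groupby("chrom", observed=True):
        pos = grp["cM"].to_numpy(dtype=float)
        if len(np.unique(pos)) != len(pos) or not np.all(np.diff(np.sort(pos)) > 0):
            raise ValueError(f"true_map positions on {chrom} must be unique")

    rng = np.random.default_rng(seed)
    maps: list[LinkageGroupMap] = []
    warnings: list[str] = []
    for p in range(n_populations):
        pop_id = f"POP{p:02d}"
        for chrom, grp in true_map.groupby("chrom", observed=True, sort=True):
            m_ids = list(grp.index)
            pos = grp["cM"].to_numpy(dtype=float)
            n_take = int(round(subsample_fraction * len(m_ids)))
            n_take = min(len(m_ids), max(n_take, 3))
            if n_take > len(m_ids):  # unreachable after min(); kept for clarity
                n_take = len(m_ids)
            if len(m_ids) < 3 or n_take < 3:
                warnings.append(f"{pop_id}/{chrom}: fewer than 3 markers available")
            take = np.sort(rng.choice(len(m_ids), size=n_take, replace=False))
            a = float(np.exp(rng.normal(0.0, distortion_scale)))
            b = float(rng.uniform(0.0, 10.0))
            eps = rng.normal(0.0, noise_sd_cM, size=n_take) if noise_sd_cM > 0 else 0.0
            maps.append(
                LinkageGroupMap(
                    population=pop_id,
                    chrom=str(chrom),
                    markers=[m_ids[i] for i in take],
                    positions=a * pos[take] + b + eps,
                )
            )
    return maps, warnings


def inject_misclassified_ploidy(
    collection: SyntheticCollection, fraction: float, seed: int = 0
) -> SyntheticCollection:
    """Flip the declared ploidy of a random sample fraction so their passport
    conflicts with their D-genome marker fraction; truth records their ids.

    Hexaploid-declared samples become 'tetraploid' and vice versa; the
    genotypes themselves are untouched, so the conflict is purely a passport
    error — exactly what genome-fraction QC is meant to catch.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    if not (collection.marker_info["genome"] == "D").any():
        raise ValueError("registry has no D-genome markers; ploidy QC undefined")
    n = collection.geno.n_samples
    n_flip = int(round(fraction * n))
    rng = np.random.default_rng([seed, 32452843])
    flip_idx = np.sort(rng.choice(n, size=n_flip, replace=False)) if n_flip else np.array([], dtype=int)

    passport = collection.passport.copy()
    flipped_ids = [collection.geno.samples[i] for i in flip_idx]
    swap = {"hexaploid": "tetraploid", "tetraploid": "hexaploid"}
    for sid in flipped_ids:
        cur = passport.at[sid, "ploidy"]
        passport.at[sid, "ploidy"] = swap.get(cur, "hexaploid")

    truth = replace(collection.truth, misclassified=flipped_ids)
    return SyntheticCollection(
        collection.geno,
        collection.marker_info,
        passport,
        truth,
        presence=collection.presence,
        spec=collection.spec,
    )
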