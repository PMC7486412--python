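# Methods

`germdiv` implements the statistical machinery of a genebank-scale germplasm
diversity analysis for wheat and its wild relatives, together with a
synthetic-data generator that gives every stage a ground truth to recover.
This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic validation does and does not
demonstrate.

## Data model

Genotypes are biallelic SNP dosages (0/1/2 count of the alternate allele,
NaN for missing) in a samples x loci matrix. Dominant SilicoDArT-style
markers are presence/absence (1/0/NaN). Marker metadata carries chromosome,
genome class (A/B/D for bread wheat's three subgenomes, `other` otherwise),
1-based bp position and cM position; passports carry taxon, biological
status, country and declared ploidy. Missing calls are distinct from 0 at
every layer because both the MAF filter and the missing-rate filters depend
on the distinction. Heterozygote phase is ignored throughout.

## Cleaning filters

The SNP cleaning order is fixed: (1) drop markers with missing fraction
> 0.50; (2) drop markers with MAF <= 0.001 (MAF on non-missing calls; the
keep-rule is strictly `MAF > 0.001`, so a marker at exactly 0.001 is
discarded); (3) drop samples with missing fraction > 0.50 (domesticated
wheat) or > 0.75 (wild relatives, whose divergence from the reference
marker panel inflates apparent missingness). SilicoDArT markers are kept at
missing fraction <= 0.80 — dominant markers tolerate a much looser call
threshold because an absent fragment is itself informative. Swapping the
marker/sample order can change the result; the reports record the order
used. A genotyping-stage pre-filter on a replicate-concordance
(reproducibility >= 0.95) column is available for datasets that carry one.

## Diversity indices

For alternate-allele frequency p at a biallelic locus:
he = 1 - p² - (1-p)² = 2p(1-p) (expected heterozygosity, max 0.5 at
p = 0.5; 2·he rescales to [0,1]); ho = heterozygotes / called samples;
f = 1 - ho/he (undefined at he = 0 — such loci are excluded from the f
average, with counts reported); sh = -p log₂ p - (1-p) log₂ (1-p) with the
0·log 0 := 0 convention (max 1.0 at p = 0.5). Averages are over loci with
defined values only.

## Distances

The modified Rogers distance between individuals x and y is the Euclidean
distance between their per-locus frequency vectors (d/2, 1-d/2) scaled by
1/√(2L), which is bounded on [0,1] and attains 1 only for opposite fixed
homozygotes at every locus. Under missing data each pair uses its
pairwise-complete loci L_xy with 1/√(2·L_xy) rescaling — unbiased when
missingness is completely at random, and identical to the complete-data
formula when nothing is missing. Pairs below `min_overlap` (default 10)
complete loci are flagged missing rather than guessed; downstream
embedding/clustering refuses matrices with missing pairs and says why.

The Jaccard similarity for presence/absence data is
n_pp / (n_pp + n_ap + n_pa) over pairwise-complete loci: joint absences
carry no signal for dominant markers and are excluded from both numerator
and denominator. As printed this is a similarity (1 for identical
profiles); the distance form 1 - s is what clustering and MDS consume.
Pairs where both profiles are entirely absent have an empty denominator and
are flagged.

## Embeddings

Classical (Torgerson) MDS double-centers the squared distance matrix
(B = -½ J D² J) and takes the top three eigenpairs; negative eigenvalues —
the signature of non-Euclidean input such as Jaccard distances — are
truncated at zero and counted in the output. SMACOF refines any starting
configuration by Guttman-transform majorization of the raw stress
Σ_{i<j} (d_ij - d̂_ij)²; each iteration provably does not increase stress,
and the implementation exposes the per-iteration stress sequence so the
guarantee is testable. Defaults: init from the classical solution,
relative stress tolerance 1e-6, 300 iterations cap, seeded random init as
fallback. Pairwise distances of configurations are computed by direct
coordinate differencing (not the Gram-matrix expansion, which loses ~half
the significant digits to cancellation and broke exact-recovery checks at
the 1e-9 level).

## Clustering and level selection

Agglomerative clustering runs on the full distance matrix via the
Lance-Williams recurrence (scipy), Ward by default — Ward is the linkage
the core-subset method prescribes, and a single consistent default beats a
per-stage zoo; average/complete/single are available. The merge tree is
kept whole so any level k can be inspected; partitions are nested by
construction and this is asserted in tests.

Level quality is the pseudo-F (Calinski-Harabasz) statistic computed
directly from distances: W = Σ_c (1/n_c) Σ_{i<j∈c} d²_ij,
T = (1/n) Σ_{i<j} d²_ij, B = T - W, F(k) = (B/(k-1)) / (W/(n-k)). On
Euclidean distances this equals the coordinate-based variance ratio exactly
(cross-checked against scikit-learn to 1e-9); on arbitrary distance
matrices it needs no embedding at all. W = 0 (perfectly tight clusters) is
reported as infinity rather than an error. The profile reports the global
maximum and all local maxima; choosing k is left to the analyst — on
real collections that choice mixes statistics with curatorial judgment, so
the package never auto-commits.

## Differentiation

Nei's diversity partition per locus: H_S is the average within-group
expected heterozygosity, H_T the heterozygosity of the pooled frequency,
D_ST = H_T - H_S >= 0 (Jensen), F_ST = D_ST/H_T (undefined and flagged when
H_T = 0). Group pooling defaults to the plain unweighted average of group
frequencies, matching the "average value" reading of the defining
equations; size-weighted pooling is an option. The global FST over loci is
the ratio of sums Σ D_ST / Σ H_T, with the mean per-locus FST as a
secondary summary. This package implements Nei's estimator throughout —
not Weir-Cockerham — and the windowed scans aggregate the same way
(ratio of sums within the window), so windows and the global value are
mutually consistent by construction.

Significance uses label permutations (default 1000): group assignments are
shuffled with sizes preserved, the global FST recomputed, and the observed
value compared with the 90th/95th null percentiles; the p-value is the
add-one estimator (#{null >= obs} + 1)/(B + 1), which is exact under
exchangeability. Windows are fixed, non-overlapping, 0-based half-open
[mW, (m+1)W) with W = 1 Mb by default; loci without a bp position are
excluded and counted. The footprint scan walks the cluster tree from the
root split down, computing a windowed FST between the two daughter groups
of each split and ranking windows; daughters with fewer than two samples
are skipped.

AMOVA supports three marker-informativeness modes because a marker set
that is polymorphic across all groups pooled differs from one polymorphic
within each pair, or within every group: `all_informative` (polymorphic in
the pooled sample), `pair_informative` (per pair, polymorphic in that
pair's pooled sample — one table per pair), `common_informative`
(polymorphic within every group).

## Core subsets (D-method)

Target size is round(fraction·n) with fraction defaulting to 0.20. Ward
strata on MRD (count chosen by the pseudo-F global maximum unless fixed);
each stratum receives slots proportional to its mean within-cluster MRD
d_k — diversity-proportional, not size-proportional, which is the point of
the D-method. Integerization is largest-remainder so the total is hit
exactly; floors (1 per non-empty cluster) and caps (cluster size) are
enforced by redistributing along remainder order. If every d_k is zero the
allocation falls back to size-proportional shares and says so. 1000
stratified candidates are drawn without replacement per stratum; the
candidate with the maximum mean within-candidate pairwise distance wins,
ties to the first drawn. The "average distance" score is read as mean
pairwise distance within the candidate (the alternative — mean distance to
the remainder — is exposed as nothing more than a different score
function the caller can apply to the same candidates). Diagnostics compare
he, 2he, ho, f, sh and the fraction of segregating alleles retained.

## Consensus maps

Per chromosome, pending linkage groups are joined to a seed map
iteratively: a group is eligible when it shares >= 3 markers with the
current consensus and those shared positions have nonzero variance;
commonality = r × ln(n_common) with r the Pearson correlation of shared
positions (Spearman optional). The eligible group with the highest score
joins if r > 0.5, by linear interpolation: shared markers are anchors and
never move; new markers interpolate between flanking anchors in the
group's coordinate system, or extrapolate from the two nearest anchors
beyond the ends (so positions can go negative; a shift-to-zero pass is
optional). Groups failing the gate are removed permanently and logged —
a retry-after-growth mode is deliberately not the default, matching the
remove-and-repeat loop structure. Score ties break by population id.
The log base in the commonality score only rescales it monotonically, and
ranking is its sole use, so natural log is used. Coincident anchors
bracketing a new marker yield the midpoint of their consensus positions.

## Synthetic collections

The generator is the package's test surface, emulating the features the
pipeline must detect:

- **Structure**: K subpopulations under the Balding-Nichols model — the
  subpopulation frequency at a locus with ancestral frequency p is
  Beta(p(1-F)/F, (1-p)(1-F)/F). This model was chosen because it gives a
  closed-form expectation for the equal-weight Nei FST:
  E[F_ST] → F(K-1)/(K-F) as L grows (for K=3, F=0.2: 0.1429), making
  parameter recovery a sharp oracle. Ancestral frequencies are uniform on
  (0.1, 0.9) by default so most loci are informative. Dosages are
  Binomial(2, p_k).
- **Missingness**: completely at random at a specified rate — the simplest
  mechanism consistent with marginal missing-rate filters.
- **Sweeps**: a window on one chromosome where two designated
  subpopulations' frequencies are shifted by ±s (clipped to [0,1]) and
  genotypes regenerated; windowed FST inside the window rises accordingly
  while loci outside are untouched bit-for-bit.
- **Ploidy misclassification**: a sample fraction gets its declared
  passport ploidy flipped, so the D-genome marker fraction (about 1/3
  under the default 1A/1B/1D chromosome cycle) conflicts with the
  passport. Genotypes are untouched: the error is purely clerical, exactly
  what genome-fraction QC targets, and recovery is deterministic.
- **Linkage maps**: per-population maps take a random marker subset of a
  true map and place it at a·x + b + ε with a = exp(N(0, scale)) (positive,
  near 1), b uniform on [0, 10] cM, ε ~ N(0, noise²) — an affine distortion
  plus local noise, the regime the interpolation-based merge assumes.
- **Admixture**: an optional sample fraction drawn from 50/50 two-parent
  frequency mixtures, the minimal structure that blurs MDS/cluster
  boundaries.

Loci are placed uniformly on 100-Mb pseudo-chromosomes and sorted, so 1-Mb
windows hold ~L/(100·n_chrom) loci at desk scale. Chromosomes cycle
through A, B, D genome classes (1A, 1B, 1D, 2A, ...). Everything is
deterministic given the spec and seed.

**What passing does not show.** Loci are independent — there is no linkage
disequilibrium, no allele-frequency spectrum realism, no coalescent
genealogy, and missingness is never informative. Sweep windows shift
frequencies directly rather than modelling hitchhiking. Results on this
generator validate the estimators' arithmetic and their ability to recover
parameters under their own assumptions; they do not certify behavior on
real genebank data, where LD, clinal structure and genotyping artifacts
all violate these assumptions to varying degrees.

## Problem sizes and determinism

Validation runs at desk scale: collections of 300-2000 samples and
400-2000 loci, 1000 permutations, 20 seeds for the FST-recovery average,
200 replicates for permutation-test calibration, 10 seeds for sweep
localization, 5 distorted maps of 200 markers for consensus recovery.
These sizes put every stochastic check's sampling noise well inside its
tolerance while keeping the full suite in tens of seconds. All randomness
flows through `numpy.random.default_rng` seeds; identical inputs and seeds
give bit-identical outputs, including the end-to-end core-subset workflow.

## Known limitations

- Clustering delegates to scipy's Lance-Williams implementation, whose
  internal tie-break (not "lowest pair index") decides between exactly
  equal merge candidates; ties have measure zero for continuous distances
  but can occur on tiny hand-built matrices.
- Multi-allelic VCF records are rejected (naming the marker) or split into
  one pseudo-biallelic locus per ALT; the indices and distances are
  defined for the biallelic/binary case only.
- The 60k x 60k out-of-core regime of the original analyses is out of
  contract; the in-memory implementation is comfortable to n ≈ 5000.
- The D-genome fraction denominator is "markers with a genome-class label
  that the sample actually scored" (and, for presence data, scored
  present); datasets whose registries lack genome labels cannot run ploidy
  QC.
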