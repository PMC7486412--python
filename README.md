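# germdiv

Genetic diversity analysis for genebank germplasm collections, built around
the workflow used to characterize wheat (*Triticum*/*Aegilops*) seed-bank
accessions from SNP and SilicoDArT (presence/absence) marker profiles:

- **QC** — marker/sample cleaning filters (missing rate, MAF) and
  genome-fraction ploidy QC that flags accessions whose declared ploidy
  conflicts with their D-subgenome marker fraction;
- **Diversity** — expected/observed heterozygosity (he = 2p(1−p), ho),
  inbreeding coefficient f = 1 − ho/he, base-2 Shannon index;
- **Distances** — modified Rogers distance
  mrd_xy = (2L)^{-1/2} ‖p(x) − p(y)‖₂ for SNPs, Jaccard similarity
  n_pp/(n_pp + n_ap + n_pa) for dominant markers;
- **Structure** — classical (Torgerson) and SMACOF MDS into 3-D, Ward
  hierarchical clustering with a pseudo-F (Calinski–Harabasz) profile over
  levels;
- **Differentiation** — Nei's partition H_T, H_S, D_ST = H_T − H_S,
  F_ST = D_ST/H_T per locus and globally (ratio of sums), permutation
  significance, 1-Mb windowed scans, and per-cluster-split
  selection-footprint scans; AMOVA under three marker-informativeness
  modes;
- **Core subsets** — the D-method: Ward strata, allocation proportional to
  within-cluster mean MRD, 1000 stratified candidates, max-average-distance
  selection, diversity diagnostics;
- **Consensus maps** — iterative merging of per-population linkage maps by
  commonality score r·ln(n_common) with an r > 0.5 gate and
  anchor-interpolated positions;
- **Synthetic data** — structured collections with known truth
  (Balding–Nichols drift, sweeps, ploidy misclassification, distorted
  linkage maps) so every stage is testable end to end.

File formats: VCF (GT), PLINK-style ped/map, dosage CSV, passport CSV,
4-column linkage maps, square distance TSV, and CurlyWhirly 3-D coordinate
files.

## Worked example

Simulate a structured collection of 3 × 100 accessions with drift F = 0.2,
then recover the differentiation it was built with:

```python
import germdiv as gd

spec = gd.PopulationSpec(n_subpops=3, samples_per_subpop=[100]*3,
                         n_loci=2000, drift_f=0.2, seed=1)
coll = gd.simulate_structured_snps(spec)

fst, _ = gd.global_fst(gd.fst_table(coll.geno, coll.labels))
print(f"global Nei FST = {fst:.4f}")        # -> global Nei FST = 0.1426

D = gd.mrd_matrix(coll.geno)
tree = gd.hierarchical_tree(D)
from germdiv.structure import pseudo_f_profile
print(pseudo_f_profile(D, tree, k_max=10).selected_k)   # -> 3

core, diag = gd.build_core(coll.geno, D, fraction=0.20, seed=1)
print(len(core.selected))                    # -> 60  (exactly 20% of 300)
print(round(diag.loc["he", "full"], 4), round(diag.loc["he", "core"], 4))
# -> 0.3621 0.361
```

The recovered FST (0.1426) matches the Balding–Nichols closed form
F(K−1)/(K−F) = 0.1429 for K = 3, F = 0.2; the pseudo-F profile peaks at the
true number of subpopulations; and the 20% D-method core reproduces the
full collection's expected heterozygosity to the third decimal.

The same workflow is scripted as a narrative analysis under `analysis/`
(`01_simulate.py` … `06_consensus_map.py`), each step printing what it
found and writing its tables under `results/`. A `germdiv` CLI wraps the
library for shell use (`germdiv simulate`, `filter`, `ploidy-qc`,
`diversity`, `distance`, `mds`, `cluster`, `fst-scan`, `core`,
`consensus-map`).

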