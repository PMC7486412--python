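"""Generate the synthetic study collection used by the downstream analyses.

A structured 'genebank' of 4 subpopulations x 200 accessions genotyped at
2,000 SNP loci on three pseudo-chromosomes (1A, 1B, 1D), with 5% missing
calls, Balding-Nichols drift F = 0.12, one injected selection-footprint
window on 1A, and 3% of accessions given a wrong declared ploidy. The raw
VCF, map, passport and truth files are bulky, so they land under
scratch/simulated/; downstream steps rebuild the collection in memory from
the same spec.
"""

from pathlib import Path

import germdiv as gd
from germdiv import geno_io

OUT = Path(__file__).resolve().parent.parent / "scratch" / "simulated"
SEED = 2024

spec = gd.PopulationSpec(
    n_subpops=4,
    samples_per_subpop=[200] * 4,
    n_loci=2000,
    drift_f=0.12,
    missing_rate=0.05,
    seed=SEED,
)
SWEEP = gd.SweepSpec("1A", 40_000_000, 41_000_000, freq_shift=0.4,
                     pop_up=0, pop_down=1)


def build_collection() -> gd.SyntheticCollection:
    coll = gd.simulate_structured_snps(spec)
    coll = gd.apply_sweeps(coll, [SWEEP])
    coll = gd.inject_misclassified_ploidy(coll, fraction=0.03, seed=SEED)
    return coll


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    coll = build_collection()
    geno_io.write_vcf(OUT / "collection.vcf", coll.geno, coll.marker_info)
    geno_io.write_linkage_map(OUT / "collection.map", coll.marker_info)
    geno_io.write_passport_csv(OUT / "collection.passport.csv", coll.passport)
    geno_io.write_truth_json(OUT / "collection.truth.json", coll)
    print(
        f"simulated {coll.geno.n_samples} accessions x {coll.geno.n_markers} loci; "
        f"sweep on {SWEEP.chrom} [{SWEEP.window_start_bp:,}, {SWEEP.window_end_bp:,}); "
        f"{len(coll.truth.misclassified)} accessions with wrong declared ploidy"
    )


if __name__ == "__main__":
    main()
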