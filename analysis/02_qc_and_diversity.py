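"""Clean the simulated collection, run ploidy QC, and summarize diversity.

Applies the fixed cleaning order (marker missing <= 0.50, MAF > 0.001, then
sample missing <= 0.50), flags accessions whose declared ploidy conflicts
with their D-genome marker fraction, and tabulates he / 2he / ho / f / sh.
Writes results/qc_report.json, results/ploidy_flags.tsv and
results/diversity.tsv.
"""

import importlib.util
import json
import sys
from pathlib import Path

import germdiv as gd
from germdiv import qc

HERE = Path(__file__).resolve().parent
RESULTS = HERE.parent / "results"

_sim = importlib.util.spec_from_file_location("sim01", HERE / "01_simulate.py")
sim01 = importlib.util.module_from_spec(_sim)
_sim.loader.exec_module(sim01)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    coll = sim01.build_collection()

    clean, reports = qc.clean_pipeline(coll.geno)
    payload = [
        {"axis": r.axis, "n_in": r.n_in, "n_out": r.n_out,
         "removed_by_rule": r.removed_by_rule, "thresholds": r.thresholds}
        for r in reports
    ]
    (RESULTS / "qc_report.json").write_text(json.dumps(payload, indent=1))
    print(f"markers {reports[0].n_in} -> {reports[0].n_out}; "
          f"samples {reports[1].n_in} -> {reports[1].n_out}")

    fracs = qc.genome_fractions(coll.geno, coll.marker_info)
    flags = qc.classify_ploidy(fracs, coll.passport["ploidy"])
    flags[flags["flag"] != "consistent"].round(4).to_csv(
        RESULTS / "ploidy_flags.tsv", sep="\t")
    flagged = set(flags.index[flags["flag"] != "consistent"])
    truth = set(coll.truth.misclassified)
    print(f"ploidy QC flagged {len(flagged)} accessions; "
          f"truth has {len(truth)}; exact recovery: {flagged == truth}")

    summary = gd.diversity_summary(clean)
    summary.to_csv(RESULTS / "diversity.tsv", sep="\t")
    print(summary.round(4).to_string())


if __name__ == "__main__":
    main()
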