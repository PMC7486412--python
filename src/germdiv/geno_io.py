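"""Readers and writers for the formats the pipeline touches.

VCF (GT-only, 4.x) is read through cyvcf2 and written as plain VCF text;
PLINK-style .ped/.map, delimited dosage CSV, passport CSV, 4-column linkage
maps, square distance-matrix TSV, and CurlyWhirly 3-D coordinate files are
handled with pandas. bp positions are 1-based at every file boundary (the
window arithmetic converts internally); missing dosage is kept distinct from
0 at every layer; heterozygote phase is ignored (0/1 == 1/0 == 0|1).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .consmap import LinkageGroupMap
from .datatypes import (
    BIOLOGICAL_STATUSES,
    GenotypeMatrix,
    make_marker_info,
    make_passport,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- VCF

def read_vcf(path, multiallelic: str = "error") -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF with GT fields into dosages (alt-allele counts).

    "./." becomes missing. Records with more than one ALT allele raise a
    ParseError naming the marker under ``multiallelic='error'`` (default),
    or are split into one biallelic locus per ALT under ``'split'``.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("error", "split"):
        raise ValueError("multiallelic must be 'error' or 'split'")
    try:
        vcf = VCF(str(path))
    except Exception as e:  # cyvcf2 raises bare exceptions on bad headers
        raise ParseError(f"{path}: malformed VCF header: {e}") from e
    samples = list(vcf.samples)
    marker_ids, chroms, bps, cols = [], [], [], []
    for rec_no, var in enumerate(vcf, start=1):
        vid = var.ID or f"{var.CHROM}_{var.POS}"
        alts = var.ALT or []
        if len(alts) > 1 and multiallelic == "error":
            raise ParseError(
                f"{path}: record {rec_no} (marker {vid}) is multi-allelic "
                f"({len(alts)} ALT alleles); rerun with multiallelic='split'"
            )
        gts = var.genotypes  # [allele1, allele2, phased] per sample
        for t in range(max(len(alts), 1)):
            dos = np.full(len(samples), np.nan)
            for si, g in enumerate(gts):
                a = [x for x in g[:-1] if x is not None]
                if not a or min(a) < 0:
                    continue
                dos[si] = sum(1 for x in a if x == t + 1)
            marker_ids.append(vid if len(alts) <= 1 else f"{vid}_alt{t + 1}")
            chroms.append(var.CHROM)
            bps.append(var.POS)
            cols.append(dos)
    if not marker_ids:
        raise ParseError(f"{path}: no variant records")
    dosage = np.column_stack(cols)
    info = make_marker_info(marker_ids, chroms, bp=bps)
    return GenotypeMatrix(samples, marker_ids, dosage), info


def write_vcf(path, geno: GenotypeMatrix, marker_info: pd.DataFrame | None = None) -> None:
    """Write dosages as a GT-only VCF 4.2 text file (REF=A, ALT=T
    placeholders). Positions/chromosomes come from ``marker_info``; markers
    without a registry entry get chromosome 'un' and a running position."""
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    if marker_info is not None:
        for c in pd.unique(marker_info.reindex(geno.markers)["chrom"].dropna()):
            lines.append(f"##contig=<ID={c}>")
    else:
        lines.append("##contig=<ID=un>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.samples))
    for j, m in enumerate(geno.markers):
        chrom, pos = "un", j + 1
        if marker_info is not None and m in marker_info.index:
            row = marker_info.loc[m]
            chrom = row["chrom"] if pd.notna(row["chrom"]) else "un"
            pos = int(row["bp"]) if pd.notna(row["bp"]) else j + 1
        gts = "\t".join(
            "./." if np.isnan(d) else gt_of[d] for d in geno.dosage[:, j]
        )
        lines.append(f"{chrom}\t{pos}\t{m}\tA\tT\t.\t.\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- PLINK ped/map

def read_plink_like(ped_path, map_path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a PLINK-style .ped/.map pair.

    Dosage counts the minor allele per marker (major allele = most frequent,
    ties broken alphabetically); '0' alleles are missing. The .map file is
    whitespace-delimited chrom, id, cM, bp; bp <= 0 or '.' is treated as
    absent, as is cM '.' or a missing column.
    """
    info = read_linkage_map(map_path)
    markers = list(info.index)
    rows, sample_ids = [], []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * len(markers):
            raise ParseError(
                f"{ped_path}:{ln}: expected {6 + 2 * len(markers)} fields "
                f"(6 + 2 x {len(markers)} markers), found {len(parts)}"
            )
        sample_ids.append(parts[1])
        rows.append(parts[6:])
    if not rows:
        raise ParseError(f"{ped_path}: no samples")
    alleles = np.array(rows).reshape(len(rows), len(markers), 2)
    dosage = np.full((len(rows), len(markers)), np.nan)
    for j in range(len(markers)):
        a = alleles[:, j, :]
        called = a != "0"
        seen, counts = np.unique(a[called], return_counts=True)
        if seen.size == 0:
            continue
        if seen.size > 2:
            raise ParseError(f"{ped_path}: marker {markers[j]} has >2 alleles")
        order = np.lexsort((seen, -counts))  # most frequent first, ties alphabetic
        major = seen[order[0]]
        both = called.all(axis=1)
        dosage[both, j] = (a[both] != major).sum(axis=1)
    return GenotypeMatrix(sample_ids, markers, dosage), info


# ---------------------------------------------------------------- dosage CSV

def read_dosage_csv(path) -> GenotypeMatrix:
    """Delimited dosage table: first column sample id, one column per marker,
    entries 0/1/2 or empty/NA for missing."""
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicated sample or marker ids")
    vals = df.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: dosage outside {{0,1,2,NA}} at sample {df.index[i]!r}, "
            f"marker {df.columns[j]!r}: {vals[i, j]!r}"
        )
    return GenotypeMatrix([str(s) for s in df.index], [str(m) for m in df.columns], vals)


def write_dosage_csv(path, geno: GenotypeMatrix) -> None:
    df = pd.DataFrame(geno.dosage, index=geno.samples, columns=geno.markers)
    df.index.name = "sample"
    # integers where called, empty where missing
    df = df.astype("Int64")
    df.to_csv(path)


# ---------------------------------------------------------------- passport CSV

def read_passport_csv(path) -> pd.DataFrame:
    """Passport CSV with columns accession, taxon, status, country, ploidy.
    Unlisted biological-status strings map to 'unknown' (warning logged)."""
    df = pd.read_csv(path, dtype=str).fillna("unknown")
    cols = {c.lower(): c for c in df.columns}
    if "accession" not in cols:
        raise ParseError(f"{path}: missing 'accession' column")
    def col(name, default):
        return df[cols[name]] if name in cols else pd.Series([default] * len(df))
    status_raw = col("status", "unknown")
    unknown = ~status_raw.isin(BIOLOGICAL_STATUSES)
    if unknown.any():
        for s in sorted(set(status_raw[unknown])):
            logger.warning("passport status %r not recognized; using 'unknown'", s)
    return make_passport(
        list(df[cols["accession"]]),
        taxon=list(col("taxon", "unknown")),
        status=list(status_raw.where(~unknown, "unknown")),
        country=list(col("country", "unknown")),
        ploidy=list(col("ploidy", "hexaploid")),
    )


def write_passport_csv(path, passport: pd.DataFrame) -> None:
    passport.to_csv(path)


# ---------------------------------------------------------------- linkage maps

def read_linkage_map(path) -> pd.DataFrame:
    """PLINK-convention 4-column map: chrom, marker id, cM, bp (whitespace
    delimited, no header). Returns a marker-indexed frame with chrom, cM
    (NaN when absent) and bp (<NA> when '.', missing, or <= 0)."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise ParseError(f"{path}:{ln}: expected 3 or 4 columns, found {len(parts)}")
        chrom, mid, cm = parts[0], parts[1], parts[2]
        bp = parts[3] if len(parts) == 4 else "."
        cm_val = np.nan if cm in (".", "") else float(cm)
        bp_val = None if bp in (".", "") else int(bp)
        if bp_val is not None and bp_val <= 0:
            bp_val = None
        rows.append((mid, chrom, cm_val, bp_val))
    if not rows:
        raise ParseError(f"{path}: empty map file")
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicated marker ids")
    return make_marker_info(
        ids,
        [r[1] for r in rows],
        bp=[r[3] for r in rows],
        cM=[r[2] for r in rows],
    )


def write_linkage_map(path, info: pd.DataFrame) -> None:
    lines = []
    for mid, row in info.iterrows():
        cm = "." if pd.isna(row.get("cM")) else f"{float(row['cM']):.6f}"
        bp = "." if pd.isna(row.get("bp")) else str(int(row["bp"]))
        lines.append(f"{row['chrom']}\t{mid}\t{cm}\t{bp}")
    Path(path).write_text("\n".join(lines) + "\n")


def map_to_linkage_groups(info: pd.DataFrame, population: str = "map") -> list[LinkageGroupMap]:
    """Split a marker-indexed map frame into one LinkageGroupMap per
    chromosome (markers without a cM position are dropped)."""
    groups = []
    ok = info[info["cM"].notna()]
    for chrom, grp in ok.groupby("chrom", observed=True, sort=True):
        groups.append(
            LinkageGroupMap(
                population=population,
                chrom=str(chrom),
                markers=list(grp.index),
                positions=grp["cM"].to_numpy(dtype=float),
            )
        )
    return groups


# ---------------------------------------------------------------- distance TSV

def write_distance_matrix(path, D) -> None:
    pd.DataFrame(D.values, index=D.ids, columns=D.ids).to_csv(path, sep="\t")


def read_distance_matrix(path, metric: str = "MRD"):
    from .datatypes import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column ids disagree")
    return DistanceMatrix([str(i) for i in df.index], df.to_numpy(dtype=float), metric)


# ---------------------------------------------------------------- CurlyWhirly

def write_curlywhirly(path, coords: pd.DataFrame, categories: pd.DataFrame | None = None) -> None:
    """CurlyWhirly 3-D coordinate text: tab-delimited with category columns
    prefixed 'categories:', then the label column, then the axis columns.
    Coordinates must be finite."""
    if coords.isna().any().any() or not np.isfinite(coords.to_numpy(dtype=float)).all():
        raise ValueError("CurlyWhirly coordinates must be finite")
    if categories is not None and len(categories) != len(coords):
        raise ValueError("one category row per sample required")
    header = []
    cols = []
    if categories is not None:
        for c in categories.columns:
            header.append(f"categories:{c}")
            cols.append(categories[c].astype(str).to_numpy())
    header.append("label")
    cols.append(np.asarray([str(i) for i in coords.index]))
    for c in coords.columns:
        header.append(str(c))
        cols.append(np.array([format(v, ".15g") for v in coords[c]]))
    lines = ["\t".join(header)]
    for i in range(len(coords)):
        lines.append("\t".join(col[i] for col in cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_curlywhirly(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of write_curlywhirly: returns (coords, categories)."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    cat_cols = [h.split(":", 1)[1] for h in header if h.startswith("categories:")]
    n_cat = len(cat_cols)
    if header[n_cat] != "label":
        raise ParseError(f"{path}: expected 'label' column after categories")
    axis_cols = header[n_cat + 1 :]
    rows = [ln.split("\t") for ln in lines[1:] if ln.strip()]
    labels = [r[n_cat] for r in rows]
    coords = pd.DataFrame(
        [[float(v) for v in r[n_cat + 1 :]] for r in rows],
        index=labels,
        columns=axis_cols,
    )
    cats = pd.DataFrame(
        [r[:n_cat] for r in rows], index=labels, columns=cat_cols
    )
    return coords, cats


# ---------------------------------------------------------------- truth JSON

def write_truth_json(path, collection) -> None:
    import json
    from dataclasses import asdict

    t = collection.truth
    payload = {
        "labels": {s: int(l) for s, l in zip(collection.geno.samples, t.labels)},
        "sweeps": [asdict(s) for s in t.sweeps],
        "misclassified": list(t.misclassified),
        "admixed": {k: list(v) for k, v in t.admixed.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))
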