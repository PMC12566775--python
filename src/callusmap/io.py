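"""Readers and writers for the pipeline's tabular formats.

Conventions: internal coordinates are 0-based half-open; TSV position
columns are presented 1-based (``pos_bp`` columns); BED outputs are 0-based
half-open.  Every table starts with a ``#`` comment line stating units and
coordinate convention, which the readers skip.  Floats are written with
fixed precision so that reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CODE_NA,
    CODE_TO_STR,
    STR_TO_CODE,
    BinMarkerMatrix,
    Chromosome,
    GeneticMap,
    GenotypeMatrix,
    QtlPeak,
    ScanResult,
    SegmentSet,
)

__all__ = [
    "read_genotype_input",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_genotype_vcf",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "read_map_tsv",
    "write_map_tsv",
    "write_segments_bed",
    "read_bins_tsv",
    "write_bins_tsv",
    "read_bulk_counts_tsv",
    "write_bulk_counts_tsv",
    "write_scan_tsv",
    "write_peaks_tsv",
    "write_intervals_bed",
    "write_genes_bed",
    "read_genes_bed",
    "read_deg_tsv",
    "write_deg_tsv",
    "write_table",
    "sha256_of",
]


def write_table(df: pd.DataFrame, path: str | Path, comment: str) -> None:
    """Write a TSV with a leading ``#`` comment naming units/conventions."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def _read_table(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


# ---------------------------------------------------------------------------
# genotype matrices


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": matrix.sites["chrom"],
            "pos_bp": matrix.sites["pos_bp"].astype(np.int64) + 1,
        }
    )
    codes = np.vectorize(CODE_TO_STR.get)(matrix.calls)
    df = pd.concat(
        [df, pd.DataFrame(codes, columns=matrix.individuals)], axis=1
    )
    write_table(
        df,
        path,
        "genotype calls; pos_bp 1-based; AA=A188 hom, BB=B73 hom, AB=het, NA=missing",
    )


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = _read_table(path, dtype={"chrom": str}, keep_default_na=False)
    individuals = [c for c in df.columns if c not in ("chrom", "pos_bp")]
    sites = pd.DataFrame(
        {"chrom": df["chrom"], "pos_bp": df["pos_bp"].astype(np.int64) - 1}
    )
    calls = np.empty((len(df), len(individuals)), dtype=np.int8)
    for j, ind in enumerate(individuals):
        try:
            calls[:, j] = [STR_TO_CODE[v] for v in df[ind]]
        except KeyError as exc:
            raise ValueError(f"unparseable genotype code {exc} in column {ind}") from exc
    return GenotypeMatrix(sites, individuals, calls)


def read_genotype_vcf(
    path: str | Path, parental_sidecar: str | Path | None
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Minimal VCF reader (GT only) with A188/B73 orientation.

    The required sidecar TSV (columns ``chrom, pos_bp`` 1-based,
    ``a188_allele``) states which allele each site inherits from A188.
    Sites with non-biallelic genotypes, absent from the sidecar, or whose
    alleles do not include the A188 allele are skipped and tallied.
    """
    import pysam

    if parental_sidecar is None:
        raise ValueError("parental orientation sidecar is required for VCF input")
    sidecar = _read_table(parental_sidecar, dtype={"chrom": str})
    a188_at = {
        (r.chrom, int(r.pos_bp) - 1): str(r.a188_allele)
        for r in sidecar.itertuples(index=False)
    }

    tally = {"non_biallelic": 0, "no_orientation": 0, "allele_mismatch": 0}
    rows = []
    calls_rows = []
    with pysam.VariantFile(str(path)) as vcf:
        individuals = list(vcf.header.samples)
        for rec in vcf:
            key = (rec.chrom, rec.pos - 1)  # pysam .pos is 1-based
            if key not in a188_at:
                tally["no_orientation"] += 1
                continue
            alleles = [rec.ref] + list(rec.alts or [])
            a188 = a188_at[key]
            if a188 not in alleles:
                tally["allele_mismatch"] += 1
                continue
            a188_idx = alleles.index(a188)
            row = np.full(len(individuals), CODE_NA, dtype=np.int8)
            bad = False
            for j, sample in enumerate(individuals):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                if any(a > 1 for a in gt):
                    bad = True
                    break
                dosage = sum(1 for a in gt if a == a188_idx)
                row[j] = 2 - dosage
            if bad:
                tally["non_biallelic"] += 1
                continue
            rows.append((rec.chrom, rec.pos - 1))
            calls_rows.append(row)
    sites = pd.DataFrame(rows, columns=["chrom", "pos_bp"])
    calls = (
        np.array(calls_rows, dtype=np.int8)
        if calls_rows
        else np.empty((0, len(individuals)), dtype=np.int8)
    )
    return GenotypeMatrix(sites, individuals, calls), tally


def read_genotype_input(
    path: str | Path, fmt: str = "tsv", parental_sidecar: str | Path | None = None
) -> GenotypeMatrix:
    if fmt == "tsv":
        return read_genotype_tsv(path)
    if fmt == "vcf":
        matrix, _ = read_genotype_vcf(path, parental_sidecar)
        return matrix
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# phenotype, map


def write_phenotype_tsv(phenotype: dict[str, int], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "individual": list(phenotype),
            "callus_type": ["TypeII" if v else "TypeI" for v in phenotype.values()],
        }
    )
    write_table(df, path, "binary callus phenotype per individual")


def read_phenotype_tsv(path: str | Path) -> dict[str, int]:
    df = _read_table(path, dtype=str)
    out = {}
    for r in df.itertuples(index=False):
        if r.callus_type not in ("TypeI", "TypeII"):
            raise ValueError(f"unrecognized callus_type {r.callus_type!r}")
        out[r.individual] = 1 if r.callus_type == "TypeII" else 0
    return out


def write_map_tsv(genetic_map: GeneticMap, path: str | Path) -> None:
    rows = []
    for c in genetic_map:
        for bp, cm in zip(c.anchors_bp, c.anchors_cm):
            rows.append((c.name, int(c.length_bp), int(bp) + 1, cm))
    df = pd.DataFrame(rows, columns=["chrom", "length_bp", "anchor_bp", "anchor_cm"])
    write_table(df, path, "genetic map anchors; anchor_bp 1-based; anchor_cm in cM")


def read_map_tsv(path: str | Path) -> GeneticMap:
    df = _read_table(path, dtype={"chrom": str})
    chroms = []
    for name, sub in df.groupby("chrom", sort=False):
        chroms.append(
            Chromosome(
                name=name,
                length_bp=int(sub["length_bp"].iloc[0]),
                anchors_bp=sub["anchor_bp"].to_numpy(float) - 1,
                anchors_cm=sub["anchor_cm"].to_numpy(float),
            )
        )
    return GeneticMap(tuple(chroms))


# ---------------------------------------------------------------------------
# segments, bins


def write_segments_bed(segsets: Sequence[SegmentSet], path: str | Path) -> None:
    rows = []
    for s in segsets:
        for seg in s.segments:
            rows.append(
                (
                    seg.chrom,
                    seg.start_bp,
                    seg.end_bp,
                    CODE_TO_STR[seg.genotype],
                    seg.n_support_snps,
                    s.individual,
                )
            )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "genotype", "n_snps", "individual"]
    )
    write_table(df, path, "per-individual segments; BED-style 0-based half-open bp")


def write_bins_tsv(bins: BinMarkerMatrix, path: str | Path) -> None:
    df = bins.bins.copy()
    for col in ("start_bp", "end_bp", "rep_pos_bp"):
        df[col] = df[col].astype(np.int64) + 1
    df["end_bp"] = df["end_bp"] - 1  # 1-based inclusive presentation
    codes = np.vectorize(CODE_TO_STR.get)(bins.calls)
    df = pd.concat(
        [df, pd.DataFrame(codes, columns=bins.individuals)], axis=1
    )
    write_table(
        df,
        path,
        "bin markers; positions 1-based inclusive; rep_pos_cm in cM; "
        "AA=A188 hom, BB=B73 hom",
    )


def read_bins_tsv(path: str | Path) -> BinMarkerMatrix:
    df = _read_table(path, dtype={"chrom": str}, keep_default_na=False)
    meta_cols = ["chrom", "start_bp", "end_bp", "rep_pos_bp", "rep_pos_cm"]
    individuals = [c for c in df.columns if c not in meta_cols]
    bins = df[meta_cols].copy()
    bins["start_bp"] = bins["start_bp"].astype(np.int64) - 1
    bins["end_bp"] = bins["end_bp"].astype(np.int64)  # inclusive -> half-open
    bins["rep_pos_bp"] = bins["rep_pos_bp"].astype(np.int64) - 1
    bins["rep_pos_cm"] = bins["rep_pos_cm"].astype(float)
    calls = np.empty((len(df), len(individuals)), dtype=np.int8)
    for j, ind in enumerate(individuals):
        calls[:, j] = [STR_TO_CODE[v] for v in df[ind]]
    return BinMarkerMatrix(bins, individuals, calls)


# ---------------------------------------------------------------------------
# bulk counts


def write_bulk_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    df = counts.copy()
    df["pos_bp"] = df["pos_bp"].astype(np.int64) + 1
    write_table(df, path, "bulk allele read counts; pos_bp 1-based")


def read_bulk_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, dtype={"chrom": str})
    df["pos_bp"] = df["pos_bp"].astype(np.int64) - 1
    return df


# ---------------------------------------------------------------------------
# scans, peaks, intervals


def write_scan_tsv(scan: ScanResult, path: str | Path) -> None:
    df = scan.table.copy()
    df["pos_bp"] = df["pos_bp"].astype(np.int64) + 1
    kind = "p-value" if scan.statistic_kind == "pvalue" else "LOD"
    write_table(
        df,
        path,
        f"genome scan ({scan.metadata.get('method', '?')}); statistic = {kind}; "
        "pos_bp 1-based; pos_cm in cM",
    )


def write_peaks_tsv(peaks: Sequence[QtlPeak], path: str | Path) -> None:
    rows = []
    for p in peaks:
        start, end = p.interval_bp if p.interval_bp else (pd.NA, pd.NA)
        rows.append(
            (
                p.name,
                p.chrom,
                p.peak_pos_bp + 1,
                round(p.peak_pos_cm, 4),
                p.lod if p.lod is not None else pd.NA,
                p.pvalue if p.pvalue is not None else pd.NA,
                start + 1 if p.interval_bp else pd.NA,
                end if p.interval_bp else pd.NA,
                p.favorable_allele or "NA",
                p.dominance_call or "NA",
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "qtl",
            "chrom",
            "peak_pos_bp",
            "peak_pos_cm",
            "lod",
            "pvalue",
            "interval_start_bp",
            "interval_end_bp",
            "favorable_allele",
            "dominance_call",
        ],
    )
    write_table(df, path, "QTL peaks; positions 1-based; interval = LOD support")


def write_intervals_bed(peaks: Sequence[QtlPeak], path: str | Path) -> None:
    rows = [
        (p.chrom, p.interval_bp[0], p.interval_bp[1], p.name)
        for p in peaks
        if p.interval_bp
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "qtl"])
    write_table(df, path, "QTL support intervals; BED-style 0-based half-open bp")


# ---------------------------------------------------------------------------
# genes, DEGs


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    df = genes[["chrom", "start_bp", "end_bp", "gene_id"]].rename(
        columns={"start_bp": "start", "end_bp": "end", "gene_id": "name"}
    )
    write_table(df, path, "gene annotation; BED-style 0-based half-open bp")


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, dtype={"chrom": str})
    return df.rename(
        columns={"start": "start_bp", "end": "end_bp", "name": "gene_id"}
    )[["gene_id", "chrom", "start_bp", "end_bp"]]


def write_deg_tsv(deg: pd.DataFrame, path: str | Path) -> None:
    write_table(deg, path, "differentially expressed genes; direction up/down")


def read_deg_tsv(path: str | Path) -> pd.DataFrame:
    return _read_table(path, dtype={"gene_id": str, "direction": str})


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
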