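"""Downstream integration: inbred profiles, candidate genes, expression prep.

Three loosely coupled utilities that sit on top of the mapping results:

* :func:`profile_inbred` re-uses the segment caller on a single (nearly)
  inbred line — e.g. a Hi-II-style highly culturable B73xA188 derivative —
  to report its chromosomal segment genotypes and recombination-breakpoint
  count, and :func:`allele_at_qtl` looks up which parental allele the line
  carries at each QTL peak and whether it is the Type II-favorable one.

* :func:`candidate_genes` intersects QTL support intervals with gene
  annotation and two directed DEG lists (e.g. Type II vs Type I calli and
  fast- vs slow-growing sectors), keeping genes that are differentially
  expressed in both contrasts — by default with concordant direction.

* :func:`standardize_expression` z-scores RPM expression rows (gene-wise
  mean 0, sample standard deviation 1) for heatmap-style reporting;
  zero-variance genes are emitted as all-zero rows and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CODE_NA, CODE_TO_STR, GenotypeMatrix, QtlPeak, SegmentSet
from .binmarkers import DEFAULT_SEGMENT_PARAMS, SegmentParams, call_segments

__all__ = [
    "InbredSegmentProfile",
    "profile_inbred",
    "allele_at_qtl",
    "candidate_genes",
    "standardize_expression",
]


@dataclass
class InbredSegmentProfile:
    """Segment genotypes and breakpoint count of one inbred-derived line."""

    line: str
    segments: SegmentSet
    breakpoint_count: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s.chrom, s.start_bp, s.end_bp, CODE_TO_STR[s.genotype], s.n_support_snps)
            for s in self.segments.segments
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "start_bp", "end_bp", "genotype", "n_support_snps"]
        )


def profile_inbred(
    matrix: GenotypeMatrix,
    line: str,
    params: SegmentParams = DEFAULT_SEGMENT_PARAMS,
) -> InbredSegmentProfile:
    """Segment one line's genotype calls and count recombination breakpoints.

    Residual-heterozygosity segments are retained and reported like any
    other segment.  The breakpoint count is the sum over chromosomes of
    (segments - 1).
    """
    from .binmarkers import count_recombination_events

    segs = call_segments(matrix, line, params)
    return InbredSegmentProfile(line, segs, count_recombination_events(segs))


def allele_at_qtl(
    profile: InbredSegmentProfile, peaks: Sequence[QtlPeak]
) -> pd.DataFrame:
    """Genotype of the line at each QTL peak, annotated favorable/unfavorable.

    A peak is ``favorable`` when the covering segment is homozygous for the
    peak's favorable parental allele, ``unfavorable`` for the opposite
    homozygote, ``het`` for a heterozygous segment, and ``NA`` when the peak
    falls in an uncovered gap (or the peak has no favorable-allele call).
    """
    rows = []
    for p in peaks:
        code = profile.segments.genotype_at(p.chrom, p.peak_pos_bp)
        geno = CODE_TO_STR[code]
        if code == CODE_NA or p.favorable_allele is None:
            status = "NA"
        elif geno == "AB":
            status = "het"
        else:
            carried = "A188" if geno == "AA" else "B73"
            status = "favorable" if carried == p.favorable_allele else "unfavorable"
        rows.append(
            (p.name, p.chrom, p.peak_pos_bp, geno, p.favorable_allele, status)
        )
    return pd.DataFrame(
        rows,
        columns=["qtl", "chrom", "peak_pos_bp", "genotype", "favorable_allele", "status"],
    )


def candidate_genes(
    qtl_intervals: pd.DataFrame,
    genes: pd.DataFrame,
    deg_contrast_1: pd.DataFrame,
    deg_contrast_2: pd.DataFrame,
    require_concordance: bool = True,
    full_containment: bool = False,
) -> pd.DataFrame:
    """DEGs inside QTL intervals, differentially expressed in both contrasts.

    ``qtl_intervals`` columns: ``qtl, chrom, start_bp, end_bp`` (half-open);
    ``genes`` columns: ``gene_id, chrom, start_bp, end_bp``; each DEG frame:
    ``gene_id, direction`` with direction in {up, down}.  A gene qualifies
    iff it overlaps >= 1 interval (any-overlap by default, full containment
    behind the flag), appears in both DEG lists, and — if
    ``require_concordance`` — with the same direction in both.  Output is
    sorted by (qtl, chrom, start_bp); duplicate gene ids are an error.
    """
    dupes = genes["gene_id"][genes["gene_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
    for name, deg in (("contrast 1", deg_contrast_1), ("contrast 2", deg_contrast_2)):
        d = deg["gene_id"][deg["gene_id"].duplicated()].unique()
        if len(d):
            raise ValueError(f"duplicate gene ids in {name}: {sorted(d)}")

    d1 = deg_contrast_1.set_index("gene_id")["direction"]
    d2 = deg_contrast_2.set_index("gene_id")["direction"]

    rows = []
    for itv in qtl_intervals.itertuples(index=False):
        on_chrom = genes[genes["chrom"] == itv.chrom]
        if full_containment:
            hit = on_chrom[
                (on_chrom["start_bp"] >= itv.start_bp)
                & (on_chrom["end_bp"] <= itv.end_bp)
            ]
        else:
            hit = on_chrom[
                (on_chrom["start_bp"] < itv.end_bp)
                & (on_chrom["end_bp"] > itv.start_bp)
            ]
        for g in hit.itertuples(index=False):
            if g.gene_id not in d1.index or g.gene_id not in d2.index:
                continue
            dir1, dir2 = d1[g.gene_id], d2[g.gene_id]
            concordant = dir1 == dir2
            if require_concordance and not concordant:
                continue
            rows.append(
                (
                    g.gene_id,
                    g.chrom,
                    g.start_bp,
                    g.end_bp,
                    itv.qtl,
                    dir1,
                    concordant,
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "chrom",
            "start_bp",
            "end_bp",
            "qtl",
            "direction",
            "concordant_in_both_contrasts",
        ],
    )
    return out.sort_values(["qtl", "chrom", "start_bp"], kind="stable").reset_index(
        drop=True
    )


def standardize_expression(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Gene-wise z-score of an RPM matrix (genes x samples).

    Each row is centred on its mean and divided by its sample standard
    deviation (ddof = 1).  Zero-variance rows become all-zero and are
    flagged.  Returns ``(standardized matrix, zero-variance flags)``.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples to standardize")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[flat] = 0.0
    out = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return out, pd.Series(flat, index=matrix.index, name="zero_variance")
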