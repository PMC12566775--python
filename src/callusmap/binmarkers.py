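"""GBS segment (bin) markers from noisy per-individual SNP calls.

Sparse, error-prone GBS genotype calls are converted into chromosomal
segments — runs of constant genotype bounded by discernible recombination
breakpoints — in three steps per chromosome:

1. a sliding plurality vote of width ``smooth_window`` over the non-missing
   calls (ties keep the original call);
2. run-length encoding of the smoothed calls into candidate segments;
3. absorption of candidates supported by fewer than ``min_snps_per_segment``
   SNPs into their flanks (merged through when both flanks agree).

Segment boundaries are placed at the bp midpoint between the last SNP of one
segment and the first SNP of the next; intervals are 0-based half-open.

The per-individual segment counts give the number of *discernible*
recombination events (double crossovers between adjacent informative SNPs are
inherently invisible).  Individuals whose count exceeds a multiple of the
expectation (2 x map length in Morgans for an F2) are flagged as likely
genotyping-error-driven and can be dropped.  Finally, segments of the
retained individuals are harmonized into population-level bin markers whose
boundaries are the union of all individual breakpoints.

Two parameter presets are provided: ``DEFAULT_SEGMENT_PARAMS`` (window 5,
min 3 SNPs) for mapping-quality segmentation, and ``QC_SEGMENT_PARAMS``
(window 1, min 2 SNPs) for the excess-recombination screen, which must keep
error-driven breakpoints visible rather than smooth them away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CODE_NA,
    BinMarkerMatrix,
    GeneticMap,
    GenotypeMatrix,
    Segment,
    SegmentSet,
)

__all__ = [
    "SegmentParams",
    "DEFAULT_SEGMENT_PARAMS",
    "QC_SEGMENT_PARAMS",
    "smooth_calls",
    "call_segments",
    "call_segments_all",
    "count_recombination_events",
    "expected_recombination_count",
    "filter_individuals",
    "harmonize_bins",
]


@dataclass(frozen=True)
class SegmentParams:
    smooth_window: int = 5
    min_snps_per_segment: int = 3

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd positive integer")
        if self.min_snps_per_segment < 1:
            raise ValueError("min_snps_per_segment must be >= 1")


DEFAULT_SEGMENT_PARAMS = SegmentParams(5, 3)
QC_SEGMENT_PARAMS = SegmentParams(1, 2)


def smooth_calls(obs: np.ndarray, window: int) -> np.ndarray:
    """Sliding plurality vote over a 1-D array of non-missing codes.

    The window is centred and truncated at the ends.  Ties (two or more codes
    sharing the window maximum) keep the original call.
    """
    obs = np.asarray(obs, dtype=np.int8)
    if window == 1 or obs.size <= 1:
        return obs.copy()
    h = window // 2
    n = obs.size
    counts = np.zeros((3, n), dtype=np.int32)
    for code in range(3):
        ind = (obs == code).astype(np.int32)
        cs = np.concatenate([[0], np.cumsum(ind)])
        lo = np.maximum(np.arange(n) - h, 0)
        hi = np.minimum(np.arange(n) + h + 1, n)
        counts[code] = cs[hi] - cs[lo]
    best = counts.max(axis=0)
    winners = counts == best[None, :]
    n_winners = winners.sum(axis=0)
    plurality = np.argmax(counts, axis=0).astype(np.int8)
    out = np.where(n_winners == 1, plurality, obs)
    return out.astype(np.int8)


def _segment_one_chrom(
    pos_bp: np.ndarray, calls: np.ndarray, params: SegmentParams
) -> list[tuple[int, int, int, int]]:
    """Segments for one chromosome as (start_bp, end_bp, genotype, n_support)."""
    nm = calls != CODE_NA
    if not nm.any():
        return []
    obs = calls[nm]
    pos = pos_bp[nm].astype(np.int64)

    smoothed = smooth_calls(obs, params.smooth_window)

    # run-length encode into [genotype, n_support, first_idx, last_idx]
    change = np.flatnonzero(smoothed[1:] != smoothed[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [smoothed.size]])
    runs = [
        [int(smoothed[s]), int(e - s), int(s), int(e - 1)]
        for s, e in zip(starts, ends)
    ]

    # absorb under-supported candidates
    min_snps = params.min_snps_per_segment
    while len(runs) > 1:
        weak = next((i for i, r in enumerate(runs) if r[1] < min_snps), None)
        if weak is None:
            break
        left = runs[weak - 1] if weak > 0 else None
        right = runs[weak + 1] if weak < len(runs) - 1 else None
        mid = runs[weak]
        if left is not None and right is not None and left[0] == right[0]:
            # merge through
            left[1] += mid[1] + right[1]
            left[3] = right[3]
            del runs[weak : weak + 2]
        else:
            if left is None:
                target = right
            elif right is None:
                target = left
            else:  # absorb into the better-supported flank, ties -> left
                target = left if left[1] >= right[1] else right
            target[1] += mid[1]
            if target is left:
                target[3] = mid[3]
            else:
                target[2] = mid[2]
            del runs[weak]

    # bp boundaries: midpoints between flanking SNPs; half-open intervals
    out = []
    for i, (geno, n_sup, s_idx, e_idx) in enumerate(runs):
        if i == 0:
            start = int(pos[0])
        else:
            start = (int(pos[runs[i - 1][3]]) + int(pos[s_idx]) + 1) // 2
        if i == len(runs) - 1:
            end = int(pos[-1]) + 1
        else:
            end = (int(pos[e_idx]) + int(pos[runs[i + 1][2]]) + 1) // 2
        out.append((start, end, geno, n_sup))
    return out


def call_segments(
    matrix: GenotypeMatrix,
    individual: str,
    params: SegmentParams = DEFAULT_SEGMENT_PARAMS,
) -> SegmentSet:
    """Infer the chromosomal segments of one individual.

    Chromosomes with zero non-missing calls simply contribute no segments.
    """
    col = matrix.column(individual)
    pos = matrix.sites["pos_bp"].to_numpy()
    segs = SegmentSet(individual=individual)
    for chrom, sl in matrix.chrom_slices().items():
        for start, end, geno, n_sup in _segment_one_chrom(pos[sl], col[sl], params):
            segs.segments.append(Segment(chrom, start, end, geno, n_sup))
    return segs


def call_segments_all(
    matrix: GenotypeMatrix, params: SegmentParams = DEFAULT_SEGMENT_PARAMS
) -> list[SegmentSet]:
    return [call_segments(matrix, ind, params) for ind in matrix.individuals]


def count_recombination_events(segset: SegmentSet) -> int:
    """Discernible recombination events = sum over chromosomes of
    (number of segments - 1)."""
    return sum(max(len(v) - 1, 0) for v in segset.by_chrom().values())


def expected_recombination_count(genetic_map: GeneticMap) -> float:
    """Expected discernible events for an F2: two gametes, each averaging one
    crossover per Morgan, each crossover yielding at most one genotype
    transition -> 2 x map length in Morgans."""
    return 2.0 * genetic_map.total_morgans


def filter_individuals(
    segsets: Sequence[SegmentSet],
    expected: float,
    multiplier: float = 2.0,
) -> tuple[list[str], pd.DataFrame]:
    """Drop individuals whose recombination count exceeds multiplier x expected.

    Returns ``(retained ids, report)`` where the report lists every individual
    with its count, the threshold, and whether it was dropped (for audit).
    """
    if multiplier <= 1.0:
        raise ValueError("multiplier must exceed 1")
    threshold = multiplier * expected
    rows = []
    retained = []
    for s in segsets:
        count = count_recombination_events(s)
        dropped = count > threshold
        rows.append((s.individual, count, threshold, dropped))
        if not dropped:
            retained.append(s.individual)
    report = pd.DataFrame(
        rows, columns=["individual", "recombination_events", "threshold", "dropped"]
    )
    return retained, report


def harmonize_bins(
    segsets: Sequence[SegmentSet],
    genetic_map: GeneticMap,
) -> BinMarkerMatrix:
    """Merge per-individual segments into population bin markers.

    Bin boundaries per chromosome are the union of all individuals' segment
    boundaries; each individual's call in a bin is the genotype of its
    covering segment (NA where uncovered).  Monomorphic bins are dropped and
    adjacent bins with identical call vectors collapsed.
    """
    if len(segsets) < 2:
        raise ValueError("need at least two individuals to harmonize bins")
    individuals = [s.individual for s in segsets]
    per_ind = [s.by_chrom() for s in segsets]

    bin_rows = []
    call_rows = []
    any_informative = False
    for chrom in genetic_map:
        bounds: set[int] = set()
        for ind_segs in per_ind:
            for seg in ind_segs.get(chrom.name, []):
                bounds.add(seg.start_bp)
                bounds.add(seg.end_bp)
        if len(bounds) < 2:
            continue
        edges = np.array(sorted(bounds), dtype=np.int64)
        starts, ends = edges[:-1], edges[1:]
        n_bins = starts.size

        calls = np.full((n_bins, len(individuals)), CODE_NA, dtype=np.int8)
        for j, ind_segs in enumerate(per_ind):
            segs = ind_segs.get(chrom.name, [])
            if not segs:
                continue
            seg_starts = np.array([s.start_bp for s in segs], dtype=np.int64)
            seg_ends = np.array([s.end_bp for s in segs], dtype=np.int64)
            genos = np.array([s.genotype for s in segs], dtype=np.int8)
            k = np.searchsorted(seg_starts, starts, side="right") - 1
            valid = (k >= 0) & (ends <= seg_ends[np.clip(k, 0, len(segs) - 1)])
            calls[valid, j] = genos[k[valid]]

        # polymorphic bins only
        keep = np.zeros(n_bins, dtype=bool)
        for b in range(n_bins):
            row = calls[b][calls[b] != CODE_NA]
            keep[b] = row.size > 0 and np.unique(row).size > 1
        if not keep.any():
            continue
        any_informative = True
        starts, ends, calls = starts[keep], ends[keep], calls[keep]

        # collapse adjacent bins with identical call vectors
        merged_rows: list[tuple[str, int, int]] = []
        merged_calls: list[np.ndarray] = []
        for b in range(starts.size):
            if merged_calls and np.array_equal(merged_calls[-1], calls[b]):
                chrom_name, s0, _ = merged_rows[-1]
                merged_rows[-1] = (chrom_name, s0, int(ends[b]))
            else:
                merged_rows.append((chrom.name, int(starts[b]), int(ends[b])))
                merged_calls.append(calls[b])
        for (chrom_name, s0, e0), row in zip(merged_rows, merged_calls):
            mid = (s0 + e0) // 2
            bin_rows.append(
                (chrom_name, s0, e0, mid, float(chrom.bp_to_cm(mid)))
            )
            call_rows.append(row)

    if not any_informative:
        raise ValueError("no informative overlap between individuals' coverage")

    bins = pd.DataFrame(
        bin_rows, columns=["chrom", "start_bp", "end_bp", "rep_pos_bp", "rep_pos_cm"]
    )
    return BinMarkerMatrix(bins, individuals, np.array(call_rows, dtype=np.int8))
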