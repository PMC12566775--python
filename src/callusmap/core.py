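"""Shared data containers for the callus-type mapping pipeline.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open ``[start_bp, end_bp)``.
Genetic positions are in centimorgan (cM); physical positions in base pairs
(bp).  TSV writers present 1-based positions (see :mod:`callusmap.io`).

Genotype codes
--------------
F2 genotypes are stored as ``int8``:

====  =====  =============================
code  label  meaning
====  =====  =============================
0     AA     homozygous for the A188 allele
1     AB     heterozygous
2     BB     homozygous for the B73 allele
-1    NA     missing call
====  =====  =============================

The orientation is fixed: ``AA`` always means the A188 homozygote, so allele
dosage (number of A188 allele copies) is ``2 - code`` for non-missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

CODE_AA: int = 0
CODE_AB: int = 1
CODE_BB: int = 2
CODE_NA: int = -1

CODE_TO_STR = {CODE_AA: "AA", CODE_AB: "AB", CODE_BB: "BB", CODE_NA: "NA"}
STR_TO_CODE = {v: k for k, v in CODE_TO_STR.items()}


def haldane_recombination_fraction(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Map distance (cM) -> recombination fraction, no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def haldane_map_distance(r: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction -> map distance (cM); r must be < 0.5."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of a genetic map.

    ``anchors_bp``/``anchors_cm`` define a piecewise-linear cM <-> bp
    interpolation.  The first anchor is at 0 cM; bp strictly increasing,
    cM non-decreasing.
    """

    name: str
    length_bp: int
    anchors_bp: np.ndarray
    anchors_cm: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.anchors_bp, dtype=float)
        cm = np.asarray(self.anchors_cm, dtype=float)
        object.__setattr__(self, "anchors_bp", bp)
        object.__setattr__(self, "anchors_cm", cm)
        if bp.ndim != 1 or bp.shape != cm.shape or bp.size < 2:
            raise ValueError(f"{self.name}: need >=2 matching anchors")
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"{self.name}: anchor bp must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"{self.name}: anchor cM must be non-decreasing")
        if cm[0] != 0.0:
            raise ValueError(f"{self.name}: first anchor must sit at 0 cM")

    @property
    def length_cm(self) -> float:
        return float(self.anchors_cm[-1])

    def bp_to_cm(self, pos_bp: np.ndarray | float) -> np.ndarray | float:
        return np.interp(pos_bp, self.anchors_bp, self.anchors_cm)

    def cm_to_bp(self, pos_cm: np.ndarray | float) -> np.ndarray | float:
        return np.interp(pos_cm, self.anchors_cm, self.anchors_bp)


@dataclass(frozen=True)
class GeneticMap:
    """Ordered collection of chromosomes with cM <-> bp interpolation."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome named {name!r}")

    @property
    def total_length_cm(self) -> float:
        return float(sum(c.length_cm for c in self.chromosomes))

    @property
    def total_morgans(self) -> float:
        return self.total_length_cm / 100.0

    @staticmethod
    def uniform(
        lengths_cm: Sequence[float],
        bp_per_cm: float = 1_000_000.0,
        prefix: str = "chr",
    ) -> "GeneticMap":
        """Build a map with constant recombination density per chromosome."""
        chroms = []
        for i, L in enumerate(lengths_cm, start=1):
            if L < 0:
                raise ValueError("negative chromosome length")
            length_bp = int(round(L * bp_per_cm)) if L > 0 else 0
            chroms.append(
                Chromosome(
                    name=f"{prefix}{i}",
                    length_bp=max(length_bp, 1),
                    anchors_bp=np.array([0.0, max(length_bp, 1)]),
                    anchors_cm=np.array([0.0, L]),
                )
            )
        return GeneticMap(tuple(chroms))


@dataclass
class GenotypeMatrix:
    """SNP sites x individuals matrix of int8 genotype codes.

    ``sites`` has columns ``chrom, pos_bp`` (optionally ``pos_cm``), sorted by
    (chrom in map order, pos_bp).  ``calls`` is ``(n_sites, n_individuals)``.
    """

    sites: pd.DataFrame
    individuals: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.individuals)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sites)}, {len(self.individuals)})"
            )
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def chrom_order(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.sites["chrom"]:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome (sites are chromosome-sorted)."""
        out: dict[str, slice] = {}
        chroms = self.sites["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def column(self, individual: str) -> np.ndarray:
        return self.calls[:, self.individuals.index(individual)]

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in ids]
        return GenotypeMatrix(self.sites.copy(), list(ids), self.calls[:, idx])


@dataclass
class Segment:
    """A run of constant genotype on one chromosome, half-open [start, end)."""

    chrom: str
    start_bp: int
    end_bp: int
    genotype: int
    n_support_snps: int


@dataclass
class SegmentSet:
    """Per-individual chromosomal segments (ordered, non-overlapping)."""

    individual: str
    segments: list[Segment] = field(default_factory=list)

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for s in self.segments:
            out.setdefault(s.chrom, []).append(s)
        return out

    def genotype_at(self, chrom: str, pos_bp: float) -> int:
        for s in self.segments:
            if s.chrom == chrom and s.start_bp <= pos_bp < s.end_bp:
                return s.genotype
        return CODE_NA


@dataclass
class BinMarkerMatrix:
    """Population-harmonized segment (bin) markers.

    ``bins`` columns: ``chrom, start_bp, end_bp, rep_pos_bp, rep_pos_cm``.
    ``calls`` is ``(n_bins, n_individuals)`` int8.
    """

    bins: pd.DataFrame
    individuals: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.bins), len(self.individuals)):
            raise ValueError("bin calls shape mismatch")
        self.bins = self.bins.reset_index(drop=True)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        chroms = self.bins["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out


@dataclass
class ScanResult:
    """Per-position statistic track from a genome scan.

    ``table`` columns: ``chrom, pos_bp, pos_cm, statistic`` plus any
    method-specific extras (``df``, ``n``).  ``statistic_kind`` is ``"pvalue"``
    (smaller = stronger) or ``"lod"`` (larger = stronger).
    """

    table: pd.DataFrame
    statistic_kind: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.statistic_kind not in ("pvalue", "lod"):
            raise ValueError("statistic_kind must be 'pvalue' or 'lod'")
        self.table = self.table.reset_index(drop=True)

    @property
    def higher_is_stronger(self) -> bool:
        return self.statistic_kind == "lod"

    def genome_extremum(self) -> float:
        """Genome-wide extremum (max LOD or min p) over finite statistics."""
        vals = self.table["statistic"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("scan has no finite statistics")
        return float(vals.max() if self.higher_is_stronger else vals.min())


@dataclass
class QtlPeak:
    """A called QTL peak with its support interval and allele annotation."""

    name: str
    chrom: str
    peak_pos_bp: int
    peak_pos_cm: float
    lod: float | None = None
    pvalue: float | None = None
    interval_bp: tuple[int, int] | None = None
    favorable_allele: str | None = None  # "A188" or "B73"
    dominance_call: str | None = None  # "additive" | "partial" | "dominant"


def dosage_from_codes(calls: np.ndarray) -> np.ndarray:
    """A188-allele dosage (0/1/2) from int8 codes; missing -> -1."""
    calls = np.asarray(calls)
    out = (2 - calls).astype(np.int8)
    out[calls == CODE_NA] = -1
    return out
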