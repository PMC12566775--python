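"""Synthetic F2 populations for the callus-type mapping pipeline.

The generator emulates the study design underlying the pipeline: a large
B73 x A188 F2 embryo population phenotyped for a binary callus morphology
(Type I compact / Type II friable), from which phenotypic extremes are drawn
for GBS genotyping and two 50-callus bulks per phenotype are pooled for
BSR-seq.

Model
-----
* Meiosis: no crossover interference.  Crossover counts per gamete and
  chromosome are Poisson(length in Morgans); positions i.i.d. uniform on the
  cM axis (Haldane model).
* Phenotype: additive liability on the log-odds scale,
  ``eta_i = mu + sum_q beta_q (x_iq - 1) + dom_q 1[x_iq == 1]`` with
  ``x_iq`` the A188-allele dosage at QTL q; ``P(Type II) = logistic(eta)``.
  Positive ``beta`` means the A188 allele favors the Type II callus.
* GBS degradation: independent per-call missingness, heterozygote
  undercalling to a random homozygote, and uniform genotype error.
* Bulks: per SNP and bulk replicate, read depth ~ Poisson(depth_mean) and
  A188-allele reads ~ Binomial(depth, f) where f is the mean A188 allele
  frequency of the bulk members — the binomial read-count model the
  association test downstream assumes.

Randomness: a single seed fans out to independent per-stage substreams
(meiosis, phenotype, selection, GBS noise, bulks, gene fixture) via
``numpy.random.SeedSequence.spawn``, so stages can be re-run independently
and the whole simulation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CODE_AA,
    CODE_AB,
    CODE_BB,
    CODE_NA,
    Chromosome,
    GeneticMap,
    GenotypeMatrix,
)

__all__ = [
    "QtlSpec",
    "SimConfig",
    "Gamete",
    "F2Truth",
    "default_map",
    "five_qtl_architecture",
    "default_config",
    "simulate_gamete",
    "simulate_f2",
    "degrade_to_gbs",
    "simulate_bulk_counts",
    "make_gene_fixture",
]

# Maize-like at reduced scale: 10 chromosomes, 100-180 cM each.
_DEFAULT_LENGTHS_CM = (180.0, 170.0, 160.0, 150.0, 140.0, 130.0, 120.0, 110.0, 105.0, 100.0)


def default_map(
    lengths_cm: Sequence[float] = _DEFAULT_LENGTHS_CM,
    bp_per_cm: float = 1_000_000.0,
) -> GeneticMap:
    """Ten maize-shaped chromosomes with uniform cM/bp density."""
    return GeneticMap.uniform(lengths_cm, bp_per_cm=bp_per_cm)


@dataclass(frozen=True)
class QtlSpec:
    """One additive QTL on the liability (log-odds of Type II) scale.

    ``beta`` is the effect per A188 allele copy; beta > 0 means the A188
    allele favors Type II, beta < 0 the B73 allele.  ``dominance`` shifts the
    heterozygote (default 0: purely additive, matching the observed
    non-dominant behavior of the callus-type QTLs).
    """

    chrom: str
    pos_cm: float
    beta: float
    dominance: float = 0.0

    def validate(self, genetic_map: GeneticMap) -> None:
        chrom = genetic_map.chromosome(self.chrom)
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not 0.0 <= self.pos_cm <= chrom.length_cm:
            raise ValueError(
                f"QTL at {self.pos_cm} cM outside {self.chrom} (0-{chrom.length_cm} cM)"
            )


def five_qtl_architecture(genetic_map: GeneticMap | None = None) -> list[QtlSpec]:
    """Five-QTL architecture mirroring the mapped callus-type loci.

    QTLs on chromosomes 2, 5, 6, 8 and 9; the chromosome-6 allele from A188
    favors Type II (beta > 0) while B73 alleles are favorable elsewhere
    (beta < 0), with the chromosome-5 QTL the strongest.  Effect magnitudes
    (0.8-1.1 liability log-odds per allele copy) are the package's own
    defaults, sized so the architecture is mappable in a ~118-extreme design.
    """
    if genetic_map is None:
        genetic_map = default_map()
    specs = [
        QtlSpec("chr2", 95.0, -0.9),
        QtlSpec("chr5", 85.0, -1.1),
        QtlSpec("chr6", 55.0, +1.0),
        QtlSpec("chr8", 70.0, -0.9),
        QtlSpec("chr9", 55.0, -0.8),
    ]
    for s in specs:
        s.validate(genetic_map)
    return specs


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic study.

    Defaults are the study-scale conditions: 2194 embryos, 100 + 100
    phenotypic extremes, two 50-callus bulks per phenotype, GBS-like 20%
    missingness / 2% genotype error / 5% het undercall, 5 SNPs per cM.
    """

    genetic_map: GeneticMap
    qtls: tuple[QtlSpec, ...]
    mu: float = 0.0
    n_embryos: int = 2194
    n_select_per_class: int = 100
    snp_density: float = 5.0  # SNPs per cM
    missing_rate: float = 0.2
    genotype_error_rate: float = 0.02
    het_undercall_rate: float = 0.05
    bulk_size: int = 50
    bulk_depth_mean: float = 200.0
    n_bulk_reps: int = 2
    selection: str = "extreme"  # "extreme" (liability tails) or "random"
    selection_noise_sd: float = 2.0  # sd of the morphology-score noise used
    seed: int = 0                    # when ranking calli for extremeness

    def __post_init__(self) -> None:
        object.__setattr__(self, "qtls", tuple(self.qtls))
        for rate in (self.missing_rate, self.genotype_error_rate, self.het_undercall_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_select_per_class * 2 > self.n_embryos:
            raise ValueError("cannot select more individuals than embryos")
        if self.snp_density <= 0 or self.bulk_depth_mean <= 0:
            raise ValueError("snp_density and bulk_depth_mean must be positive")
        if self.selection not in ("extreme", "random"):
            raise ValueError("selection must be 'extreme' or 'random'")
        if self.selection_noise_sd < 0:
            raise ValueError("selection_noise_sd must be non-negative")
        for q in self.qtls:
            q.validate(self.genetic_map)
        for c in self.genetic_map:
            if c.length_cm <= 0:
                raise ValueError(f"zero-length chromosome {c.name}")


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-scale config with the five-QTL architecture."""
    gmap = overrides.pop("genetic_map", default_map())
    qtls = overrides.pop("qtls", tuple(five_qtl_architecture(gmap)))
    return SimConfig(genetic_map=gmap, qtls=tuple(qtls), seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Meiosis


@dataclass(frozen=True)
class Gamete:
    """One haploid product: per chromosome, founder phase of the leftmost
    segment (0 = A188, 1 = B73) and sorted crossover positions in cM."""

    phases: tuple[int, ...]
    breaks: tuple[np.ndarray, ...]

    def allele(self, chrom_index: int, pos_cm: np.ndarray | float) -> np.ndarray:
        """A188-allele indicator (1 = carries A188) at cM position(s)."""
        k = np.searchsorted(self.breaks[chrom_index], pos_cm, side="right")
        return ((self.phases[chrom_index] + k) % 2 == 0).astype(np.int8)


def simulate_gamete(genetic_map: GeneticMap, rng: np.random.Generator) -> Gamete:
    """Draw one gamete under the no-interference (Haldane) model."""
    phases = []
    breaks = []
    for chrom in genetic_map:
        n_x = rng.poisson(chrom.length_cm / 100.0)
        pos = np.sort(rng.uniform(0.0, chrom.length_cm, size=n_x))
        phases.append(int(rng.integers(0, 2)))
        breaks.append(pos)
    return Gamete(tuple(phases), tuple(breaks))


def _simulate_gametes_batch(
    genetic_map: GeneticMap, n: int, rng: np.random.Generator
) -> list[Gamete]:
    return [simulate_gamete(genetic_map, rng) for _ in range(n)]


# ---------------------------------------------------------------------------
# F2 population


@dataclass
class F2Truth:
    """Ground truth for a simulated F2 population.

    ``dosage`` holds the A188-allele dosage (0/1/2) at every simulated SNP for
    every embryo; genotype codes are recovered as ``2 - dosage``.
    """

    config: SimConfig
    snp_sites: pd.DataFrame  # chrom, pos_bp, pos_cm
    individuals: list[str]
    gametes: list[tuple[Gamete, Gamete]]
    dosage: np.ndarray  # (n_snps, n_individuals) int8
    qtl_dosage: np.ndarray  # (n_qtls, n_individuals) int8
    liability: np.ndarray
    phenotype: np.ndarray  # 1 = Type II
    selected_type1: list[str] = field(default_factory=list)
    selected_type2: list[str] = field(default_factory=list)

    @property
    def genotype_codes(self) -> np.ndarray:
        """True int8 genotype codes (0=AA .. 2=BB) at every SNP."""
        return (2 - self.dosage).astype(np.int8)

    def true_matrix(self, ids: Sequence[str] | None = None) -> GenotypeMatrix:
        ids = list(ids) if ids is not None else list(self.individuals)
        idx = [self.individuals.index(i) for i in ids]
        return GenotypeMatrix(self.snp_sites.copy(), ids, self.genotype_codes[:, idx])

    def true_transition_count(self, individual: str) -> int:
        """Genotype changes along the true SNP-level calls (all chromosomes)."""
        col = self.genotype_codes[:, self.individuals.index(individual)]
        total = 0
        chroms = self.snp_sites["chrom"].to_numpy()
        for chrom in pd.unique(chroms):
            g = col[chroms == chrom]
            total += int(np.sum(g[1:] != g[:-1]))
        return total


def _snp_sites(config: SimConfig) -> pd.DataFrame:
    rows = []
    for chrom in config.genetic_map:
        n = max(int(round(config.snp_density * chrom.length_cm)), 1)
        pos_cm = (np.arange(n) + 0.5) / n * chrom.length_cm
        pos_bp = np.asarray(chrom.cm_to_bp(pos_cm)).round().astype(np.int64)
        rows.append(
            pd.DataFrame({"chrom": chrom.name, "pos_bp": pos_bp, "pos_cm": pos_cm})
        )
    return pd.concat(rows, ignore_index=True)


def simulate_f2(config: SimConfig) -> F2Truth:
    """Simulate the full F2 design: meiosis, phenotype, extreme selection.

    Raises ``ValueError`` (with both class sizes) if either phenotype class is
    smaller than ``n_select_per_class``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_meiosis, rng_pheno, rng_select = [
        np.random.default_rng(s) for s in ss.spawn(3)
    ]

    sites = _snp_sites(config)
    n = config.n_embryos
    individuals = [f"F2_{i + 1:04d}" for i in range(n)]

    gametes = [
        (simulate_gamete(config.genetic_map, rng_meiosis),
         simulate_gamete(config.genetic_map, rng_meiosis))
        for _ in range(n)
    ]

    chrom_names = config.genetic_map.names
    site_chrom = sites["chrom"].to_numpy()
    site_cm = sites["pos_cm"].to_numpy()
    chrom_site_idx = {c: np.flatnonzero(site_chrom == c) for c in chrom_names}

    dosage = np.empty((len(sites), n), dtype=np.int8)
    for j, (g1, g2) in enumerate(gametes):
        for ci, cname in enumerate(chrom_names):
            idx = chrom_site_idx[cname]
            pos = site_cm[idx]
            dosage[idx, j] = g1.allele(ci, pos) + g2.allele(ci, pos)

    n_q = len(config.qtls)
    qtl_dosage = np.zeros((n_q, n), dtype=np.int8)
    for qi, q in enumerate(config.qtls):
        ci = chrom_names.index(q.chrom)
        for j, (g1, g2) in enumerate(gametes):
            qtl_dosage[qi, j] = g1.allele(ci, q.pos_cm) + g2.allele(ci, q.pos_cm)

    liability = np.full(n, config.mu, dtype=float)
    for qi, q in enumerate(config.qtls):
        x = qtl_dosage[qi].astype(float)
        liability += q.beta * (x - 1.0)
        if q.dominance != 0.0:
            liability += q.dominance * (x == 1.0)
    p_type2 = 1.0 / (1.0 + np.exp(-liability))
    phenotype = (rng_pheno.uniform(size=n) < p_type2).astype(np.int8)

    idx1 = np.flatnonzero(phenotype == 0)
    idx2 = np.flatnonzero(phenotype == 1)
    k = config.n_select_per_class
    if idx1.size < k or idx2.size < k:
        raise ValueError(
            "phenotype class smaller than n_select_per_class: "
            f"Type I = {idx1.size}, Type II = {idx2.size}, need {k} each"
        )
    if config.selection == "extreme":
        # "extremely Type I/II" calli: the clearest morphologies, modeled as
        # the tails of a noisy morphology score within each phenotype class
        score_noise = rng_select.normal(0.0, config.selection_noise_sd, size=n)
        jitter = rng_select.uniform(0, 1e-9, size=n)
        lia = liability + score_noise + jitter
        sel1_idx = idx1[np.argsort(lia[idx1])[:k]]
        sel2_idx = idx2[np.argsort(-lia[idx2])[:k]]
    else:
        sel1_idx = rng_select.choice(idx1, size=k, replace=False)
        sel2_idx = rng_select.choice(idx2, size=k, replace=False)
    sel1 = sorted(individuals[i] for i in sel1_idx)
    sel2 = sorted(individuals[i] for i in sel2_idx)

    return F2Truth(
        config=config,
        snp_sites=sites,
        individuals=individuals,
        gametes=gametes,
        dosage=dosage,
        qtl_dosage=qtl_dosage,
        liability=liability,
        phenotype=phenotype,
        selected_type1=sel1,
        selected_type2=sel2,
    )


# ---------------------------------------------------------------------------
# GBS degradation


def degrade_to_gbs(
    truth: F2Truth,
    individuals: Sequence[str] | None = None,
    missing_rate: float | None = None,
    genotype_error_rate: float | None = None,
    het_undercall_rate: float | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Corrupt true genotypes into GBS-like observations.

    Per call, independently: set missing w.p. ``missing_rate``; surviving
    heterozygote calls become a random homozygote w.p. ``het_undercall_rate``;
    any surviving call is replaced by a uniformly chosen *different* code w.p.
    ``genotype_error_rate``.  Rates default to the truth's config.
    """
    cfg = truth.config
    missing_rate = cfg.missing_rate if missing_rate is None else missing_rate
    genotype_error_rate = (
        cfg.genotype_error_rate if genotype_error_rate is None else genotype_error_rate
    )
    het_undercall_rate = (
        cfg.het_undercall_rate if het_undercall_rate is None else het_undercall_rate
    )
    for r in (missing_rate, genotype_error_rate, het_undercall_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])

    ids = list(individuals) if individuals is not None else list(truth.individuals)
    idx = [truth.individuals.index(i) for i in ids]
    calls = truth.genotype_codes[:, idx].copy()
    shape = calls.shape

    if het_undercall_rate > 0:
        undercall = (calls == CODE_AB) & (rng.uniform(size=shape) < het_undercall_rate)
        calls[undercall] = rng.choice(
            np.array([CODE_AA, CODE_BB], dtype=np.int8), size=int(undercall.sum())
        )
    if genotype_error_rate > 0:
        err = rng.uniform(size=shape) < genotype_error_rate
        # uniformly pick one of the two *other* codes
        shift = rng.integers(1, 3, size=int(err.sum()), dtype=np.int8)
        calls[err] = (calls[err] + shift) % 3
    if missing_rate > 0:
        calls[rng.uniform(size=shape) < missing_rate] = CODE_NA

    return GenotypeMatrix(truth.snp_sites.copy(), ids, calls)


# ---------------------------------------------------------------------------
# Bulk read counts


def simulate_bulk_counts(
    truth: F2Truth,
    bulks: dict[str, tuple[str, Sequence[str]]] | None = None,
    depth_mean: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Binomial allele read counts for pooled bulks.

    ``bulks`` maps bulk id -> (phenotype class label, member ids); by default
    the selected extremes are split into ``n_bulk_reps`` bulks of
    ``bulk_size`` per class ("XT-I"/"XT-II").  Per SNP and bulk: depth ~
    Poisson(depth_mean), A188 reads ~ Binomial(depth, mean member A188 allele
    frequency).  Returns a tidy frame with one row per SNP x bulk.
    """
    cfg = truth.config
    depth_mean = cfg.bulk_depth_mean if depth_mean is None else depth_mean
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[4])

    if bulks is None:
        bulks = {}
        for cls, sel in (("XT-I", truth.selected_type1), ("XT-II", truth.selected_type2)):
            for r in range(cfg.n_bulk_reps):
                members = sel[r * cfg.bulk_size : (r + 1) * cfg.bulk_size]
                bulks[f"{cls}_rep{r + 1}"] = (cls, members)

    frames = []
    for bulk_id, (cls, members) in bulks.items():
        if len(members) == 0:
            raise ValueError(f"bulk {bulk_id!r} is empty")
        idx = [truth.individuals.index(m) for m in members]
        f = truth.dosage[:, idx].astype(float).mean(axis=1) / 2.0
        depth = rng.poisson(depth_mean, size=len(f))
        a188 = rng.binomial(depth, f)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": truth.snp_sites["chrom"],
                    "pos_bp": truth.snp_sites["pos_bp"],
                    "bulk_id": bulk_id,
                    "phenotype_class": cls,
                    "a188_reads": a188,
                    "b73_reads": depth - a188,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Gene / DEG fixture for the integration stage


def make_gene_fixture(
    genetic_map: GeneticMap,
    n_genes: int,
    qtl_intervals: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    de_fraction: float = 0.1,
    in_interval_boost: float = 0.3,
    gene_length_bp: int = 5_000,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Random gene annotation plus two directed DEG lists.

    Genes are placed uniformly in bp.  Each gene is independently declared DE
    (direction up/down) in each of two contrasts with probability
    ``de_fraction`` (``+ in_interval_boost`` for genes overlapping a QTL
    interval, so the candidate set is non-trivially populated).  Returns
    ``(genes, deg_contrast_1, deg_contrast_2)``; the expected candidate set is
    computable from these tables by brute force.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_genes == 0:
        genes = pd.DataFrame(columns=["gene_id", "chrom", "start_bp", "end_bp"])
        deg = pd.DataFrame(columns=["gene_id", "direction", "padj"])
        return genes, deg.copy(), deg.copy()

    lengths = np.array([c.length_bp for c in genetic_map], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(lengths), size=n_genes, p=probs)
    rows = []
    for i, ci in enumerate(sorted(chrom_idx.tolist())):
        chrom = genetic_map.chromosomes[ci]
        start = int(rng.integers(0, max(chrom.length_bp - gene_length_bp, 1)))
        rows.append((f"gene{i + 1:05d}", chrom.name, start, start + gene_length_bp))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start_bp", "end_bp"])
    genes = genes.sort_values(["chrom", "start_bp"], kind="stable").reset_index(drop=True)

    in_interval = np.zeros(n_genes, dtype=bool)
    if qtl_intervals is not None:
        for _, itv in qtl_intervals.iterrows():
            hit = (
                (genes["chrom"] == itv["chrom"])
                & (genes["start_bp"] < itv["end_bp"])
                & (genes["end_bp"] > itv["start_bp"])
            )
            in_interval |= hit.to_numpy()

    p_de = np.where(in_interval, de_fraction + in_interval_boost, de_fraction)
    degs = []
    for _ in range(2):
        is_de = rng.uniform(size=n_genes) < p_de
        direction = np.where(rng.uniform(size=n_genes) < 0.5, "up", "down")
        padj = rng.uniform(0.0, 0.1, size=n_genes)
        degs.append(
            pd.DataFrame(
                {
                    "gene_id": genes["gene_id"][is_de],
                    "direction": direction[is_de],
                    "padj": padj[is_de].round(6),
                }
            ).reset_index(drop=True)
        )
    return genes, degs[0], degs[1]
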