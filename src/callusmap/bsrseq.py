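"""Bulk-segregant RNA-seq (BSR-seq) allele association.

SNPs called from the pooled Type I and Type II bulk RNA-seq are first
filtered on record quality (``AF >= 0.2 && QUAL >= 30.0 && DP >= 100 &&
DP < 10,000``, boundary semantics exactly as written) and on parental
concordance (the site must be a fixed homozygous difference between A188 and
B73 whose alleles match the record).  Each surviving SNP is then tested for
a divergent parental-allele read distribution between the two bulk classes
with a binomial GLM: under the default pooling the replicate bulks of a
class are summed and the class-effect likelihood-ratio (deviance) test on
the pooled 2x2 table is the classic G-test, computed in closed form; a
``replicate_term`` variant fits the GLM with a replicate nuisance factor via
statsmodels.  Genome-wide significance uses the Bonferroni cutoff
``alpha / n_tests``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "SnpFilterThresholds",
    "BsrTestResult",
    "filter_snp_records",
    "filter_parental_concordance",
    "binomial_deviance_test",
    "bsr_association_test",
    "bsr_scan",
    "bonferroni_cutoff",
]


def binomial_deviance_test(
    a1: np.ndarray, b1: np.ndarray, a2: np.ndarray, b2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized binomial-GLM deviance (G) test on pooled 2x2 tables.

    Arrays are A188/B73 read counts in class 1 and class 2.  Returns
    ``(deviance, pvalue)`` with a 1-df chi-square reference; tables with an
    empty class give NaN.  Equivalent to the likelihood-ratio test of the
    class effect in a binomial GLM of the A188-read proportion (logit link).
    """
    a1, b1, a2, b2 = (np.asarray(x, dtype=float) for x in (a1, b1, a2, b2))
    n1, n2 = a1 + b1, a2 + b2
    a, b, n = a1 + a2, b1 + b2, n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = np.stack([n1 * a, n1 * b, n2 * a, n2 * b]) / np.maximum(n, 1)
        obs = np.stack([a1, b1, a2, b2])
        g = 2.0 * special.xlogy(obs, obs / np.maximum(exp, 1e-300)).sum(axis=0)
    dev = np.where((n1 > 0) & (n2 > 0), np.maximum(g, 0.0), np.nan)
    pvals = np.where(np.isfinite(dev), stats.chi2.sf(np.nan_to_num(dev), 1), np.nan)
    return dev, pvals


@dataclass(frozen=True)
class SnpFilterThresholds:
    af_min: float = 0.2
    qual_min: float = 30.0
    dp_min: int = 100
    dp_max: int = 10_000  # exclusive


def filter_snp_records(
    records: pd.DataFrame,
    thresholds: SnpFilterThresholds = SnpFilterThresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Quality-filter SNP records.

    ``records`` needs columns ``chrom, pos_bp, ref_allele, alt_allele, qual,
    depth, alt_frequency``.  A record is retained iff it is bi-allelic
    (single-base ref and alt) and ``af >= af_min``, ``qual >= qual_min``,
    ``dp_min <= depth < dp_max``.  Records with missing fields are rejected
    as ``malformed``.  Returns ``(retained, rejection tally by rule)``; a
    record is tallied under the first rule it fails (malformed, biallelic,
    af, qual, dp).
    """
    required = ["chrom", "pos_bp", "ref_allele", "alt_allele", "qual", "depth", "alt_frequency"]
    missing_cols = [c for c in required if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records missing columns: {missing_cols}")

    tally = {"malformed": 0, "not_biallelic": 0, "af": 0, "qual": 0, "dp": 0}
    num = records[["qual", "depth", "alt_frequency"]].apply(pd.to_numeric, errors="coerce")
    malformed = (
        num.isna().any(axis=1)
        | records["ref_allele"].isna()
        | records["alt_allele"].isna()
    ).to_numpy()
    bases = {"A", "C", "G", "T"}
    biallelic = np.array(
        [
            (not m)
            and str(r) in bases
            and str(a) in bases
            and str(r) != str(a)
            for m, r, a in zip(malformed, records["ref_allele"], records["alt_allele"])
        ]
    )
    af_ok = num["alt_frequency"].to_numpy() >= thresholds.af_min
    qual_ok = num["qual"].to_numpy() >= thresholds.qual_min
    dp = num["depth"].to_numpy()
    dp_ok = (dp >= thresholds.dp_min) & (dp < thresholds.dp_max)

    keep = np.zeros(len(records), dtype=bool)
    for i in range(len(records)):
        if malformed[i]:
            tally["malformed"] += 1
        elif not biallelic[i]:
            tally["not_biallelic"] += 1
        elif not af_ok[i]:
            tally["af"] += 1
        elif not qual_ok[i]:
            tally["qual"] += 1
        elif not dp_ok[i]:
            tally["dp"] += 1
        else:
            keep[i] = True
    return records[keep].reset_index(drop=True), tally


def filter_parental_concordance(
    records: pd.DataFrame, parental: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep records at fixed homozygous A188/B73 differences.

    ``parental`` has columns ``chrom, pos_bp, a188_allele, b73_allele`` where
    an allele is a single base for a homozygous call or e.g. ``A/G`` for a
    het call.  Retained iff the site is present, both parents are homozygous
    for different alleles, and {ref, alt} equals the parental allele pair.
    Tallies: ``absent``, ``parent_het``, ``parents_identical``,
    ``allele_mismatch``.
    """
    key = parental.set_index(["chrom", "pos_bp"])
    tally = {"absent": 0, "parent_het": 0, "parents_identical": 0, "allele_mismatch": 0}
    keep = np.zeros(len(records), dtype=bool)
    for i, row in enumerate(records.itertuples(index=False)):
        k = (row.chrom, row.pos_bp)
        if k not in key.index:
            tally["absent"] += 1
            continue
        a188 = str(key.loc[k, "a188_allele"])
        b73 = str(key.loc[k, "b73_allele"])
        if len(a188) != 1 or len(b73) != 1:
            tally["parent_het"] += 1
            continue
        if a188 == b73:
            tally["parents_identical"] += 1
            continue
        if {str(row.ref_allele), str(row.alt_allele)} != {a188, b73}:
            tally["allele_mismatch"] += 1
            continue
        keep[i] = True
    return records[keep].reset_index(drop=True), tally


@dataclass
class BsrTestResult:
    """Association result at one SNP."""

    table: pd.DataFrame  # pooled 2x2: rows XT-I/XT-II, cols a188/b73 reads
    deviance: float
    pvalue: float
    direction: str | None  # class with the higher A188-read proportion
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.pvalue)


def _gtest_2x2(a1: float, b1: float, a2: float, b2: float) -> tuple[float, float]:
    """Deviance (G) statistic and 1-df chi-square p for a pooled 2x2 table.

    Identical to the binomial-GLM likelihood-ratio test of the class effect
    on the A188-read proportion (logit link).
    """
    n1, n2 = a1 + b1, a2 + b2
    a, b = a1 + a2, b1 + b2
    n = n1 + n2
    obs = np.array([a1, b1, a2, b2], dtype=float)
    exp = np.array([n1 * a, n1 * b, n2 * a, n2 * b], dtype=float) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 2.0 * np.sum(special.xlogy(obs, obs / np.maximum(exp, 1e-300)))
    g = max(float(g), 0.0)
    return g, float(stats.chi2.sf(g, 1))


def bsr_association_test(
    counts: pd.DataFrame, pooling: str = "pool_replicates"
) -> BsrTestResult:
    """Test one SNP for divergent allele distribution between bulk classes.

    ``counts`` has one row per bulk replicate with columns
    ``phenotype_class`` (``XT-I``/``XT-II``), ``a188_reads``, ``b73_reads``.
    ``pool_replicates`` (default) sums replicates within class and applies
    the closed-form binomial deviance test; ``replicate_term`` fits a
    binomial GLM with a replicate nuisance factor (statsmodels) and tests
    the class effect by LRT.  Zero total reads in a class -> missing result.
    """
    classes = ("XT-I", "XT-II")
    pooled = {}
    for cls in classes:
        sub = counts[counts["phenotype_class"] == cls]
        pooled[cls] = (float(sub["a188_reads"].sum()), float(sub["b73_reads"].sum()))
    table = pd.DataFrame(pooled, index=["a188_reads", "b73_reads"]).T
    if any(sum(pooled[c]) == 0 for c in classes):
        return BsrTestResult(table, np.nan, np.nan, None, reason="zero reads in a class")

    (a1, b1), (a2, b2) = pooled["XT-I"], pooled["XT-II"]
    f1 = a1 / (a1 + b1)
    f2 = a2 / (a2 + b2)
    direction = "XT-I" if f1 > f2 else ("XT-II" if f2 > f1 else None)

    if pooling == "pool_replicates":
        dev, p = _gtest_2x2(a1, b1, a2, b2)
        return BsrTestResult(table, dev, p, direction)

    if pooling == "replicate_term":
        import statsmodels.api as sm

        sub = counts[counts["phenotype_class"].isin(classes)].reset_index(drop=True)
        endog = np.column_stack(
            [sub["a188_reads"].to_numpy(float), sub["b73_reads"].to_numpy(float)]
        )
        is_t2 = (sub["phenotype_class"] == "XT-II").to_numpy(float)
        rep = pd.get_dummies(
            sub.groupby("phenotype_class").cumcount(), drop_first=True, dtype=float
        ).to_numpy()
        X_full = sm.add_constant(np.column_stack([is_t2, rep]) if rep.size else is_t2)
        X_null = sm.add_constant(rep) if rep.size else np.ones((len(sub), 1))
        fit_full = sm.GLM(endog, X_full, family=sm.families.Binomial()).fit()
        fit_null = sm.GLM(endog, X_null, family=sm.families.Binomial()).fit()
        dev = max(float(2.0 * (fit_full.llf - fit_null.llf)), 0.0)
        return BsrTestResult(table, dev, float(stats.chi2.sf(dev, 1)), direction)

    raise ValueError(f"unknown pooling {pooling!r}")


def bsr_scan(counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Vectorized pooled association test over all SNPs.

    ``counts`` is tidy (one row per SNP x bulk) with columns ``chrom,
    pos_bp, phenotype_class, a188_reads, b73_reads``.  Returns one row per
    SNP with the deviance, p-value, direction, and a ``significant`` flag at
    the Bonferroni cutoff over the testable SNPs.
    """
    pooled = (
        counts.groupby(["chrom", "pos_bp", "phenotype_class"], sort=False)[
            ["a188_reads", "b73_reads"]
        ]
        .sum()
        .unstack("phenotype_class")
    )
    a1 = pooled[("a188_reads", "XT-I")].to_numpy(float)
    b1 = pooled[("b73_reads", "XT-I")].to_numpy(float)
    a2 = pooled[("a188_reads", "XT-II")].to_numpy(float)
    b2 = pooled[("b73_reads", "XT-II")].to_numpy(float)

    n1, n2 = a1 + b1, a2 + b2
    dev, pvals = binomial_deviance_test(a1, b1, a2, b2)

    f1 = np.divide(a1, n1, out=np.full_like(a1, np.nan), where=n1 > 0)
    f2 = np.divide(a2, n2, out=np.full_like(a2, np.nan), where=n2 > 0)
    direction = np.where(f1 > f2, "XT-I", np.where(f2 > f1, "XT-II", "none"))

    n_tests = int(np.isfinite(pvals).sum())
    cutoff = bonferroni_cutoff(max(n_tests, 1), alpha)
    out = pooled.index.to_frame(index=False)
    out["a188_reads_xt1"] = a1
    out["b73_reads_xt1"] = b1
    out["a188_reads_xt2"] = a2
    out["b73_reads_xt2"] = b2
    out["deviance"] = dev
    out["pvalue"] = pvals
    out["a188_enriched_in"] = direction
    out["significant"] = np.isfinite(pvals) & (pvals <= cutoff)
    return out


def bonferroni_cutoff(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test p cutoff for genome-wide significance: alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
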