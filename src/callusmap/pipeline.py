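"""End-to-end orchestration: simulate -> segments -> scan -> bsr -> integrate.

``run_pipeline`` executes every stage into a run directory, writing each
stage's tables plus a manifest (config, seeds, sha256 digests of every
output) and a log with per-filter rejection tallies.  Outputs contain no
timestamps and all floats are written with fixed precision, so rerunning
the same configuration reproduces byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import binmarkers, bsrseq, integrate, io, qtlscan, simdata
from .binmarkers import SegmentParams
from .config import PipelineConfig
from .core import GeneticMap

__all__ = ["run_pipeline"]


class _Log:
    def __init__(self) -> None:
        self.lines: list[str] = []

    def __call__(self, msg: str) -> None:
        self.lines.append(msg)

    def write(self, path: Path) -> None:
        path.write_text("".join(line + "\n" for line in self.lines))


def _sim_config(cfg: PipelineConfig) -> simdata.SimConfig:
    s = cfg.sim
    gmap = GeneticMap.uniform(s.chromosome_lengths_cm, bp_per_cm=s.bp_per_cm)
    if s.qtls is None:
        qtls = tuple(simdata.five_qtl_architecture(gmap))
    else:
        qtls = tuple(
            simdata.QtlSpec(
                q["chrom"], q["pos_cm"], q["beta"], q.get("dominance", 0.0)
            )
            for q in s.qtls
        )
    return simdata.SimConfig(
        genetic_map=gmap,
        qtls=qtls,
        mu=s.mu,
        n_embryos=s.n_embryos,
        n_select_per_class=s.n_select_per_class,
        snp_density=s.snp_density,
        missing_rate=s.missing_rate,
        genotype_error_rate=s.genotype_error_rate,
        het_undercall_rate=s.het_undercall_rate,
        bulk_size=s.bulk_size,
        bulk_depth_mean=s.bulk_depth_mean,
        n_bulk_reps=s.n_bulk_reps,
        seed=cfg.seed,
    )


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage; returns the run directory.

    Any stage failure propagates with the stage name prefixed; outputs of
    completed stages are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log()
    outputs: list[Path] = []
    stage = "simulate"
    try:
        # ------------------------------------------------------------------
        sim_cfg = _sim_config(cfg)
        truth = simdata.simulate_f2(sim_cfg)
        selected = truth.selected_type1 + truth.selected_type2
        phenotype = {i: 0 for i in truth.selected_type1}
        phenotype.update({i: 1 for i in truth.selected_type2})
        gbs = simdata.degrade_to_gbs(truth, individuals=selected)
        bulk_counts = simdata.simulate_bulk_counts(truth)

        seed_seq = np.random.SeedSequence(cfg.seed)
        rng_genes = np.random.default_rng(seed_seq.spawn(7)[6])
        # enrich DE genes around the true QTL neighborhoods (+-10 cM)
        qtl_neighborhoods = pd.DataFrame(
            [
                {
                    "chrom": q.chrom,
                    "start_bp": int(sim_cfg.genetic_map.chromosome(q.chrom).cm_to_bp(
                        max(q.pos_cm - 10, 0))),
                    "end_bp": int(sim_cfg.genetic_map.chromosome(q.chrom).cm_to_bp(
                        min(q.pos_cm + 10,
                            sim_cfg.genetic_map.chromosome(q.chrom).length_cm))),
                }
                for q in sim_cfg.qtls
            ]
        ) if sim_cfg.qtls else None
        genes, deg1, deg2 = simdata.make_gene_fixture(
            sim_cfg.genetic_map, cfg.sim.n_genes,
            qtl_intervals=qtl_neighborhoods, rng=rng_genes,
        )
        rpm = pd.DataFrame(
            rng_genes.gamma(2.0, 20.0, size=(len(genes), 4)).round(3),
            index=genes["gene_id"] if len(genes) else None,
            columns=["XT-I_rep1", "XT-I_rep2", "XT-II_rep1", "XT-II_rep2"],
        )

        io.write_genotype_tsv(gbs, outdir / "genotypes.tsv")
        io.write_phenotype_tsv(phenotype, outdir / "phenotypes.tsv")
        io.write_map_tsv(sim_cfg.genetic_map, outdir / "genetic_map.tsv")
        io.write_bulk_counts_tsv(bulk_counts, outdir / "bulk_counts.tsv")
        io.write_genes_bed(genes, outdir / "genes.bed")
        io.write_deg_tsv(deg1, outdir / "deg_type2_vs_type1.tsv")
        io.write_deg_tsv(deg2, outdir / "deg_fast_vs_slow.tsv")
        io.write_json(
            {
                "seed": cfg.seed,
                "qtls": [
                    {"chrom": q.chrom, "pos_cm": q.pos_cm, "beta": q.beta,
                     "dominance": q.dominance}
                    for q in sim_cfg.qtls
                ],
                "n_embryos": sim_cfg.n_embryos,
                "n_selected_per_class": sim_cfg.n_select_per_class,
            },
            outdir / "truth.json",
        )
        outputs += [
            outdir / f
            for f in (
                "genotypes.tsv", "phenotypes.tsv", "genetic_map.tsv",
                "bulk_counts.tsv", "genes.bed", "deg_type2_vs_type1.tsv",
                "deg_fast_vs_slow.tsv", "truth.json",
            )
        ]
        log(f"simulate: {sim_cfg.n_embryos} embryos, {len(selected)} selected, "
            f"{gbs.n_sites} SNPs")

        # ------------------------------------------------------------------
        stage = "segments"
        seg_cfg = cfg.segments
        qc_params = SegmentParams(seg_cfg.qc_smooth_window, seg_cfg.qc_min_snps_per_segment)
        map_params = SegmentParams(seg_cfg.smooth_window, seg_cfg.min_snps_per_segment)
        qc_segs = binmarkers.call_segments_all(gbs, qc_params)
        expected = binmarkers.expected_recombination_count(sim_cfg.genetic_map)
        retained, report = binmarkers.filter_individuals(
            qc_segs, expected, seg_cfg.qc_multiplier
        )
        io.write_table(
            report, outdir / "recombination_qc.tsv",
            "recombination QC; expected = 2 x map Morgans",
        )
        gbs_kept = gbs.subset_individuals(retained)
        segsets = binmarkers.call_segments_all(gbs_kept, map_params)
        bins = binmarkers.harmonize_bins(segsets, sim_cfg.genetic_map)
        io.write_segments_bed(segsets, outdir / "segments.bed")
        io.write_bins_tsv(bins, outdir / "bin_markers.tsv")
        outputs += [outdir / "recombination_qc.tsv", outdir / "segments.bed",
                    outdir / "bin_markers.tsv"]
        log(f"segments: retained {len(retained)}/{len(selected)} individuals "
            f"(expected {expected:.1f} events, multiplier {seg_cfg.qc_multiplier}); "
            f"{bins.n_bins} bin markers")

        # ------------------------------------------------------------------
        stage = "scan"
        sc = cfg.scan
        y = qtlscan.align_phenotype(bins.individuals, phenotype)
        rng_perm = np.random.default_rng(seed_seq.spawn(8)[7])

        logistic = qtlscan.genome_scan_logistic(bins, y)
        fdr_hits = qtlscan.fdr_significant(logistic, q=sc.fdr_q)
        interval = qtlscan.interval_scan_binary(
            bins, sim_cfg.genetic_map, y, step_cm=sc.step_cm
        )
        thresholds: dict[str, float | None] = {
            "lod_fixed": sc.lod_threshold, "logistic_perm": None, "interval_perm": None,
        }
        if sc.n_perm > 0:
            thr_p, _ = qtlscan.permutation_threshold(
                qtlscan.logistic_extremum_fn(bins), y, n_perm=sc.n_perm,
                alpha=sc.alpha, rng=rng_perm, higher_is_stronger=False,
            )
            thr_lod, _ = qtlscan.permutation_threshold(
                qtlscan.interval_extremum_fn(bins, sim_cfg.genetic_map, step_cm=max(sc.step_cm, 2.0)),
                y, n_perm=sc.n_perm, alpha=sc.alpha, rng=rng_perm,
                higher_is_stronger=True,
            )
            thresholds["logistic_perm"] = thr_p
            thresholds["interval_perm"] = thr_lod
            lod_cut = max(thr_lod, sc.lod_threshold)
        else:
            log("scan: n_perm=0 -> no permutation thresholds; "
                f"using fixed LOD {sc.lod_threshold}")
            lod_cut = sc.lod_threshold
        peaks = qtlscan.find_peaks(interval, lod_cut, sc.min_separation_cm)
        qtlscan.annotate_peaks(peaks, bins, y, scan=interval, lod_drop=sc.lod_drop)
        summary: dict = {"thresholds": thresholds, "n_fdr_significant_bins": len(fdr_hits)}
        if peaks:
            joint_lod, n_used = qtlscan.joint_qtl_fit(bins, peaks, y)
            summary["joint_lod"] = round(joint_lod, 4)
            summary["variance_explained_pct"] = round(
                qtlscan.variance_explained(joint_lod, n_used), 2
            )
            summary["n_joint_fit"] = n_used
        io.write_scan_tsv(logistic, outdir / "scan_logistic.tsv")
        io.write_scan_tsv(interval, outdir / "scan_interval.tsv")
        io.write_peaks_tsv(peaks, outdir / "qtl_peaks.tsv")
        io.write_intervals_bed(peaks, outdir / "qtl_intervals.bed")
        io.write_json(summary, outdir / "scan_summary.json")
        outputs += [outdir / f for f in (
            "scan_logistic.tsv", "scan_interval.tsv", "qtl_peaks.tsv",
            "qtl_intervals.bed", "scan_summary.json")]
        log(f"scan: {len(peaks)} peaks at LOD cutoff {lod_cut:.3g}; "
            f"{len(fdr_hits)} bins at FDR {sc.fdr_q}")

        # ------------------------------------------------------------------
        stage = "bsr"
        bsr = bsrseq.bsr_scan(bulk_counts, alpha=cfg.bsr.alpha)
        bsr_out = bsr.copy()
        bsr_out["pos_bp"] = bsr_out["pos_bp"].astype(np.int64) + 1
        io.write_table(bsr_out, outdir / "bsr_results.tsv",
                        "BSR-seq association; pos_bp 1-based; Bonferroni flag")
        sig = bsr[bsr["significant"]]
        sig_bed = sig[["chrom", "pos_bp"]].copy()
        sig_bed["end"] = sig_bed["pos_bp"] + 1
        io.write_table(sig_bed.rename(columns={"pos_bp": "start"}),
                        outdir / "bsr_significant.bed",
                        "significant BSR-seq SNPs; BED-style 0-based half-open")
        outputs += [outdir / "bsr_results.tsv", outdir / "bsr_significant.bed"]
        log(f"bsr: {len(sig)}/{len(bsr)} SNPs significant (Bonferroni, "
            f"alpha={cfg.bsr.alpha})")

        # ------------------------------------------------------------------
        stage = "integrate"
        if peaks:
            intervals = pd.DataFrame(
                [
                    {"qtl": p.name, "chrom": p.chrom,
                     "start_bp": p.interval_bp[0], "end_bp": p.interval_bp[1]}
                    for p in peaks if p.interval_bp
                ]
            )
            candidates = integrate.candidate_genes(
                intervals, genes, deg1, deg2,
                require_concordance=cfg.integrate.require_concordance,
                full_containment=cfg.integrate.full_containment,
            )
        else:
            candidates = pd.DataFrame()
        io.write_table(candidates, outdir / "candidate_genes.tsv",
                        "QTL-interval x DEG candidates; bp 0-based half-open")
        # inbred-style profile of one selected Type II individual (demo)
        profile = integrate.profile_inbred(gbs_kept, retained[-1])
        io.write_table(profile.to_frame(), outdir / "inbred_profile.tsv",
                        "segment profile; bp 0-based half-open")
        if len(rpm):
            z, flags = integrate.standardize_expression(rpm)
            io.write_table(z.reset_index(), outdir / "rpm_standardized.tsv",
                            "gene-wise z-scored RPM (mean 0, sd 1)")
            outputs.append(outdir / "rpm_standardized.tsv")
        outputs += [outdir / "candidate_genes.tsv", outdir / "inbred_profile.tsv"]
        log(f"integrate: {len(candidates)} candidate genes; "
            f"{profile.breakpoint_count} breakpoints in demo profile")

    except Exception as exc:
        log(f"FAILED at stage {stage}: {exc}")
        log_path = outdir / "pipeline.log"
        log.write(log_path)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "callusmap",
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "outputs": {p.name: io.sha256_of(p) for p in sorted(outputs)},
    }
    io.write_json(manifest, outdir / "manifest.json")
    log.write(outdir / "pipeline.log")
    return outdir
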