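"""End-to-end pipeline: simulate -> discover -> genotype -> filter ->
per-locus stats -> outlier scan -> windowed scan -> LD -> smoothing.

Every stage logs its inputs, seed and counts, writes TSV outputs under
the run directory, and the run finishes with a manifest of all files.
Re-running with the same configuration reproduces every output
bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import discovery, genomescan, io as rio, outliers as outl, qcfilter, simdata, stats
from .genotyping import call_matrix

log = logging.getLogger("radpopgen")


def setup_logging(level: str = "INFO", logfile=None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True,
    )


def run_pipeline(config: rio.RunConfig, outdir=None) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "seed": config.seed, "counts": {}}

    def emit(name: str, path: Path) -> Path:
        manifest["outputs"][name] = str(path)
        return path

    # -- simulate ----------------------------------------------------------
    log.info("simulate: %d loci, seed=%d", config.sim.n_loci, config.sim.seed)
    ds = simdata.simulate_dataset(config.sim)
    ds.truth.table.to_csv(emit("truth", out / "truth.tsv"), sep="\t")
    rio.write_read_counts(ds.read_counts, emit("read_counts", out / "read_counts.tsv"))
    rio.write_linkage_map(ds.linkage_map, emit("linkage_map", out / "map.tsv"))
    rio.write_metadata(ds.genotypes.metadata, emit("metadata", out / "metadata.tsv"))

    # -- discovery on a subset of individuals (reads) ----------------------
    n_disc = min(config.n_discovery_individuals, len(ds.genotypes.individuals))
    disc_inds = list(ds.genotypes.individuals[:n_disc])
    reads_path = emit("discovery_reads", out / "discovery_reads.fasta")
    sub = ds.genotypes.subset_individuals(
        np.isin(np.arange(len(ds.genotypes.individuals)), np.arange(n_disc)))
    # discovery reads are shallower per individual: stacking pools the
    # subset, and the [5, 200] stack-depth band targets pooled depths
    disc_cfg = config.sim.replace(mean_depth=config.sim.discovery_mean_depth)
    n_reads = simdata.emit_reads(sub, ds.truth, disc_cfg, reads_path)
    log.info("discovery: %d reads from %d individuals", n_reads, n_disc)
    pops = list(config.sim.pop_names)
    subsets = [set(disc_inds)]
    for pop in pops:
        members = {i for i in disc_inds if i.startswith(pop)}
        if members:
            subsets.append(members)
    candidate_sets = []
    from Bio.SeqIO.FastaIO import SimpleFastaParser
    for subset in subsets:
        with open(reads_path) as fh:
            candidate_sets.append(
                discovery.discover(SimpleFastaParser(fh), individuals=subset)
            )
    database = discovery.build_snp_database(candidate_sets)
    database.to_csv(emit("snp_database", out / "snp_database.tsv"), sep="\t")
    manifest["counts"]["discovered_loci"] = len(database)
    log.info("discovery: %d candidate loci", len(database))

    # -- genotyping --------------------------------------------------------
    called = call_matrix(ds.read_counts, ds.genotypes.metadata, config.thresholds)
    rio.write_genotype_table(called, emit("genotypes", out / "genotypes.tsv"))
    manifest["counts"]["genotyped_loci"] = len(called.loci)

    # -- filtering ---------------------------------------------------------
    filtered, report = qcfilter.run_filter_cascade(called, config.filters)
    report.to_frame().to_csv(emit("filter_report", out / "filter_report.tsv"),
                             sep="\t", index=False)
    rio.write_genotype_table(filtered, emit("filtered_genotypes",
                                            out / "filtered_genotypes.tsv"))
    for line in report.lines():
        log.info("filter: %s", line)
    manifest["counts"]["filtered_loci"] = len(filtered.loci)

    # -- per-locus statistics ---------------------------------------------
    het = stats.heterozygosities(filtered)
    fst = stats.pairwise_fst(filtered)
    priv = stats.private_alleles(filtered)
    locus_stats = het.join(fst[["fst", "fst_raw"]]).join(priv)
    locus_stats.to_csv(emit("locus_stats", out / "locus_stats.tsv"), sep="\t")
    manifest["counts"]["mean_fst"] = fst.attrs["mean_fst"]
    log.info("stats: mean FST %.4f over %d loci",
             fst.attrs["mean_fst"], len(filtered.loci))

    # -- outlier scan ------------------------------------------------------
    observed = pd.DataFrame({"fst": fst["fst"], "he": het["h_e"]}).dropna()
    ann, table, f_star = outl.scan(observed, config.outliers)
    ann.to_csv(emit("outlier_table", out / "outliers.tsv"), sep="\t")
    pd.DataFrame({"he": table.he, "fst": table.fst}).to_csv(
        emit("null_table", out / "null_table.tsv"), sep="\t", index=False)
    n_cand = int((ann["classification"] == outl.CANDIDATE_POSITIVE).sum())
    manifest["counts"]["candidate_positive"] = n_cand
    manifest["counts"]["calibrated_F"] = f_star
    log.info("outliers: F*=%.4f, %d candidate-positive loci", f_star, n_cand)

    # -- windowed scan (per population) ------------------------------------
    windows = []
    for pop in pops:
        w = stats.windowed_scan(filtered, pop, config.windows)
        w.insert(0, "population", pop)
        windows.append(w)
    window_stats = pd.concat(windows)
    window_stats.to_csv(emit("window_stats", out / "window_stats.tsv"), sep="\t")

    # -- LD ----------------------------------------------------------------
    ld_frames = []
    chrom_means = {}
    for pop in pops:
        summary = genomescan.chromosome_ld_summary(filtered, ds.linkage_map, pop)
        summary.insert(0, "population", pop)
        ld_frames.append(summary)
        chrom_means[pop] = summary["mean_d_prime"].to_numpy()
        manifest["counts"][f"mean_d_prime_{pop}"] = summary.attrs["overall_mean"]
    ld = pd.concat(ld_frames)
    ld.to_csv(emit("ld_summary", out / "ld_summary.tsv"), sep="\t", index=False)
    if all(len(v) >= 2 for v in chrom_means.values()):
        t, p = genomescan.compare_ld_populations(*chrom_means.values())
        manifest["counts"]["ld_t_statistic"] = t
        manifest["counts"]["ld_p_value"] = p

    # -- smoothing ---------------------------------------------------------
    track = genomescan.smooth_map(ds.linkage_map, fst["fst"], config.smoothing)
    track.to_csv(emit("smoothed_fst", out / "smoothed_fst.tsv"), sep="\t",
                 index=False)

    # -- VCF + manifest ----------------------------------------------------
    rio.write_vcf(filtered, emit("vcf", out / "genotypes.vcf"), ds.linkage_map)
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest"] = str(manifest_path)
    log.info("pipeline complete: %d outputs under %s",
             len(manifest["outputs"]), out)
    return manifest
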