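"""High-level stage runners shared by the CLI and the analysis drivers.

Each runner reads its inputs from and writes its outputs to a working
directory, so the stages compose as: simulate -> bsa / rnaseq / hormones ->
associate -> report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, bsa, hormones, io, rnaseq, simulate
from .config import RunConfig

log = logging.getLogger("bulkseg")


def _ensure(outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(config: RunConfig, outdir) -> dict:
    """Generate the full synthetic BC8 dataset and write every input file."""
    out = _ensure(outdir)
    config.log_echo()
    sim = simulate.SimulationConfig(
        seed=config.seed,
        generations=config.generations,
        population_size=config.population_size,
        n_tall_bulk=config.n_tall_bulk,
        n_dwarf_bulk=config.n_dwarf_bulk,
        mean_depth_tall=config.mean_depth_tall,
        mean_depth_dwarf=config.mean_depth_dwarf,
        n_genes=config.n_genes,
    )
    rng = np.random.default_rng(sim.seed)
    genome = simulate.default_genome()
    pop = simulate.advance_backcross(
        simulate.f1_hybrid(genome),
        simulate.recurrent_parent(genome),
        sim.generations,
        genome,
        rng,
        select_carriers=True,
        n_offspring=sim.population_size,
    )
    tall, dwarf = simulate.select_bulks(pop, sim.n_tall_bulk, sim.n_dwarf_bulk, rng)
    depths = simulate.simulate_bulk_depths(
        tall, dwarf, genome, sim.mean_depth_tall, sim.mean_depth_dwarf, rng
    )
    io.write_allele_depths(depths, out / "allele_depths.tsv")
    io.write_vcf_depths(depths, out / "allele_depths.vcf")

    genes = simulate.default_gene_models(genome, sim.n_genes)
    io.write_gene_models(genes, out / "gene_models.tsv")
    cchrom, cpos = genome.causal
    region = (cchrom, max(1, cpos - 3_000_000), cpos + 3_000_000)
    counts, truth = simulate.simulate_counts(sim, genes, region, rng)
    io.write_counts(counts, genes.set_index("gene_id")["length"], out / "counts.tsv")
    truth.to_csv(out / "truth_de.tsv", sep="\t", index=False)

    panel = simulate.simulate_hormones(sim, rng)
    io.write_csv(panel, out / "hormones.csv")
    qpcr = simulate.simulate_qpcr(truth, rng, noise_sd=sim.qpcr_noise_sd)
    io.write_csv(qpcr, out / "qpcr.csv")

    meta = {
        "seed": sim.seed,
        "causal": {"chrom": cchrom, "pos": cpos},
        "region": {"chrom": region[0], "start": region[1], "end": region[2]},
        "n_tall": len(tall),
        "n_dwarf": len(dwarf),
    }
    (out / "truth_meta.json").write_text(json.dumps(meta, indent=2))
    log.info("simulated %d SNP records, %d genes", len(depths), len(genes))
    return meta


def run_bsa(config: RunConfig, workdir, depths_path=None) -> list[bsa.CandidateInterval]:
    """SNP-index scan: filter, index, smooth, thresholds, interval calls."""
    out = _ensure(workdir)
    config.log_echo()
    path = Path(depths_path) if depths_path else out / "allele_depths.tsv"
    records = io.read_allele_depths(
        path,
        **(
            {}
            if path.suffix != ".vcf"
            else {
                "tall_sample": config.tall_sample,
                "dwarf_sample": config.dwarf_sample,
                "maternal_is_ref": config.maternal_is_ref,
            }
        ),
    )
    kept = bsa.filter_informative_snps(records, config.min_depth, config.max_depth)
    track = bsa.compute_index_track(kept)
    track = bsa.smooth_delta(track, span=config.span)
    # sparse depth grid: thresholds vary slowly with coverage
    depth_grid = np.unique(
        np.clip(np.array([10, 30, 60, 120, 200]), config.min_depth, config.max_depth)
    )
    positions = {
        str(c): g["pos"].to_numpy(np.int64) for c, g in track.groupby("chrom", sort=False)
    }
    thr = bsa.simulate_null_thresholds(
        config.n_tall_bulk,
        config.n_dwarf_bulk,
        depth_grid,
        generation=config.generations,
        confidence_levels=(0.95, 0.99),
        reps=config.threshold_reps,
        rng=np.random.default_rng(config.seed + 7_000_000),
        positions=positions,
        rate_cm_per_mb=config.rate_cm_per_mb,
        span=config.span,
    )
    track["threshold"] = bsa.threshold_at_depth(
        thr,
        np.minimum(track["M_tall"] + track["P_tall"], track["M_dwarf"] + track["P_dwarf"]),
        config.confidence_level,
    )
    intervals = bsa.call_candidate_intervals(
        track, thr, config.min_snps, config.merge_gap, config.confidence_level
    )
    io.write_track(track, out / "index_track.tsv")
    thr.to_csv(out / "thresholds.tsv", sep="\t", index=False)
    io.write_intervals(intervals, out / "intervals.tsv")
    io.write_intervals_bed(intervals, out / "intervals.bed")
    log.info(
        "called %d interval(s), span %.2f Mb",
        len(intervals),
        bsa.total_interval_span(intervals) if intervals else 0.0,
    )
    return intervals


def run_rnaseq(config: RunConfig, workdir, counts_path=None, qpcr_path=None) -> pd.DataFrame:
    """FPKM, NB Wald test, DEG classification, clustering, qPCR concordance."""
    out = _ensure(workdir)
    config.log_echo()
    path = Path(counts_path) if counts_path else out / "counts.tsv"
    if not path.exists():
        raise FileNotFoundError(path)
    counts, lengths = io.read_counts(path)
    groups = pd.Series(
        ["tall" if c.lower().startswith("tall") else "dwarf" for c in counts.columns],
        index=counts.columns,
    )
    fpkm = rnaseq.compute_fpkm(counts, lengths, None)
    de = rnaseq.nb_wald_test(counts, groups)
    de = rnaseq.classify_degs(
        de,
        fpkm,
        lfc_cutoff=config.lfc_cutoff,
        padj_cutoff=config.padj_cutoff,
        fpkm_min=config.fpkm_min,
        filter_rule=config.fpkm_filter_rule,
    )
    de.index.name = "gene_id"
    de.to_csv(out / "de_results.tsv", sep="\t", na_rep="NA")

    degs = de.index[de["status"].isin(["up", "down"])]
    if len(degs) >= config.kmeans_k:
        prof = rnaseq.zscore_profiles(fpkm, degs)
        clusters = rnaseq.kmeans_cluster(
            prof, groups, k=config.kmeans_k, seed=config.seed, restarts=config.kmeans_restarts
        )
        clusters.index.name = "gene_id"
        clusters.to_csv(out / "clusters.tsv", sep="\t")

    qp = Path(qpcr_path) if qpcr_path else out / "qpcr.csv"
    if qp.exists():
        ct = io.read_qpcr(qp)
        qfc = rnaseq.qpcr_fold_changes(ct)
        paired = qfc.index.intersection(de.index)
        r2 = rnaseq.qpcr_concordance(qfc.loc[paired], de.loc[paired, "log2fc"])
        pd.DataFrame(
            {"gene_id": paired, "qpcr_log2fc": qfc.loc[paired], "rnaseq_log2fc": de.loc[paired, "log2fc"]}
        ).to_csv(out / "qpcr_concordance.tsv", sep="\t", index=False)
        (out / "qpcr_r2.txt").write_text(f"{r2:.4f}\n")
        log.info("qPCR vs RNA-seq concordance R^2 = %.4f", r2)
    log.info(
        "DEGs: %d up, %d down of %d genes",
        int((de["status"] == "up").sum()),
        int((de["status"] == "down").sum()),
        len(de),
    )
    return de


def run_hormones(config: RunConfig, workdir, panel_path=None) -> pd.DataFrame:
    out = _ensure(workdir)
    config.log_echo()
    path = Path(panel_path) if panel_path else out / "hormones.csv"
    if not path.exists():
        raise FileNotFoundError(path)
    panel = io.read_hormone_panel(path)
    by_class = hormones.compare_groups(panel, by="class")
    by_compound = hormones.compare_groups(panel, by="compound")
    by_class.to_csv(out / "hormone_classes.tsv", sep="\t", index=False)
    by_compound.to_csv(out / "hormone_compounds.tsv", sep="\t", index=False)
    return by_class


def run_associate(config: RunConfig, workdir) -> pd.DataFrame:
    out = _ensure(workdir)
    config.log_echo()
    genes = io.read_gene_models(out / "gene_models.tsv")
    intervals = io.read_intervals(out / "intervals.tsv")
    de = pd.read_csv(out / "de_results.tsv", sep="\t", index_col="gene_id", na_values="NA")
    members = association.intersect_genes_intervals(genes, intervals)
    tally = association.tally_direction(de["status"], members)
    tally.to_csv(out / "association.tsv", sep="\t", index=False, na_rep="NA")
    return tally


def run_report(config: RunConfig, workdir) -> dict:
    """Merge the stage outputs into one JSON summary."""
    out = _ensure(workdir)
    summary: dict = {"seed": config.seed, "config": config.digest()}
    ivp = out / "intervals.tsv"
    if ivp.exists():
        intervals = io.read_intervals(ivp)
        summary["n_intervals"] = len(intervals)
        summary["interval_span_mb"] = bsa.total_interval_span(intervals) if intervals else 0.0
    dep = out / "de_results.tsv"
    if dep.exists():
        de = pd.read_csv(dep, sep="\t", index_col="gene_id", na_values="NA")
        summary["n_up"] = int((de["status"] == "up").sum())
        summary["n_down"] = int((de["status"] == "down").sum())
    assoc = out / "association.tsv"
    if assoc.exists():
        tally = pd.read_csv(assoc, sep="\t", na_values="NA")
        union = tally[tally["interval"] == "union"].iloc[0]
        summary["region_genes"] = int(union["genes"])
        summary["region_degs"] = int(union["degs"])
        if union["degs"]:
            summary["region_pct_up"] = float(union["pct_up"])
            summary["region_pct_deg"] = association.percent(
                int(union["degs"]), int(union["genes"])
            )
    r2p = out / "qpcr_r2.txt"
    if r2p.exists():
        summary["qpcr_r2"] = float(r2p.read_text().strip())
    (out / "report.json").write_text(json.dumps(summary, indent=2))
    log.info("report: %s", json.dumps(summary))
    return summary
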