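"""End-to-end orchestration: simulate -> call -> integrate -> report.

`run_all` chains every stage from a single :class:`RunConfig`, writes all
intermediate artifacts (FASTA/GFF3/BED/CX/TSV) into an output directory,
and returns a summary dictionary.  Output is a pure function of
(config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import dmr as dmr_mod
from . import expression as expr_mod
from . import integrate as int_mod
from . import io as io_mod
from . import methylcall as mc_mod
from .config import RunConfig, dump_config
from .simulate import CONTROL_CHROM, simulate_dataset

logger = logging.getLogger(__name__)


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(config, outdir / "config.resolved.yaml")
    pp = config.pipeline

    logger.info("simulating dataset (scenario=%s, seed=%d)", config.sim.scenario, config.sim.seed)
    ds = simulate_dataset(config.sim)
    io_mod.write_fasta(ds.genome, outdir / "genome.fa")
    io_mod.write_gff3(ds.annotation.genes, ds.annotation.subfeatures, outdir / "annotation.gff3")
    io_mod.write_bed(ds.annotation.repeats.assign(name="repeat"), outdir / "repeats.bed")
    cx_dir = outdir / "cx"
    cx_dir.mkdir(exist_ok=True)
    for sample, sub in ds.methyl_counts.groupby("sample"):
        io_mod.write_cx(sub, cx_dir / f"{sample}.cx.tsv")
    io_mod.write_counts_matrix(ds.expr_counts, outdir / "expression_counts.tsv")
    io_mod.write_tsv(ds.design, outdir / "design.tsv")
    io_mod.write_tsv(ds.truth.planted_dmrs, outdir / "truth_dmrs.tsv")
    io_mod.write_tsv(ds.truth.planted_degs, outdir / "truth_degs.tsv")

    if pp.r is None:
        model = mc_mod.estimate_r(ds.methyl_counts, CONTROL_CHROM)
    else:
        model = mc_mod.ConversionModel(pp.r, source="config")
    logger.info("non-conversion rate r=%.5f (%s)", model.r, model.source)

    calls = mc_mod.call_sites(
        ds.methyl_counts, model, alpha=pp.site_alpha, min_coverage=pp.min_coverage
    )
    call_summary = (
        calls.groupby(["sample", "context"])["is_methylated"].agg(["sum", "count"])
        .rename(columns={"sum": "n_methylated", "count": "n_tested"})
        .reset_index()
    )
    io_mod.write_tsv(call_summary, outdir / "site_call_summary.tsv")

    bins = mc_mod.bin_genome(ds.chrom_lengths, width=pp.bin_width)
    bin_ml = mc_mod.methylation_level(ds.methyl_counts, bins)
    io_mod.write_tsv(bin_ml, outdir / "ml_bins.tsv")

    features = dmr_mod.build_features(
        ds.annotation.genes, ds.annotation.subfeatures, ds.chrom_lengths,
        promoter_length=pp.promoter_length, repeats=ds.annotation.repeats,
    )
    feat_regions = features.assign(
        region_id=features["gene_id"].fillna("repeat").astype(str) + ":" + features["kind"]
    )[["region_id", "chrom", "start", "end"]]
    feature_ml = mc_mod.methylation_level(ds.methyl_counts, feat_regions)
    io_mod.write_tsv(feature_ml, outdir / "ml_features.tsv")

    params = dmr_mod.DmrParams(
        window=pp.window, step=pp.step, delta_min=pp.delta_min,
        alpha=pp.dmr_alpha, merge_gap=pp.merge_gap,
    )
    dmrs = dmr_mod.call_dmrs(
        ds.methyl_counts, ds.case_samples, ds.control_samples, ds.chrom_lengths, params
    )
    io_mod.write_tsv(dmrs, outdir / "dmrs.tsv")
    io_mod.write_bed(io_mod.dmrs_to_bed(dmrs), outdir / "dmrs.bed")

    links = dmr_mod.associate_dmrs(dmrs, features)
    dmgs = dmr_mod.aggregate_dmgs(links)
    io_mod.write_tsv(links, outdir / "dmr_gene_links.tsv")
    io_mod.write_tsv(dmgs, outdir / "dmgs.tsv")

    io_mod.write_tsv(ds.library_sizes.reset_index(name="library_size"), outdir / "library_sizes.tsv")
    rpkm = expr_mod.rpkm(ds.expr_counts, ds.gene_lengths, ds.library_sizes)
    io_mod.write_tsv(rpkm.reset_index(), outdir / "rpkm.tsv")
    degs = expr_mod.call_degs(
        rpkm, ds.case_samples, ds.control_samples,
        fc_min=pp.fc_min, alpha=pp.deg_alpha, pseudocount=pp.pseudocount,
    )
    io_mod.write_tsv(degs, outdir / "degs.tsv")

    records = int_mod.overlap_dmg_deg(links, degs)
    io_mod.write_tsv(records, outdir / "integration_records.tsv")
    quadrants = int_mod.classify_quadrants(records)
    io_mod.write_tsv(quadrants.reset_index(), outdir / "quadrants.tsv")
    if not records.empty:
        for axis in ("context", "feature"):
            io_mod.write_tsv(
                int_mod.distribution_by(records, axis), outdir / f"distribution_{axis}.tsv"
            )
        report = int_mod.gene_report(records, sorted(records["gene_id"].unique()))
        io_mod.write_tsv(report, outdir / "gene_report.tsv")
    pairs = int_mod.scatter_pairs(links, degs, gene_set="linked")
    io_mod.write_tsv(pairs, outdir / "scatter_pairs.tsv")
    correlations = int_mod.correlate(pairs)
    io_mod.write_tsv(correlations, outdir / "correlations.tsv")

    summary = {
        "scenario": config.sim.scenario,
        "seed": config.sim.seed,
        "r_estimate": model.r,
        "n_sites": int(ds.methyl_counts[["chrom", "pos", "strand"]].drop_duplicates().shape[0]),
        "n_dmrs": int(len(dmrs)),
        "n_dmrs_by_context": {
            k: int(v) for k, v in dmrs["context"].value_counts().items()
        } if not dmrs.empty else {},
        "n_dmgs": int(len(dmgs)),
        "n_degs": int((degs["de_status"] != "none").sum()),
        "n_dmg_deg_genes": int(records["gene_id"].nunique()),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
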